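"""Correlation screening, genomic distance and cis/trans assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lncflow as lf
from test_triage import make_tx


def tx_at(tid, chrom, start, end):
    return lf.TranscriptModel(
        transcript_id=tid,
        gene_id=tid,
        chrom=chrom,
        strand="+",
        exons=((start, end),),
        class_code="u",
    )


class TestPearsonWithP:
    def test_identity_and_reflection(self):
        x = np.arange(8.0)
        r, p = lf.pearson_with_p(x, x)
        assert (r, p) == (1.0, 0.0)
        r, p = lf.pearson_with_p(x, -x)
        assert (r, p) == (-1.0, 0.0)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            r, p = lf.pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            lf.pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            lf.pearson_with_p([1.0, 2.0], [1.0, 2.0])


class TestInferTransTargets:
    def test_planted_noise_free_pairs_retained_with_sign(self):
        del_expr, deg_expr, _, planted = lf.noise_free_pair_fixture(seed=3)
        pairs = lf.infer_trans_targets(del_expr, deg_expr)
        got = {(p.del_id, p.deg_id): p.sign for p in pairs}
        for pl in planted:
            assert got[(pl.lnc_id, pl.gene_id)] == pl.sign

    def test_sub_threshold_r_excluded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        # construct y with sample correlation exactly 0.89
        y = 0.89 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.89**2) * _orth(x)
        del_expr = pd.DataFrame([x], index=["L"], columns=list("abcdefgh"))
        deg_expr = pd.DataFrame([y], index=["G"], columns=list("abcdefgh"))
        r, _ = lf.pearson_with_p(x, y)
        assert abs(r) == pytest.approx(0.89, abs=1e-9)
        assert lf.infer_trans_targets(del_expr, deg_expr) == []

    def test_null_retention_rate_is_low(self):
        rng = np.random.default_rng(2)
        n_del, n_deg = 20, 100  # 2,000 independent pairs
        samples = [f"s{i}" for i in range(8)]
        del_expr = pd.DataFrame(
            rng.normal(size=(n_del, 8)),
            index=[f"L{i}" for i in range(n_del)], columns=samples,
        )
        deg_expr = pd.DataFrame(
            rng.normal(size=(n_deg, 8)),
            index=[f"G{i}" for i in range(n_deg)], columns=samples,
        )
        pairs = lf.infer_trans_targets(del_expr, deg_expr)
        assert len(pairs) / (n_del * n_deg) < 0.01

    def test_disjoint_sample_sets_rejected(self):
        a = pd.DataFrame([[1.0, 2.0, 3.0]], index=["L"], columns=list("abc"))
        b = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G"], columns=list("xyz"))
        with pytest.raises(ValueError, match="sample set"):
            lf.infer_trans_targets(a, b)


def _orth(x):
    """Unit-variance vector orthogonal to (centered) x."""
    rng = np.random.default_rng(99)
    z = rng.normal(size=x.size)
    xc = (x - x.mean()) / x.std()
    z = z - z.mean()
    z = z - (z @ xc) / (xc @ xc) * xc
    return z / z.std()


class TestGenomicDistance:
    def test_overlap_is_zero(self):
        a = tx_at("a", "chr1", 100, 200)
        b = tx_at("b", "chr1", 150, 300)
        assert lf.genomic_distance(a, b) == 0

    def test_gap_arithmetic(self):
        a = tx_at("a", "chr1", 100, 200)
        b = tx_at("b", "chr1", 251, 400)
        assert lf.genomic_distance(a, b) == 50  # 251 - 200 - 1

    def test_different_chromosomes(self):
        a = tx_at("a", "chr1", 100, 200)
        b = tx_at("b", "chr2", 100, 200)
        assert lf.genomic_distance(a, b) is None

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s1, s2 = rng.integers(1, 10_000, size=2)
            a = tx_at("a", "chr1", int(s1), int(s1) + 100)
            b = tx_at("b", "chr1", int(s2), int(s2) + 500)
            assert lf.genomic_distance(a, b) == lf.genomic_distance(b, a)

    def test_span_is_used_not_exons(self):
        a = make_tx("a", length=200, n_exons=2)  # span covers the intron
        b = tx_at("b", "chr1", a.span[1] + 11, a.span[1] + 200)
        assert lf.genomic_distance(a, b) == 10


class TestAssignCis:
    def pair(self, del_id="L", deg_id="G"):
        return lf.RegulatoryPair(
            del_id=del_id, deg_id=deg_id, r=0.95, p_value=1e-4,
            sign="positive", mode="trans",
        )

    @pytest.mark.parametrize("gap,mode", [(19_999, "cis"), (20_000, "trans")])
    def test_boundary_distances(self, gap, mode):
        a = tx_at("L", "chr1", 1000, 2000)
        b = tx_at("G", "chr1", 2000 + gap + 1, 2000 + gap + 500)
        out = lf.assign_cis([self.pair()], {"L": a, "G": b})
        assert out[0].mode == mode
        assert out[0].distance_bp == gap

    def test_missing_annotation_is_an_error(self):
        with pytest.raises(KeyError, match="G"):
            lf.assign_cis([self.pair()], {"L": tx_at("L", "chr1", 1, 100)})

    def test_conserves_pairs(self):
        del_expr, deg_expr, annotation, _ = lf.noise_free_pair_fixture(seed=5)
        pairs = lf.infer_trans_targets(del_expr, deg_expr)
        out = lf.assign_cis(pairs, annotation)
        assert len(out) == len(pairs)
        assert {(p.del_id, p.deg_id) for p in out} == {
            (p.del_id, p.deg_id) for p in pairs
        }

    def test_noise_free_modes_recovered_exactly(self):
        del_expr, deg_expr, annotation, planted = lf.noise_free_pair_fixture(
            seed=7
        )
        pairs = lf.assign_cis(
            lf.infer_trans_targets(del_expr, deg_expr), annotation
        )
        got = {(p.del_id, p.deg_id): p.mode for p in pairs}
        expected = {(p.lnc_id, p.gene_id): p.mode for p in planted}
        assert got == expected


class TestSummarizeNetwork:
    def test_empty(self):
        s = lf.summarize_network([])
        assert s.n_pairs == 0 and s.dual_mode_del_ids == ()

    def test_counting(self):
        def mk(i, sign, mode):
            r = 0.95 if sign == "positive" else -0.95
            return lf.RegulatoryPair(
                f"L{i}", f"G{i}", r, 1e-4, sign, mode
            )

        pairs = [
            mk(0, "positive", "cis"),
            mk(1, "positive", "trans"),
            mk(2, "positive", "trans"),
            mk(3, "negative", "cis"),
            mk(4, "negative", "trans"),
        ]
        s = lf.summarize_network(pairs)
        assert (s.n_pairs, s.n_positive, s.n_negative) == (5, 3, 2)
        assert (s.n_cis, s.n_trans) == (2, 3)

    def test_dual_mode_detection(self):
        pairs = [
            lf.RegulatoryPair("L", "G1", 0.95, 1e-4, "positive", "cis"),
            lf.RegulatoryPair("L", "G2", 0.92, 1e-4, "positive", "trans"),
            lf.RegulatoryPair("M", "G3", 0.92, 1e-4, "positive", "trans"),
        ]
        s = lf.summarize_network(pairs)
        assert s.dual_mode_del_ids == ("L",)


class TestRegulatoryPairInvariants:
    def test_sign_must_match_r(self):
        with pytest.raises(ValueError, match="sign"):
            lf.RegulatoryPair("L", "G", -0.95, 0.001, "positive", "trans")

    def test_r_squared(self):
        p = lf.RegulatoryPair("L", "G", -0.95, 0.001, "negative", "trans")
        assert p.r_squared == pytest.approx(0.9025, abs=1e-12)
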