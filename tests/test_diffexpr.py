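"""Normalization, NB Wald testing, BH adjustment, DE calling, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import lncflow as lf
from lncflow.simulate import nb_counts
from test_triage import make_tx


def two_group_design(n=4, ref="A", con="B"):
    groups = {f"{ref}{i}": ref for i in range(n)}
    groups.update({f"{con}{i}": con for i in range(n)})
    return lf.Design(groups, ref, con)


def null_counts(seed, n_features=200, mu=100.0, alpha=0.05, n=4):
    rng = np.random.default_rng(seed)
    design = two_group_design(n)
    counts = pd.DataFrame(
        nb_counts(rng, np.full((n_features, 2 * n), mu), alpha),
        index=[f"f{i}" for i in range(n_features)],
        columns=design.samples,
    )
    return counts, design


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(lf.size_factors(df), [1.0, 1.0])

    def test_doubled_column_scales_proportionally(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = lf.size_factors(df)
        assert f["b"] / f["a"] == pytest.approx(2.0)
        assert np.prod(f) == pytest.approx(1.0)  # geometric mean 1

    def test_matches_literal_median_of_ratios(self):
        # odd feature count: the log-space median used by the estimator
        # coincides exactly with the literal linear median of ratios
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(1, 1000, size=(51, 8)),
            columns=[f"s{i}" for i in range(8)],
        )
        f = lf.size_factors(df)
        geo = np.exp(np.log(df).mean(axis=1))
        expected = df.div(geo, axis=0).median(axis=0)
        assert np.allclose(f, expected)

    def test_matches_reference_engine(self):
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(60, 8)),
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(8)],
        )
        meta = pd.DataFrame(
            {"condition": ["A"] * 4 + ["B"] * 4}, index=counts.columns
        )
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        assert np.allclose(
            lf.size_factors(counts), dds.obs["size_factors"], atol=1e-8
        )

    def test_no_universally_expressed_feature_is_an_error(self):
        df = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="filter"):
            lf.size_factors(df)


class TestNbWaldTest:
    def test_null_feature_near_zero_lfc(self):
        counts, design = null_counts(0, n_features=500)
        res = lf.nb_wald_test(counts, design)
        assert abs(res["log2fc"].mean()) < 0.05
        assert res["p_value"].between(0, 1).all()

    def test_all_zero_feature_flagged(self):
        counts, design = null_counts(1, n_features=50)
        counts.iloc[0] = 0
        res = lf.nb_wald_test(counts, design)
        assert res.iloc[0]["all_zero"]
        assert res.iloc[0]["p_value"] == 1.0
        assert res.iloc[0]["log2fc"] == 0.0

    def test_type_i_error_calibrated(self):
        # smaller version of the 20-seed calibration; the full run is in
        # the acceptance suite
        rates = []
        for seed in range(5):
            counts, design = null_counts(seed, n_features=1000)
            res = lf.nb_wald_test(counts, design)
            rates.append((res["p_value"] < 0.05).mean())
        assert 0.02 <= np.mean(rates) <= 0.10

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(5)
        design = two_group_design()
        lfc = np.array([3.0] * 20 + [0.0] * 180)
        mu = 100.0 * 2.0 ** (
            np.where(np.arange(8) >= 4, lfc[:, None] / 2, -lfc[:, None] / 2)
        )
        counts = pd.DataFrame(
            nb_counts(rng, mu, 0.05),
            index=[f"f{i}" for i in range(200)],
            columns=design.samples,
        )
        res = lf.nb_wald_test(counts, design)
        de = (res["p_adjusted"] < 0.05) & (res["log2fc"].abs() >= 1)
        assert de[:20].mean() >= 0.9


class TestBhAdjust:
    def test_single_p_identity(self):
        assert lf.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        got = lf.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lf.bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(lf.bh_adjust(p), expected, atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)
    )
    def test_adjusted_at_least_raw_and_order_free(self, p):
        adj = lf.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()


class TestCallDe:
    def make_results(self, padj, lfc):
        return pd.DataFrame(
            {
                "base_mean": 100.0,
                "log2fc": lfc,
                "se_log2fc": 0.1,
                "wald_stat": 1.0,
                "p_value": padj,
                "p_adjusted": padj,
                "all_zero": False,
            },
            index=[f"f{i}" for i in range(len(padj))],
        )

    def test_boundary_padj_not_de(self):
        res = self.make_results([0.05], [2.0])
        call = lf.call_de(res, {"f0": "lncRNA"})
        assert not call.results["is_de"].iloc[0]

    def test_boundary_lfc_is_de(self):
        res = self.make_results([0.01], [1.0])
        call = lf.call_de(res, {"f0": "lncRNA"})
        assert call.results["is_de"].iloc[0]
        assert call.results["direction"].iloc[0] == "up"
        assert list(call.dels.index) == ["f0"]

    def test_up_down_partition(self, sim_counts, sim_annotation):
        cm, design = sim_counts
        _, _, truth = sim_annotation
        res = lf.nb_wald_test(cm.counts, design)
        call = lf.call_de(res, truth.feature_class)
        for sub in (call.dels, call.degs):
            ups = (sub["direction"] == "up").sum()
            downs = (sub["direction"] == "down").sum()
            assert ups + downs == len(sub)
        assert len(call.dels) + len(call.degs) == call.results["is_de"].sum()

    def test_invariant_to_feature_order(self, sim_counts, sim_annotation):
        cm, design = sim_counts
        _, _, truth = sim_annotation
        res = lf.nb_wald_test(cm.counts, design)
        call = lf.call_de(res, truth.feature_class)
        shuffled = res.sample(frac=1, random_state=0)
        call2 = lf.call_de(shuffled, truth.feature_class)
        assert set(call.dels.index) == set(call2.dels.index)
        assert set(call.degs.index) == set(call2.degs.index)


class TestSampleSimilarity:
    def test_duplicated_sample_distance_zero(self):
        counts, design = null_counts(3, n_features=100)
        counts["B0"] = counts["A0"]
        _, _, dist = lf.sample_similarity(counts)
        assert dist.loc["A0", "B0"] == pytest.approx(0.0)
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0.0)

    def test_variance_fractions_sum_below_one(self):
        counts, _ = null_counts(4, n_features=100)
        _, frac, _ = lf.sample_similarity(counts)
        assert 0 < frac.sum() <= 1.0 + 1e-12

    def test_distance_matches_hand_computation(self):
        counts = pd.DataFrame(
            {"a": [1, 2], "b": [1, 2], "c": [4, 8]},
            index=["f1", "f2"],
        )
        factors = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        _, _, dist = lf.sample_similarity(counts, factors)
        la = np.log2(np.array([1, 2]) + 1)
        lc = np.log2(np.array([4, 8]) + 1)
        assert dist.loc["a", "c"] == pytest.approx(
            np.sqrt(((la - lc) ** 2).sum())
        )


class TestCompareFeatureStructure:
    def test_hand_arithmetic_mean_sem(self):
        txs = [
            make_tx("a", length=100, n_exons=2),
            make_tx("b", length=300, n_exons=2),
            make_tx("c", length=500, n_exons=5),
        ]
        labels = {"a": "lncRNA", "b": "lncRNA", "c": "mRNA"}
        out = lf.compare_feature_structure(txs, labels)
        row = out["summary"].loc["lncRNA"]
        assert row["length_mean"] == pytest.approx(200)
        assert row["length_sem"] == pytest.approx(100)
        mrna = out["summary"].loc["mRNA"]
        assert mrna["length_sem"] == 0.0 and not mrna["sem_defined"]

    def test_single_class_is_an_error(self):
        txs = [make_tx("a"), make_tx("b")]
        with pytest.raises(ValueError, match="both classes"):
            lf.compare_feature_structure(txs, {"a": "lncRNA", "b": "lncRNA"})

    def test_planted_ordering_recovered(self, sim_annotation):
        reference, novel, truth = sim_annotation
        txs = list(reference) + list(novel)
        labels = {t.transcript_id: "mRNA" for t in reference}
        labels.update(
            {
                t.transcript_id: (
                    "lncRNA"
                    if truth.true_class[t.transcript_id] == "lncRNA"
                    else "mRNA"
                )
                for t in novel
            }
        )
        out = lf.compare_feature_structure(txs, labels)
        s = out["summary"]
        assert (
            s.loc["lncRNA", "length_mean"] < s.loc["mRNA", "length_mean"]
        )
        assert (
            s.loc["lncRNA", "exon_number_mean"]
            < s.loc["mRNA", "exon_number_mean"]
        )
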