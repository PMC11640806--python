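"""Synthetic-data generators: planted truth, determinism, NB moments."""

import numpy as np
import pytest

import lncflow as lf
from lncflow.simulate import (
    ConfigurationError,
    GenerationError,
    _coding_sequence,
    _noncoding_sequence,
    nb_counts,
)


class TestSimulationConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigurationError, match="sum to"):
            lf.SimulationConfig(class_code_mix={"u": 0.5, "i": 0.4})

    def test_small_groups_rejected(self):
        with pytest.raises(ConfigurationError, match="n_per_group"):
            lf.SimulationConfig(n_per_group=1)


class TestSimulateAnnotation:
    def test_forced_class_code_mix(self):
        cfg = lf.SimulationConfig(
            seed=1, class_code_mix={"u": 1.0}, n_novel_transcripts=30
        )
        _, novel, _ = lf.simulate_annotation(cfg)
        assert all(t.class_code == "u" for t in novel)

    def test_empty_novel_set(self):
        cfg = lf.SimulationConfig(seed=1, n_novel_transcripts=0)
        _, novel, truth = lf.simulate_annotation(cfg)
        assert novel == [] and truth.true_class == {}

    def test_cis_gap_below_window_by_interval_arithmetic(self):
        # many seeds, every planted cis gap recomputed independently
        for seed in range(30):
            cfg = lf.example_config(seed=seed)
            reference, novel, truth = lf.simulate_annotation(cfg)
            by_id = {t.transcript_id: t for t in novel}
            genes = {t.gene_id: t for t in reference}
            for pair in truth.true_pairs:
                if pair.mode != "cis":
                    continue
                lnc, gene = by_id[pair.lnc_id], genes[pair.gene_id]
                assert lnc.chrom == gene.chrom
                gap = max(
                    lnc.span[0] - gene.span[1] - 1,
                    gene.span[0] - lnc.span[1] - 1,
                    0,
                )
                assert gap < 20_000
                assert truth.cis_distances[(pair.lnc_id, pair.gene_id)] == gap

    def test_trans_pairs_fail_the_cis_window(self, sim_annotation):
        reference, novel, truth = sim_annotation
        by_id = {t.transcript_id: t for t in novel}
        genes = {t.gene_id: t for t in reference}
        for pair in truth.true_pairs:
            if pair.mode == "trans":
                assert by_id[pair.lnc_id].chrom != genes[pair.gene_id].chrom

    def test_survivor_transcripts_pass_structural_filters(self, sim_annotation):
        _, novel, truth = sim_annotation
        planted_ids = {p.lnc_id for p in truth.true_pairs}
        for t in novel:
            if t.transcript_id in planted_ids:
                assert t.length >= 200 and t.exon_count >= 2

    def test_deterministic(self, sim_config):
        a = lf.simulate_annotation(sim_config)
        b = lf.simulate_annotation(sim_config)
        assert [t.transcript_id for t in a[1]] == [
            t.transcript_id for t in b[1]
        ]
        assert [t.exons for t in a[1]] == [t.exons for t in b[1]]


class TestSimulateSequences:
    def test_planted_orf_contrast(self, sim_annotation, sim_sequences):
        _, novel, truth = sim_annotation
        for t in novel:
            orf = lf.find_longest_orf(sim_sequences[t.transcript_id])
            if truth.true_class[t.transcript_id] == "coding":
                assert orf.length_nt >= 300
            else:
                assert orf.length_nt < 300

    def test_sequence_length_matches_exon_chain(self, sim_annotation, sim_sequences):
        _, novel, _ = sim_annotation
        for t in novel:
            assert len(sim_sequences[t.transcript_id]) == t.length

    def test_identical_seeds_identical_output(self, sim_config, sim_annotation):
        _, novel, truth = sim_annotation
        a = lf.simulate_sequences(novel, truth, sim_config)
        b = lf.simulate_sequences(novel, truth, sim_config)
        assert a == b

    def test_orf_longer_than_transcript_is_an_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(GenerationError, match="cannot host"):
            _coding_sequence(rng, 200)

    def test_noncoding_generator_suppresses_long_orfs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = _noncoding_sequence(rng, 2000)
            assert lf.find_longest_orf(seq).length_nt < 300


class TestSimulateCounts:
    def test_null_config_centres_log_ratios_at_zero(self):
        cfg = lf.SimulationConfig(seed=3, n_novel_transcripts=40)
        _, _, truth = lf.simulate_annotation(cfg)
        cm, design = lf.simulate_counts(cfg, truth)
        ref = cm.counts[design.samples_of(design.reference)].mean(axis=1)
        con = cm.counts[design.samples_of(design.contrast)].mean(axis=1)
        ratios = np.log2((con + 0.5) / (ref + 0.5))
        assert abs(ratios.mean()) < 0.05

    def test_nb_moments(self):
        rng = np.random.default_rng(4)
        draws = nb_counts(rng, np.full(10_000, 100.0), 0.05)
        se_mean = np.sqrt((100 + 0.05 * 100**2) / 10_000)
        assert abs(draws.mean() - 100) < 3 * se_mean
        var = draws.var(ddof=1)
        assert 0.7 * 600 < var < 1.3 * 600  # mu + alpha*mu^2 = 600

    def test_zero_dispersion_pair_perfectly_correlated(self):
        cfg = lf.example_config(seed=5, nb_dispersion=0.0)
        _, _, truth = lf.simulate_annotation(cfg)
        cm, design, means = lf.simulate_counts(cfg, truth, return_means=True)
        logm = np.log2(means)
        for pair in truth.true_pairs:
            r = np.corrcoef(logm.loc[pair.lnc_id], logm.loc[pair.gene_id])[0, 1]
            expected = 1.0 if pair.sign == "positive" else -1.0
            assert r == pytest.approx(expected, abs=1e-9)

    def test_counts_are_nonnegative_integers(self, sim_counts):
        cm, _ = sim_counts
        assert (cm.counts.values >= 0).all()
        assert np.issubdtype(cm.counts.values.dtype, np.integer)

    def test_deterministic(self, sim_config, sim_annotation):
        _, _, truth = sim_annotation
        a, _ = lf.simulate_counts(sim_config, truth)
        b, _ = lf.simulate_counts(sim_config, truth)
        assert a.counts.equals(b.counts)


class TestSimulateHitTable:
    def test_planted_no_hit_candidates_absent_or_insignificant(
        self, sim_config, sim_annotation
    ):
        _, novel, truth = sim_annotation
        table = lf.simulate_hit_table(novel, truth, sim_config)
        for tid, group in truth.homology_group.items():
            rows = table[table["qseqid"] == tid]
            if group == 3:
                assert rows.empty or (rows["evalue"] > 1e-5).all()
            elif group == 1:
                sig = rows[rows["evalue"] <= 1e-5]
                assert set(sig["subject_type"]) <= {
                    "protein_coding", "non_lncRNA",
                }
                assert not sig.empty
            else:
                sig = rows[rows["evalue"] <= 1e-5]
                assert (sig["subject_type"] == "lncRNA").all()
                assert not sig.empty

    def test_coding_truth_gets_significant_coding_hit(
        self, sim_config, sim_annotation
    ):
        _, novel, truth = sim_annotation
        table = lf.simulate_hit_table(novel, truth, sim_config)
        coding_ids = [
            t.transcript_id
            for t in novel
            if truth.true_class[t.transcript_id] == "coding"
        ]
        for tid in coding_ids:
            rows = table[
                (table["qseqid"] == tid) & (table["evalue"] <= 1e-5)
            ]
            assert not rows.empty
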