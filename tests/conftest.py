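"""Shared fixtures: simulated datasets and a trained classifier.

Everything is generated programmatically at fixed seeds; the expensive
classifier training is session-scoped so several tests can share it.
"""

from __future__ import annotations

import numpy as np
import pytest

import lncflow as lf


@pytest.fixture(scope="session")
def sim_config() -> lf.SimulationConfig:
    return lf.example_config(seed=11)


@pytest.fixture(scope="session")
def sim_annotation(sim_config):
    reference, novel, truth = lf.simulate_annotation(sim_config)
    return reference, novel, truth


@pytest.fixture(scope="session")
def sim_sequences(sim_config, sim_annotation):
    _, novel, truth = sim_annotation
    return lf.simulate_sequences(novel, truth, sim_config)


@pytest.fixture(scope="session")
def training_corpus(sim_config):
    """Planted separable corpus: 200 coding + 200 noncoding sequences."""
    coding, noncoding = lf.simulate_training_sequences(sim_config)
    return coding, noncoding


@pytest.fixture(scope="session")
def trained_classifier(training_corpus):
    coding, noncoding = training_corpus
    training = lf.build_training_set(coding, noncoding)
    return lf.train_classifier(training, k_folds=10, seed=11)


@pytest.fixture(scope="session")
def sim_counts(sim_config, sim_annotation):
    _, _, truth = sim_annotation
    cm, design = lf.simulate_counts(sim_config, truth)
    return cm, design


def orf_oracle(sequence: str) -> lf.OrfResult:
    """Exhaustive (start, frame) ORF scan used as the independent oracle."""
    seq = sequence.upper()
    n = len(seq)
    stops = {"TAA", "TAG", "TGA"}
    best = lf.OrfResult()
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        length = 0
        has_stop = False
        i = start
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if "N" in codon:
                break
            if codon in stops:
                has_stop = True
                break
            length += 3
            i += 3
        cand = lf.OrfResult(start, length, start % 3, has_stop)
        if cand.length_nt > best.length_nt or (
            cand.length_nt == best.length_nt
            and best.length_nt > 0
            and (cand.start_offset, cand.frame)
            < (best.start_offset, best.frame)
        ):
            best = cand
    return best


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = list("ACGTN" if with_n else "ACGT")
    p = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(alphabet, size=length, p=p))
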