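"""Coding-potential classification of candidate transcripts.

A random-forest classifier separates mRNA from lncRNA on sequence-derived
features: longest-ORF statistics, GC content, a Fickett TESTCODE score,
a hexamer usage log-ratio learned from the training corpus, and k-mer
spectra for k <= 3.  Training sequences are deduplicated first (identical
nucleotide sequences bias cross-validation), trained with stratified
10-fold cross-validation, and the final model is refit on the full
training set.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold

from .triage import find_longest_orf

__all__ = [
    "LabeledSequenceSet",
    "HexamerTable",
    "FEATURE_NAMES",
    "TrainedClassifier",
    "build_training_set",
    "extract_features",
    "fickett_score",
    "train_classifier",
    "predict",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_KMERS = {
    k: ["".join(p) for p in product(_BASES, repeat=k)] for k in (1, 2, 3)
}

#: Fixed feature order used by the classifier.
FEATURE_NAMES: tuple[str, ...] = (
    "orf_length_nt",
    "orf_coverage",
    "gc_fraction",
    "fickett_score",
    "hexamer_bias",
    *(f"freq1_{m}" for m in _KMERS[1]),
    *(f"freq2_{m}" for m in _KMERS[2]),
    *(f"freq3_{m}" for m in _KMERS[3]),
)

# Classic Fickett TESTCODE lookup tables: probability that a sequence with
# the given position-asymmetry / composition value is coding, and the
# weight of each parameter (Fickett 1982 constants).
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_EDGES = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


@dataclass(frozen=True)
class LabeledSequenceSet:
    """Deduplicated training sequences with coding/noncoding labels."""

    records: tuple[tuple[str, str, str], ...]  # (id, sequence, label)
    provenance: str = ""

    def __post_init__(self) -> None:
        seqs = [seq for _, seq, _ in self.records]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate sequences in LabeledSequenceSet")
        bad = {lab for _, _, lab in self.records} - {"coding", "noncoding"}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    def by_label(self, label: str) -> list[tuple[str, str]]:
        return [(i, s) for i, s, lab in self.records if lab == label]


def build_training_set(
    coding_seqs: Iterable[tuple[str, str]],
    noncoding_seqs: Iterable[tuple[str, str]],
    provenance: str = "",
) -> LabeledSequenceSet:
    """Deduplicate and merge labeled sequences into a training set.

    Exact duplicate sequences within a class collapse to the first record;
    a sequence appearing under both labels is contradictory and removed
    entirely (logged).  Raises if either class is empty afterwards.
    """
    coding = dict()
    for sid, seq in coding_seqs:
        coding.setdefault(seq.upper(), sid)
    noncoding = dict()
    for sid, seq in noncoding_seqs:
        noncoding.setdefault(seq.upper(), sid)
    if not coding or not noncoding:
        raise ValueError("both classes must be non-empty")
    conflicts = set(coding) & set(noncoding)
    for seq in conflicts:
        logger.warning(
            "sequence labeled both coding (%s) and noncoding (%s); removed",
            coding[seq],
            noncoding[seq],
        )
    records = [
        (sid, seq, "coding")
        for seq, sid in coding.items()
        if seq not in conflicts
    ] + [
        (sid, seq, "noncoding")
        for seq, sid in noncoding.items()
        if seq not in conflicts
    ]
    labels = {lab for _, _, lab in records}
    if labels != {"coding", "noncoding"}:
        raise ValueError("a class became empty after deduplication")
    return LabeledSequenceSet(tuple(records), provenance)


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic (higher suggests protein-coding).

    Combines the base-position asymmetry across the three codon positions
    with overall base composition through the classic lookup tables.
    """
    seq = sequence.upper()
    n = len(seq)
    if n == 0:
        return 0.0
    score = 0.0
    for base in _BASES:
        pos_counts = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == base:
                pos_counts[i % 3] += 1
        position_value = max(pos_counts) / (min(pos_counts) + 1)
        content_value = sum(pos_counts) / n
        for idx, edge in enumerate(_POSITION_EDGES):
            if position_value >= edge:
                score += _POSITION_PROB[base][idx] * _POSITION_WEIGHT[base]
                break
        for idx, edge in enumerate(_CONTENT_EDGES):
            if content_value >= edge:
                score += _CONTENT_PROB[base][idx] * _CONTENT_WEIGHT[base]
                break
    return score


class HexamerTable:
    """Hexamer log-ratio table estimated from a labeled training corpus.

    Frequencies use add-one smoothing over all 4096 hexamers; the per-
    sequence score is the mean log(coding frequency / noncoding frequency)
    over the sequence's overlapping hexamers.
    """

    def __init__(self, log_ratio: dict[str, float]):
        self.log_ratio = log_ratio

    @classmethod
    def fit(cls, training: LabeledSequenceSet) -> "HexamerTable":
        counts = {
            "coding": np.ones(4096),
            "noncoding": np.ones(4096),
        }
        index = {
            "".join(p): i
            for i, p in enumerate(product(_BASES, repeat=6))
        }
        for _, seq, label in training.records:
            c = counts[label]
            s = seq.upper()
            for i in range(len(s) - 5):
                idx = index.get(s[i : i + 6])
                if idx is not None:
                    c[idx] += 1
        ratio = np.log(counts["coding"] / counts["coding"].sum()) - np.log(
            counts["noncoding"] / counts["noncoding"].sum()
        )
        kmers = ["".join(p) for p in product(_BASES, repeat=6)]
        return cls(dict(zip(kmers, ratio)))

    def score(self, sequence: str) -> float:
        s = sequence.upper()
        vals = [
            self.log_ratio[s[i : i + 6]]
            for i in range(len(s) - 5)
            if s[i : i + 6] in self.log_ratio
        ]
        return float(np.mean(vals)) if vals else 0.0


def _kmer_freqs(seq: str, k: int) -> np.ndarray:
    counts = np.zeros(4**k)
    index = {m: i for i, m in enumerate(_KMERS[k])}
    for i in range(len(seq) - k + 1):
        idx = index.get(seq[i : i + k])
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no valid k-mers (all N?)")
    return counts / total


def extract_features(
    sequence: str, hexamer_table: HexamerTable | None = None
) -> np.ndarray:
    """Deterministic feature vector for one sequence (order = FEATURE_NAMES)."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) <= {"N"}:
        raise ValueError("all-N sequence")
    orf = find_longest_orf(seq)
    f1 = _kmer_freqs(seq, 1)
    gc = f1[1] + f1[2]  # C + G
    vec = [
        float(orf.length_nt),
        orf.length_nt / len(seq),
        float(gc),
        fickett_score(seq),
        hexamer_table.score(seq) if hexamer_table is not None else 0.0,
    ]
    vec.extend(f1)
    vec.extend(_kmer_freqs(seq, 2))
    vec.extend(_kmer_freqs(seq, 3))
    return np.asarray(vec, dtype=float)


@dataclass
class TrainedClassifier:
    """Fitted random-forest model plus its CV metrics and feature contract."""

    model: RandomForestClassifier
    hexamer_table: HexamerTable
    feature_names: tuple[str, ...]
    cv_metrics: list[dict[str, float]] = field(default_factory=list)
    heldout_metrics: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    best_params: dict = field(default_factory=dict)

    @property
    def mean_cv(self) -> dict[str, float]:
        keys = self.cv_metrics[0].keys() if self.cv_metrics else ()
        return {
            k: float(np.mean([m[k] for m in self.cv_metrics])) for k in keys
        }


def _feature_matrix(
    seqs: Sequence[str], table: HexamerTable
) -> np.ndarray:
    return np.vstack([extract_features(s, table) for s in seqs])


def train_classifier(
    training: LabeledSequenceSet,
    k_folds: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
    depth_grid: Sequence[int | None] = (None, 10, 20),
) -> TrainedClassifier:
    """Train the random forest with stratified k-fold cross-validation.

    Tree depth is tuned over ``depth_grid`` by mean CV F1-like score
    (precision·recall balance of the noncoding class); the reported
    ``cv_metrics`` are the per-fold precision/recall/accuracy of the best
    depth, and the final model is refit on the full training set.
    Identical seed implies identical metrics and model.
    """
    labels = np.array([lab for _, _, lab in training.records])
    classes = set(labels)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < k_folds:
        raise ValueError(
            f"need >= {k_folds} records per class, have {counts}"
        )
    seqs = [s for _, s, _ in training.records]
    # the hexamer table is label-derived, so it must be re-estimated inside
    # each fold from that fold's training records only; otherwise the
    # hexamer_bias feature leaks held-out sequences into the CV metrics
    table = HexamerTable.fit(training)
    X = _feature_matrix(seqs, table)
    hex_col = FEATURE_NAMES.index("hexamer_bias")
    y = (labels == "noncoding").astype(int)  # positive class = noncoding

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_hex: list[np.ndarray] = []
    for tr, _ in folds:
        sub = LabeledSequenceSet(
            tuple(training.records[i] for i in tr), training.provenance
        )
        fold_table = HexamerTable.fit(sub)
        fold_hex.append(np.array([fold_table.score(s) for s in seqs]))

    def fold_metrics(depth) -> list[dict[str, float]]:
        out = []
        for i, (tr, te) in enumerate(folds):
            Xf = X.copy()
            Xf[:, hex_col] = fold_hex[i]
            rf = RandomForestClassifier(
                n_estimators=n_estimators,
                max_features="sqrt",
                max_depth=depth,
                random_state=seed + i,
                n_jobs=1,
            )
            rf.fit(Xf[tr], y[tr])
            pred = rf.predict(Xf[te])
            out.append(
                {
                    "precision": precision_score(y[te], pred, zero_division=0),
                    "recall": recall_score(y[te], pred, zero_division=0),
                    "accuracy": accuracy_score(y[te], pred),
                }
            )
        return out

    best_depth, best_metrics, best_score = None, None, -1.0
    for depth in depth_grid:
        metrics = fold_metrics(depth)
        score = float(
            np.mean([m["precision"] + m["recall"] for m in metrics])
        )
        if score > best_score:
            best_depth, best_metrics, best_score = depth, metrics, score

    final = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        max_depth=best_depth,
        random_state=seed,
        n_jobs=1,
    )
    final.fit(X, y)
    return TrainedClassifier(
        model=final,
        hexamer_table=table,
        feature_names=FEATURE_NAMES,
        cv_metrics=best_metrics,
        heldout_metrics={},
        seed=seed,
        best_params={"max_depth": best_depth, "n_estimators": n_estimators},
    )


def predict(
    classifier: TrainedClassifier,
    candidates: Sequence[tuple[str, str]],
) -> tuple[list[tuple[str, str, float]], list[str]]:
    """Label candidate (id, sequence) pairs as coding or noncoding.

    Returns ``(per_candidate, lncRNA_ids)`` where ``per_candidate`` rows are
    (id, label, probability-of-noncoding) and ``lncRNA_ids`` keeps only the
    noncoding-predicted candidates (mRNA-predicted ones are removed).
    """
    if not candidates:
        return [], []
    X = _feature_matrix(
        [seq for _, seq in candidates], classifier.hexamer_table
    )
    if X.shape[1] != len(classifier.feature_names):
        raise ValueError("feature-order mismatch between model and input")
    proba = classifier.model.predict_proba(X)
    # column for class 1 = noncoding
    col = list(classifier.model.classes_).index(1)
    p_nc = proba[:, col]
    rows = []
    lnc_ids = []
    for (cid, _), p in zip(candidates, p_nc):
        label = "noncoding" if p >= 0.5 else "coding"
        rows.append((cid, label, float(p)))
        if label == "noncoding":
            lnc_ids.append(cid)
    return rows, lnc_ids
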