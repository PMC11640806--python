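"""Negative-binomial differential expression between two treatment groups.

The engine follows the standard bulk RNA-seq recipe: per-sample size
factors by the median-of-ratios estimator, per-feature NB dispersion by
method-of-moments shrunk toward a fitted mean-dispersion trend
``alpha(mu) = a0 + a1/mu``, a Wald test on the log2 fold change between the
two groups, and Benjamini-Hochberg adjustment.  Features are called
differentially expressed at adjusted p < 0.05 (strict) and |log2FC| >= 1
(non-strict), and split by feature class into differentially expressed
lncRNAs (DELs) and genes (DEGs).

Sample-similarity summaries (PCA on log-normalized counts, Euclidean
distance matrix) and lncRNA-vs-mRNA structural comparisons live here too.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .triage import TranscriptModel

__all__ = [
    "CountMatrix",
    "Design",
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "call_de",
    "DECall",
    "sample_similarity",
    "compare_feature_structure",
    "log_normalize",
]

_LN2 = np.log(2.0)

#: dispersion floor; method-of-moments estimates below this are clipped up
MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0


@dataclass(frozen=True)
class Design:
    """Two-group sample design: sample -> group, with the contrast direction.

    ``log2fc`` downstream is contrast over reference, so a positive value
    means the feature is upregulated in the contrast group.
    """

    groups: Mapping[str, str]
    reference: str
    contrast: str

    def __post_init__(self) -> None:
        seen = set(self.groups.values())
        if seen != {self.reference, self.contrast}:
            raise ValueError(
                f"design groups {sorted(seen)} do not match "
                f"reference={self.reference!r}, contrast={self.contrast!r}"
            )
        for g in (self.reference, self.contrast):
            n = sum(1 for v in self.groups.values() if v == g)
            if n < 2:
                raise ValueError(f"group {g!r} has {n} samples; need >= 2")

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def samples(self) -> list[str]:
        return list(self.groups)


@dataclass
class CountMatrix:
    """Non-negative integer counts (features x samples) with feature classes."""

    counts: pd.DataFrame
    feature_class: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")


def _counts_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors, one positive real per sample.

    For each feature with all-positive counts the per-sample ratio to the
    feature's geometric mean is formed; the factor is the per-sample median
    of those ratios.
    """
    df = _counts_frame(counts)
    positive = df[(df > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no feature has positive counts in every sample; "
            "filter low-count features first"
        )
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def log_normalize(counts, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1), the expression scale used downstream."""
    df = _counts_frame(counts)
    if factors is None:
        factors = size_factors(df)
    return np.log2(df.div(factors, axis=1) + 1.0)


def estimate_dispersions(
    norm: pd.DataFrame, design: Design, shrink: float = 0.5
) -> pd.Series:
    """Per-feature NB dispersion on normalized counts.

    Method-of-moments within groups (pooled residual variance), floored at
    ``MIN_DISPERSION``, then shrunk toward the least-squares trend
    ``alpha(mu) = a0 + a1/mu`` fitted across features: the returned value is
    ``(1-shrink)*raw + shrink*trend``.
    """
    ref = norm[design.samples_of(design.reference)].to_numpy()
    con = norm[design.samples_of(design.contrast)].to_numpy()
    n_r, n_c = ref.shape[1], con.shape[1]
    mu_r = ref.mean(axis=1)
    mu_c = con.mean(axis=1)
    ss = ((ref - mu_r[:, None]) ** 2).sum(axis=1) + (
        (con - mu_c[:, None]) ** 2
    ).sum(axis=1)
    var_pooled = ss / max(n_r + n_c - 2, 1)
    mu = (mu_r + mu_c) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var_pooled - mu) / mu**2
    raw = np.where(np.isfinite(raw), raw, MIN_DISPERSION)
    raw = np.clip(raw, MIN_DISPERSION, MAX_DISPERSION)

    # trend alpha(mu) = a0 + a1/mu, least squares on informative features
    ok = mu > 0
    if ok.sum() >= 2:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-12), raw)
        trend = np.clip(trend, MIN_DISPERSION, MAX_DISPERSION)
    else:
        trend = raw
    alpha = (1.0 - shrink) * raw + shrink * trend
    return pd.Series(
        np.clip(alpha, MIN_DISPERSION, MAX_DISPERSION),
        index=norm.index,
        name="dispersion",
    )


def nb_wald_test(
    counts,
    design: Design,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature NB Wald test of contrast vs reference.

    The log2 fold change is the ratio of normalized group means with a
    pseudo-count added to both means (shrinking fold changes of
    zero-count groups toward 0).  Its standard error comes from the delta
    method with NB variance ``mu/s_i + alpha*mu^2`` per normalized
    observation; the Wald statistic is referred to a normal distribution.
    All-zero features are flagged and given p = 1, log2FC = 0.

    Returns a DataFrame with columns base_mean, log2fc, se_log2fc,
    wald_stat, p_value, p_adjusted, all_zero.
    """
    df = _counts_frame(counts)
    missing = [s for s in design.samples if s not in df.columns]
    if missing:
        raise ValueError(f"samples missing from counts: {missing}")
    if factors is None:
        factors = size_factors(df)
    norm = df.div(factors, axis=1)
    ref_samples = design.samples_of(design.reference)
    con_samples = design.samples_of(design.contrast)
    ref = norm[ref_samples].to_numpy(dtype=float)
    con = norm[con_samples].to_numpy(dtype=float)
    s_ref = factors[ref_samples].to_numpy(dtype=float)
    s_con = factors[con_samples].to_numpy(dtype=float)

    mu_r = ref.mean(axis=1)
    mu_c = con.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()
    all_zero = (df[design.samples].sum(axis=1) == 0).to_numpy()

    alpha = estimate_dispersions(norm, design).to_numpy()

    mu_r_p = mu_r + pseudocount
    mu_c_p = mu_c + pseudocount
    log2fc = np.log2(mu_c_p / mu_r_p)

    # Var of a normalized group mean via the NB variance of each sample's
    # normalized count, evaluated at the pseudo-counted group mean.
    def var_mean(mu_p: np.ndarray, s: np.ndarray) -> np.ndarray:
        per_sample = mu_p[:, None] / s[None, :] + alpha[:, None] * (
            mu_p[:, None] ** 2
        )
        return per_sample.sum(axis=1) / (len(s) ** 2)

    var_log2_r = var_mean(mu_r_p, s_ref) / (mu_r_p**2 * _LN2**2)
    var_log2_c = var_mean(mu_c_p, s_con) / (mu_c_p**2 * _LN2**2)
    se = np.sqrt(var_log2_r + var_log2_c)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))

    log2fc = np.where(all_zero, 0.0, log2fc)
    wald = np.where(all_zero, 0.0, wald)
    p = np.where(all_zero, 1.0, p)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "wald_stat": wald,
            "p_value": p,
            "all_zero": all_zero,
        },
        index=df.index,
    )
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted
    p-values, mapped back to the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class DECall:
    """DE-called results split by feature class."""

    results: pd.DataFrame
    dels: pd.DataFrame  # differentially expressed lncRNAs
    degs: pd.DataFrame  # differentially expressed genes (mRNA)


def call_de(
    results: pd.DataFrame,
    feature_class: Mapping[str, str],
    padj_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> DECall:
    """Call DE at adjusted p < ``padj_max`` (strict) and |log2FC| >= threshold.

    Adds ``is_de``, ``direction`` (up/down in the contrast group) and
    ``feature_class`` columns, and returns the DE subsets per class
    (DELs = lncRNA, DEGs = mRNA).
    """
    res = results.copy()
    res["feature_class"] = [
        feature_class.get(f, "mRNA") for f in res.index
    ]
    res["is_de"] = (res["p_adjusted"] < padj_max) & (
        res["log2fc"].abs() >= min_abs_log2fc
    )
    res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
    de = res[res["is_de"]]
    return DECall(
        results=res,
        dels=de[de["feature_class"] == "lncRNA"],
        degs=de[de["feature_class"] == "mRNA"],
    )


def sample_similarity(
    counts, factors: pd.Series | None = None, n_components: int = 2
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """PCA coordinates and Euclidean distance matrix between samples.

    Both are computed on log2(normalized count + 1).  Returns
    ``(coordinates, explained_variance_fraction, distance_matrix)``; the
    PCA uses the SVD of the column-centered sample x feature matrix.
    """
    norm = log_normalize(counts, factors)
    X = norm.to_numpy().T  # samples x features
    if X.shape[0] < 3:
        raise ValueError("need >= 3 samples for a PCA summary")
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    coords = pd.DataFrame(
        U[:, :k] * S[:k],
        index=norm.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    total = (S**2).sum()
    frac = pd.Series(
        (S[:k] ** 2) / total if total > 0 else np.zeros(k),
        index=coords.columns,
        name="variance_fraction",
    )
    dist = pd.DataFrame(
        squareform(pdist(X)), index=norm.columns, columns=norm.columns
    )
    return coords, frac, dist


#: length bins (nt) and exon-count bins used in the structural comparison
LENGTH_BINS = ((0, 1500), (1500, 3000), (3000, np.inf))
EXON_BINS = ((2, 3), (4, 10), (11, np.inf))


def compare_feature_structure(
    transcripts: Sequence[TranscriptModel],
    labels: Mapping[str, str],
) -> dict[str, pd.DataFrame]:
    """Per-class structural summaries: lncRNA vs mRNA architecture.

    Returns a dict with a ``summary`` table (per class: n, mean and SEM of
    transcript length, mean exon length and exon number; SEM is reported
    as 0 with ``sem_defined=False`` for singleton classes) and binned
    ``length_hist`` / ``exon_hist`` tables.
    """
    rows: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        cls = labels.get(t.transcript_id)
        if cls is not None:
            rows.setdefault(cls, []).append(t)
    if len(rows) < 2:
        raise ValueError(
            f"need both classes non-empty, found {sorted(rows)}"
        )

    def mean_sem(values: list[float]) -> tuple[float, float, bool]:
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            return float(arr.mean()), 0.0, False
        return (
            float(arr.mean()),
            float(arr.std(ddof=1) / np.sqrt(arr.size)),
            True,
        )

    summary_rows = []
    length_hist = []
    exon_hist = []
    for cls, ts in sorted(rows.items()):
        lengths = [float(t.length) for t in ts]
        exon_lens = [
            float(np.mean([e - s + 1 for s, e in t.exons])) for t in ts
        ]
        exon_ns = [float(t.exon_count) for t in ts]
        lm, ls, ld = mean_sem(lengths)
        em, es, _ = mean_sem(exon_lens)
        nm, ns, _ = mean_sem(exon_ns)
        summary_rows.append(
            {
                "class": cls,
                "n": len(ts),
                "length_mean": lm,
                "length_sem": ls,
                "exon_length_mean": em,
                "exon_length_sem": es,
                "exon_number_mean": nm,
                "exon_number_sem": ns,
                "sem_defined": ld,
            }
        )
        for lo, hi in LENGTH_BINS:
            label = (
                f"<{hi:g}" if lo == 0 else (f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}")
            )
            k = sum(1 for v in lengths if lo <= v < hi)
            length_hist.append({"class": cls, "bin": label, "count": k})
        for lo, hi in EXON_BINS:
            label = f">{lo - 1:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}"
            k = sum(1 for v in exon_ns if lo <= v <= hi)
            exon_hist.append({"class": cls, "bin": label, "count": k})

    return {
        "summary": pd.DataFrame(summary_rows).set_index("class"),
        "length_hist": pd.DataFrame(length_hist),
        "exon_hist": pd.DataFrame(exon_hist),
    }
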