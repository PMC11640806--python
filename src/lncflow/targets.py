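"""Cis/trans target-gene inference for differentially expressed lncRNAs.

Candidate regulatory pairs (DEL, DEG) are screened by co-expression:
Pearson correlation of the log-normalized expression profiles across all
samples (both groups pooled), retained at |r| >= 0.90 and p below a
configurable threshold (default 0.01).  Retained pairs are then assigned
a mode: *cis* when the two loci sit on the same chromosome with a span
gap below 20 kb (strict), *trans* otherwise.  A DEL appearing in at least
one cis and one trans pair acts in both capacities (dual mode).
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .triage import TranscriptModel

__all__ = [
    "RegulatoryPair",
    "NetworkSummary",
    "pearson_with_p",
    "infer_trans_targets",
    "genomic_distance",
    "assign_cis",
    "summarize_network",
]


@dataclass(frozen=True)
class RegulatoryPair:
    """One (DEL, DEG) co-expression pair with mode and genomic distance.

    ``distance_bp`` is None when the loci are on different chromosomes.
    """

    del_id: str
    deg_id: str
    r: float
    p_value: float
    sign: str  # positive | negative
    mode: str  # cis | trans
    distance_bp: int | None = None

    @property
    def r_squared(self) -> float:
        return self.r * self.r

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"r out of range: {self.r}")
        if self.sign != ("positive" if self.r > 0 else "negative"):
            raise ValueError("sign inconsistent with r")
        if self.mode not in {"cis", "trans"}:
            raise ValueError(f"unknown mode {self.mode!r}")


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value from the t distribution.

    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; |r| = 1 gives
    p = 0 exactly.  Zero-variance input raises ValueError (callers skip
    such pairs).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = xa.size
    if n != ya.size or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance vector; correlation undefined")
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def infer_trans_targets(
    del_expr: pd.DataFrame,
    deg_expr: pd.DataFrame,
    min_abs_r: float = 0.90,
    p_max: float = 0.01,
) -> list[RegulatoryPair]:
    """Screen all DEL x DEG pairs by correlation on shared samples.

    Both matrices are features x samples on the log-normalized scale and
    must share an identical sample set.  Pairs are retained at
    |r| >= ``min_abs_r`` and p < ``p_max``; zero-variance features are
    skipped with a warning.  All retained pairs start as mode "trans";
    :func:`assign_cis` may later reassign genomically proximal ones.
    """
    if set(del_expr.columns) != set(deg_expr.columns):
        raise ValueError("DEL and DEG matrices must share the sample set")
    deg_expr = deg_expr[del_expr.columns]
    pairs: list[RegulatoryPair] = []
    for del_id, x in del_expr.iterrows():
        for deg_id, y in deg_expr.iterrows():
            try:
                r, p = pearson_with_p(x.to_numpy(), y.to_numpy())
            except ValueError:
                warnings.warn(
                    f"zero-variance profile in pair ({del_id}, {deg_id}); "
                    "skipped",
                    stacklevel=2,
                )
                continue
            if abs(r) >= min_abs_r and p < p_max:
                pairs.append(
                    RegulatoryPair(
                        del_id=str(del_id),
                        deg_id=str(deg_id),
                        r=r,
                        p_value=p,
                        sign="positive" if r > 0 else "negative",
                        mode="trans",
                    )
                )
    return pairs


def genomic_distance(
    a: TranscriptModel, b: TranscriptModel
) -> int | None:
    """Gap in bp between two transcript spans; 0 if they overlap.

    Spans run from the first exon start to the last exon end; strand is
    ignored.  Returns None when the transcripts sit on different
    chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    a_start, a_end = a.span
    b_start, b_end = b.span
    if a_start > b_end:
        return a_start - b_end - 1
    if b_start > a_end:
        return b_start - a_end - 1
    return 0


def assign_cis(
    pairs: Sequence[RegulatoryPair],
    annotation: Mapping[str, TranscriptModel],
    max_distance_bp: int = 20_000,
) -> list[RegulatoryPair]:
    """Reassign pair modes by genomic proximity.

    mode = cis iff same chromosome and span gap < ``max_distance_bp``
    (strict); every other pair is trans.  ``annotation`` maps each pair
    member id to its transcript model.
    """
    out = []
    for pair in pairs:
        for fid in (pair.del_id, pair.deg_id):
            if fid not in annotation:
                raise KeyError(f"feature {fid!r} missing from annotation")
        d = genomic_distance(annotation[pair.del_id], annotation[pair.deg_id])
        mode = "cis" if (d is not None and d < max_distance_bp) else "trans"
        out.append(replace(pair, mode=mode, distance_bp=d))
    return out


@dataclass(frozen=True)
class NetworkSummary:
    """Tallies over the final regulatory-pair set."""

    n_pairs: int
    n_positive: int
    n_negative: int
    n_cis: int
    n_trans: int
    dual_mode_del_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_cis": self.n_cis,
            "n_trans": self.n_trans,
            "dual_mode_del_ids": list(self.dual_mode_del_ids),
        }


def summarize_network(pairs: Sequence[RegulatoryPair]) -> NetworkSummary:
    """Count signs and modes, and find DELs acting in both cis and trans."""
    cis_dels = {p.del_id for p in pairs if p.mode == "cis"}
    trans_dels = {p.del_id for p in pairs if p.mode == "trans"}
    return NetworkSummary(
        n_pairs=len(pairs),
        n_positive=sum(1 for p in pairs if p.sign == "positive"),
        n_negative=sum(1 for p in pairs if p.sign == "negative"),
        n_cis=sum(1 for p in pairs if p.mode == "cis"),
        n_trans=sum(1 for p in pairs if p.mode == "trans"),
        dual_mode_del_ids=tuple(sorted(cis_dels & trans_dels)),
    )


def pairs_to_frame(pairs: Sequence[RegulatoryPair]) -> pd.DataFrame:
    """Tabular view of a pair list (one row per pair)."""
    return pd.DataFrame(
        [
            {
                "del_id": p.del_id,
                "deg_id": p.deg_id,
                "r": p.r,
                "r_squared": p.r_squared,
                "p_value": p.p_value,
                "sign": p.sign,
                "mode": p.mode,
                "distance_bp": p.distance_bp,
            }
            for p in pairs
        ],
        columns=[
            "del_id",
            "deg_id",
            "r",
            "r_squared",
            "p_value",
            "sign",
            "mode",
            "distance_bp",
        ],
    )
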