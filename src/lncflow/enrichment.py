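"""Hypergeometric over-representation analysis against a supplied term map.

Functional enrichment of a query gene set (e.g. the DEG targets of the
differentially expressed lncRNAs) is tested per term with the exact
upper-tail hypergeometric probability P(X >= k), Benjamini-Hochberg
adjusted across tested terms, and called enriched at adjusted p <= 0.05
(non-strict).  The gene -> term annotation map is an input file; no live
GO/KEGG download is involved.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import bh_adjust

__all__ = ["Term", "TermMap", "hypergeometric_p", "enrich"]

NAMESPACES = frozenset({"BP", "CC", "MF", "pathway"})


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    namespace: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(
                f"{self.term_id}: unknown namespace {self.namespace!r}"
            )
        if not self.genes:
            raise ValueError(f"{self.term_id}: empty gene set")


@dataclass(frozen=True)
class TermMap:
    """term id -> Term, plus the annotation universe (all mapped genes)."""

    terms: Mapping[str, Term]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        stray = set().union(*(t.genes for t in self.terms.values())) - set(
            self.universe
        ) if self.terms else set()
        if stray:
            raise ValueError(
                f"{len(stray)} annotated genes missing from universe"
            )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, str]]
    ) -> "TermMap":
        """Build from (gene, term_id, term_name, namespace) rows."""
        genes: dict[str, set[str]] = {}
        meta: dict[str, tuple[str, str]] = {}
        universe: set[str] = set()
        for gene, term_id, name, namespace in records:
            genes.setdefault(term_id, set()).add(gene)
            meta.setdefault(term_id, (name, namespace))
            universe.add(gene)
        terms = {
            tid: Term(tid, meta[tid][0], meta[tid][1], frozenset(gs))
            for tid, gs in genes.items()
        }
        return cls(terms, frozenset(universe))


def _log_comb(n, k) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeom(N, K, n).

    N is the universe size, K the term size, n the query size, k the
    overlap.  Computed as a log-space sum of hypergeometric point masses
    for numerical stability; k = 0 returns exactly 1.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"infeasible tuple (k={k}, K={K}, n={n}, N={N})")
    if k == 0:
        return 1.0
    x = np.arange(k, min(K, n) + 1)
    # feasibility of the lower tail of the other category: n - x <= N - K
    x = x[(n - x) <= (N - K)]
    if x.size == 0:
        return 0.0
    log_pmf = (
        _log_comb(K, x) + _log_comb(N - K, n - x) - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def enrich(
    query: Iterable[str],
    term_map: TermMap,
    padj_max: float = 0.05,
    min_term_size: int = 3,
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Over-representation of ``query`` genes in each term of the map.

    The universe defaults to the term map's annotated genes; passing
    ``universe`` (e.g. the expressed gene set) intersects it with the map.
    Query genes outside the universe are dropped with a warning.  One
    hypergeometric test per term with >= ``min_term_size`` genes in the
    universe; BH across tested terms; enriched iff adjusted p <=
    ``padj_max`` (non-strict).  Rows sorted by (p_adjusted, term_id).
    """
    uni = set(term_map.universe)
    if universe is not None:
        uni &= set(universe)
    q_all = set(query)
    q = q_all & uni
    if q_all - uni:
        warnings.warn(
            f"{len(q_all - uni)} query genes outside the universe dropped",
            stacklevel=2,
        )
    if not q:
        raise ValueError("no query genes remain within the universe")

    N = len(uni)
    n = len(q)
    rows = []
    for tid in sorted(term_map.terms):
        term = term_map.terms[tid]
        genes = term.genes & uni
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(q & genes)
        rows.append(
            {
                "term_id": tid,
                "name": term.name,
                "namespace": term.namespace,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeometric_p(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "name", "namespace", "k", "K", "n", "N",
                "p_value", "p_adjusted", "enriched",
            ]
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = out["p_adjusted"] <= padj_max
    return out.sort_values(
        ["p_adjusted", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
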