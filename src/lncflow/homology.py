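"""Homology triage of predicted lncRNA candidates.

Candidates are compared against a pre-computed nucleotide homology search
(BLASTn tabular output with an added subject-type column) and split into
three groups:

1. significant match to a protein-coding gene or another non-lncRNA
   transcript — excluded from further analysis;
2. significant match to a known lncRNA — retained (known lncRNA);
3. no significant match — retained (putative novel lncRNA).

A hit is significant when its E-value is at or below the threshold
(default 1e-5).  When one candidate has significant hits of several
subject types, the coding/non-lncRNA evidence dominates (conservative
exclusion), then lncRNA evidence.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

__all__ = ["HitRecord", "HomologyGroups", "classify_by_homology"]

SUBJECT_TYPES = frozenset({"protein_coding", "non_lncRNA", "lncRNA"})
_EXCLUDING_TYPES = frozenset({"protein_coding", "non_lncRNA"})


@dataclass(frozen=True)
class HitRecord:
    """One homology hit (BLAST outfmt-6 row plus a subject-type label)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    subject_type: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value on hit for {self.query_id}")
        if self.subject_type not in SUBJECT_TYPES:
            raise ValueError(
                f"unknown subject_type {self.subject_type!r} "
                f"(expected one of {sorted(SUBJECT_TYPES)})"
            )


@dataclass
class HomologyGroups:
    """Partition of candidate ids by homology evidence."""

    group1_excluded: list[str] = field(default_factory=list)
    group2_known_lncrna: list[str] = field(default_factory=list)
    group3_no_match: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        """Groups 2 and 3 continue downstream as novel lncRNAs."""
        return self.group2_known_lncrna + self.group3_no_match

    def group_of(self, candidate_id: str) -> int:
        if candidate_id in set(self.group1_excluded):
            return 1
        if candidate_id in set(self.group2_known_lncrna):
            return 2
        return 3


def classify_by_homology(
    candidates: Sequence[str],
    hits: Iterable[HitRecord],
    evalue_max: float = 1e-5,
) -> HomologyGroups:
    """Partition candidate ids into the three homology groups.

    Hits whose query is not among the candidates are warned about and
    ignored.  The three groups always partition the candidate set.
    """
    cand_set = set(candidates)
    significant: dict[str, set[str]] = {}
    for h in hits:
        if h.query_id not in cand_set:
            warnings.warn(
                f"hit query {h.query_id!r} is not a candidate; ignored",
                stacklevel=2,
            )
            continue
        if h.evalue <= evalue_max:
            significant.setdefault(h.query_id, set()).add(h.subject_type)

    groups = HomologyGroups()
    for cid in candidates:
        types = significant.get(cid, set())
        if types & _EXCLUDING_TYPES:
            groups.group1_excluded.append(cid)
        elif "lncRNA" in types:
            groups.group2_known_lncrna.append(cid)
        else:
            groups.group3_no_match.append(cid)
    return groups
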