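"""Candidate-lncRNA triage from assembled transcripts.

Assembled transcripts (e.g. a StringTie assembly compared against a
reference annotation with gffcompare) are funnelled through three filters:

1. class-code retention — keep transcripts whose relation to the reference
   annotation is one of the "novel-compatible" gffcompare codes
   (default ``{x, o, i, u, j}``);
2. structural filter — drop short (< 200 nt) or mono-exonic transcripts,
   which are enriched for assembly artifacts;
3. coding filter — drop transcripts whose longest open reading frame is
   long enough (>= 300 nt, i.e. 100 aa) to suggest protein-coding capacity.

The result is a set of candidate lncRNA transcripts for downstream
coding-potential classification and homology triage.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

__all__ = [
    "TranscriptModel",
    "OrfResult",
    "TriageReport",
    "DEFAULT_CLASS_CODES",
    "filter_by_class_code",
    "filter_by_structure",
    "find_longest_orf",
    "filter_by_orf",
    "run_triage",
]

#: gffcompare class codes retained as potential novel lncRNAs:
#: x (exonic antisense), o (other-strand overlap), i (intronic),
#: u (intergenic), j (novel isoform).
DEFAULT_CLASS_CODES = frozenset("xoiuj")

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class TranscriptModel:
    """One assembled transcript: coordinates, exon chain, class code.

    Exons are 1-based closed intervals (GTF convention), sorted by start
    and pairwise non-overlapping.  ``sequence``, when present, is the
    spliced transcript sequence and must match the exon-chain length.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = ()
    class_code: str = "."
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end < start:
                raise ValueError(
                    f"{self.transcript_id}: exon end {end} < start {start}"
                )
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = end
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= exon-chain length {self.length}"
            )

    @property
    def length(self) -> int:
        """Spliced transcript length in nt."""
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end)."""
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        return self.exons[0][0], self.exons[-1][1]

    def with_sequence(self, sequence: str) -> "TranscriptModel":
        from dataclasses import replace

        return replace(self, sequence=sequence)


@dataclass(frozen=True)
class OrfResult:
    """Longest open reading frame found in a transcript sequence.

    ``length_nt`` counts ATG through the last codon before the stop (the
    stop codon itself is excluded), so 100 aa corresponds to 300 nt.
    ``has_stop`` is False for ORFs running off the 3' end of the sequence.
    """

    start_offset: int = 0
    length_nt: int = 0
    frame: int = 0
    has_stop: bool = False


def find_longest_orf(sequence: str) -> OrfResult:
    """Scan the three forward frames for the longest ATG-initiated ORF.

    The scan walks codons in each frame and tracks maximal ATG->stop runs;
    a codon containing N terminates the current run (the run up to the
    previous codon is still reported, without a stop).  Ties are broken by
    smallest start offset, then smallest frame.  An empty sequence or one
    without any ATG yields ``OrfResult(length_nt=0)``.
    """
    seq = sequence.upper()
    n = len(seq)
    best: OrfResult | None = None

    def consider(start: int, length: int, frame: int, has_stop: bool) -> None:
        nonlocal best
        if length <= 0:
            return
        cand = OrfResult(start, length, frame, has_stop)
        if (
            best is None
            or cand.length_nt > best.length_nt
            or (
                cand.length_nt == best.length_nt
                and (cand.start_offset, cand.frame)
                < (best.start_offset, best.frame)
            )
        ):
            best = cand

    for frame in range(3):
        open_start: int | None = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if "N" in codon:
                if open_start is not None:
                    consider(open_start, i - open_start, frame, False)
                    open_start = None
            elif codon in _STOP_CODONS:
                if open_start is not None:
                    consider(open_start, i - open_start, frame, True)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
            i += 3
        if open_start is not None:
            consider(open_start, i - open_start, frame, False)

    return best if best is not None else OrfResult()


def filter_by_class_code(
    transcripts: Iterable[TranscriptModel],
    allowed: frozenset[str] | set[str] = DEFAULT_CLASS_CODES,
) -> list[TranscriptModel]:
    """Keep transcripts whose class code is in ``allowed`` (order preserved).

    Class codes outside the known gffcompare alphabet trigger a warning;
    the transcript is dropped (it is not in the allowed set either way).
    """
    known = set("=ckmnjexiyopsru.")
    out = []
    for t in transcripts:
        if t.class_code not in known:
            warnings.warn(
                f"unknown class code {t.class_code!r} on {t.transcript_id}; "
                "transcript dropped",
                stacklevel=2,
            )
        if t.class_code in allowed:
            out.append(t)
    return out


def filter_by_structure(
    transcripts: Iterable[TranscriptModel],
    min_length: int = 200,
    min_exons: int = 2,
) -> list[TranscriptModel]:
    """Keep transcripts with length >= ``min_length`` and >= ``min_exons`` exons."""
    return [
        t
        for t in transcripts
        if t.length >= min_length and t.exon_count >= min_exons
    ]


def filter_by_orf(
    transcripts: Iterable[TranscriptModel],
    orf_threshold_nt: int = 300,
    mode: str = "drop_long",
) -> list[TranscriptModel]:
    """Filter on the longest-ORF length.

    mode "drop_long" (default, standard lncRNA practice): keep transcripts
    whose longest ORF is *shorter* than ``orf_threshold_nt`` — long-ORF
    transcripts are presumed coding and removed.  mode "drop_short" keeps
    only long-ORF transcripts (the inverse rule, available for
    completeness).
    """
    if mode not in {"drop_long", "drop_short"}:
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(
                f"transcript {t.transcript_id} has no sequence attached"
            )
        long_orf = find_longest_orf(t.sequence).length_nt >= orf_threshold_nt
        if (mode == "drop_long") != long_orf:
            out.append(t)
    return out


@dataclass
class TriageReport:
    """Per-transcript fate through the triage cascade plus stage counts."""

    status: dict[str, str] = field(default_factory=dict)
    retained: list[TranscriptModel] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = {
            "input": len(self.status),
            "retained": 0,
            "dropped_class_code": 0,
            "dropped_structure": 0,
            "dropped_orf": 0,
        }
        for s in self.status.values():
            c[s] += 1
        return c


def run_triage(
    transcripts: Sequence[TranscriptModel],
    allowed_codes: frozenset[str] | set[str] = DEFAULT_CLASS_CODES,
    min_length: int = 200,
    min_exons: int = 2,
    orf_threshold_nt: int = 300,
    orf_mode: str = "drop_long",
) -> TriageReport:
    """Apply the three filters in order and report each transcript's fate."""
    report = TriageReport()
    stage1 = filter_by_class_code(transcripts, allowed_codes)
    kept1 = {t.transcript_id for t in stage1}
    stage2 = filter_by_structure(stage1, min_length, min_exons)
    kept2 = {t.transcript_id for t in stage2}
    stage3 = filter_by_orf(stage2, orf_threshold_nt, orf_mode)
    kept3 = {t.transcript_id for t in stage3}
    for t in transcripts:
        tid = t.transcript_id
        if tid not in kept1:
            report.status[tid] = "dropped_class_code"
        elif tid not in kept2:
            report.status[tid] = "dropped_structure"
        elif tid not in kept3:
            report.status[tid] = "dropped_orf"
        else:
            report.status[tid] = "retained"
    report.retained = stage3
    return report
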