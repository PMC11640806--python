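"""Readers and writers for the pipeline's on-disk formats.

GTF (gffcompare-annotated dialect with a ``class_code`` attribute), FASTA,
counts/design TSVs, BLAST outfmt-6 hit tables with a trailing
``subject_type`` column, and gene -> term annotation maps.  Coordinates are
1-based closed intervals in memory (GTF convention), so GTF I/O is a
straight copy.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import CountMatrix, Design
from .enrichment import TermMap
from .homology import HitRecord
from .triage import TranscriptModel

__all__ = [
    "read_transcripts_gtf",
    "write_transcripts_gtf",
    "read_fasta",
    "write_fasta",
    "attach_sequences",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_hit_table",
    "write_hit_table",
    "read_term_map",
    "write_term_map",
    "write_json",
]

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "subject_type",
]


def read_transcripts_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models (with class codes) from a GTF file.

    Exon features are grouped by their ``transcript_id`` attribute;
    ``class_code`` defaults to "." when absent (reference annotations).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    def attr(feature, key, default=None):
        vals = feature.attributes.get(key, [])
        return vals[0] if vals else default

    for f in db.all_features():
        tid = attr(f, "transcript_id")
        if tid is None:
            continue
        if f.featuretype == "exon":
            exons.setdefault(tid, []).append((f.start, f.end))
        if tid not in meta:
            order.append(tid)
            meta[tid] = {
                "gene_id": attr(f, "gene_id", tid),
                "chrom": f.seqid,
                "strand": f.strand if f.strand in "+-" else ".",
                "class_code": attr(f, "class_code", "."),
            }
        elif attr(f, "class_code") is not None:
            meta[tid]["class_code"] = attr(f, "class_code")

    out = []
    for tid in order:
        ex = sorted(exons.get(tid, []))
        if not ex:
            continue
        m = meta[tid]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(ex),
                class_code=m["class_code"],
            )
        )
    return out


def write_transcripts_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "lncflow",
) -> None:
    """Write transcripts (and their exons) as 9-column GTF."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'class_code "{t.class_code}";'
            )
            start, end = t.span
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{start}\t{end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for es, ee in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{es}\t{ee}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(
    sequences: Mapping[str, str], path: str | Path, width: int = 60
) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def attach_sequences(
    transcripts: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    strict: bool = True,
) -> list[TranscriptModel]:
    """Return transcripts with their spliced sequences attached."""
    out = []
    for t in transcripts:
        seq = sequences.get(t.transcript_id)
        if seq is None:
            if strict:
                raise KeyError(
                    f"no sequence for transcript {t.transcript_id}"
                )
            out.append(t)
        else:
            out.append(t.with_sequence(seq))
    return out


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_counts(counts, path: str | Path) -> None:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_design(
    path: str | Path, reference: str, contrast: str
) -> Design:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(
            f"design file {path} must have 'sample' and 'group' columns"
        )
    return Design(
        groups=dict(zip(df["sample"].astype(str), df["group"].astype(str))),
        reference=reference,
        contrast=contrast,
    )


def write_design(design: Design, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(design.groups), "group": list(design.groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table {path} missing columns: {sorted(missing)}")
    return [
        HitRecord(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            percent_identity=float(r.pident),
            alignment_length=int(r.length),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
            subject_type=str(r.subject_type),
        )
        for r in df.itertuples(index=False)
    ]


def write_hit_table(table: pd.DataFrame, path: str | Path) -> None:
    table[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_term_map(path: str | Path) -> TermMap:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "term", "name", "namespace"}
    if not required <= set(df.columns):
        raise ValueError(
            f"term map {path} must have columns {sorted(required)}"
        )
    return TermMap.from_records(
        (str(r.gene), str(r.term), str(r.name), str(r.namespace))
        for r in df.itertuples(index=False)
    )


def write_term_map(
    records: Iterable[tuple[str, str, str, str]], path: str | Path
) -> None:
    pd.DataFrame(
        records, columns=["gene", "term", "name", "namespace"]
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
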