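"""Synthetic data with planted ground truth for the whole pipeline.

Every downstream stage is exercisable without a download: the generators
produce a reference annotation plus novel transcripts carrying gffcompare-
style class codes, transcript sequences with a planted coding/noncoding
contrast (long in-frame ORFs and biased codon usage vs short ORFs and a
different base composition), negative-binomially distributed counts for a
two-group, four-replicates-per-group design with planted differential
lncRNAs, planted lncRNA-gene correlation structure (some pairs < 20 kb
apart on the genome, some on distant loci), a homology hit table, and a
gene -> term annotation map.

The planted truth (class labels, fold changes, regulatory pairs, homology
groups) is returned alongside, so recovery by the analysis stages can be
checked exactly.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix, Design
from .homology import HitRecord
from .triage import TranscriptModel, find_longest_orf

__all__ = [
    "SimulationConfig",
    "PlantedPair",
    "GroundTruth",
    "ConfigurationError",
    "GenerationError",
    "simulate_annotation",
    "simulate_sequences",
    "simulate_training_sequences",
    "simulate_counts",
    "simulate_hit_table",
    "simulate_term_map",
    "noise_free_pair_fixture",
    "example_config",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """A requested structure cannot be generated (e.g. ORF > transcript)."""


@dataclass(frozen=True)
class PlantedPair:
    """A planted regulatory relationship between a lncRNA and a gene."""

    lnc_id: str
    gene_id: str
    sign: str  # positive | negative
    mode: str  # cis | trans

    def __post_init__(self) -> None:
        if self.sign not in {"positive", "negative"}:
            raise ConfigurationError(f"bad sign {self.sign!r}")
        if self.mode not in {"cis", "trans"}:
            raise ConfigurationError(f"bad mode {self.mode!r}")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study-design defaults.

    The defaults emulate the design the pipeline targets: two treatment
    groups ("CPA" vs "CPA_TAM") with four replicates each, NB counts with
    bulk-typical dispersion 0.05, novel transcripts dominated by the
    intergenic class code "u", and planted effects of |log2FC| >= 1.
    """

    seed: int = 0
    n_chromosomes: int = 4
    n_reference_genes: int = 120
    n_novel_transcripts: int = 150
    class_code_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "u": 0.50, "i": 0.15, "x": 0.10, "o": 0.10, "j": 0.10, "=": 0.05,
        }
    )
    novel_coding_fraction: float = 0.4
    structural_fail_fraction: float = 0.1
    n_coding: int = 200
    n_noncoding: int = 200
    groups: tuple[str, str] = ("CPA", "CPA_TAM")
    n_per_group: int = 4
    planted_del_ids: Mapping[str, float] = field(default_factory=dict)
    nb_dispersion: float = 0.05
    planted_pairs: tuple[PlantedPair, ...] = ()
    lncrna_hit_fraction: float = 0.4
    latent_sd: float = 1.0  # shared-factor SD on the log2 scale
    base_mean_range: tuple[float, float] = (20.0, 500.0)

    def __post_init__(self) -> None:
        total = float(sum(self.class_code_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_code_mix proportions sum to {total}, expected 1"
            )
        if any(p < 0 for p in self.class_code_mix.values()):
            raise ConfigurationError("negative class-code proportion")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ConfigurationError("need two distinct group labels")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator stage."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class GroundTruth:
    """Everything planted by the generators, for exact recovery checks."""

    true_class: dict[str, str] = field(default_factory=dict)  # novel id -> coding|lncRNA
    true_de: dict[str, float] = field(default_factory=dict)  # feature -> log2FC
    true_pairs: list[PlantedPair] = field(default_factory=list)
    cis_distances: dict[tuple[str, str], int] = field(default_factory=dict)
    homology_group: dict[str, int] = field(default_factory=dict)
    features: list[str] = field(default_factory=list)
    feature_class: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "true_class": self.true_class,
            "true_de": self.true_de,
            "true_pairs": [
                [p.lnc_id, p.gene_id, p.sign, p.mode] for p in self.true_pairs
            ],
            "cis_distances": {
                f"{a}|{b}": d for (a, b), d in self.cis_distances.items()
            },
            "homology_group": self.homology_group,
            "features": self.features,
            "feature_class": self.feature_class,
        }


_GENE_ID = "gene_{:04d}"
_REF_TX_ID = "reftx_{:04d}"
_NOVEL_ID = "novel_{:04d}"


def _make_exons(
    rng: np.random.Generator,
    start: int,
    n_exons: int,
    exon_len_range: tuple[int, int],
    intron_len_range: tuple[int, int],
) -> tuple[tuple[int, int], ...]:
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(*exon_len_range))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(*intron_len_range))
    return tuple(exons)


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], list[TranscriptModel], GroundTruth]:
    """Generate the reference annotation, novel transcripts and truth.

    Reference genes (one transcript each, class code "=") are laid out
    sequentially per chromosome with >= 20 kb intergenic gaps.  Novel
    transcripts draw their class code from ``class_code_mix``; those
    involved in planted pairs are forced to the intergenic code "u",
    labeled lncRNA-truth, and placed with a span gap < 20 kb from their
    partner gene (cis) or on a different chromosome (trans).  A
    configurable fraction of the remaining novels deliberately fails the
    structural filters (single exon or < 200 nt).
    """
    rng = config.rng(1)
    truth = GroundTruth()

    # --- reference genes ---
    reference: list[TranscriptModel] = []
    gene_by_id: dict[str, TranscriptModel] = {}
    cursors = {f"chr{i + 1}": 10_000 for i in range(config.n_chromosomes)}
    chrom_names = list(cursors)
    for g in range(config.n_reference_genes):
        chrom = chrom_names[g % len(chrom_names)]
        start = cursors[chrom]
        n_ex = int(rng.integers(3, 13))
        exons = _make_exons(rng, start, n_ex, (120, 401), (300, 3001))
        model = TranscriptModel(
            transcript_id=_REF_TX_ID.format(g),
            gene_id=_GENE_ID.format(g),
            chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            exons=exons,
            class_code="=",
        )
        reference.append(model)
        gene_by_id[model.gene_id] = model
        cursors[chrom] = exons[-1][1] + 20_000 + int(rng.integers(0, 60_000))

    # --- planted pairs drive placement of their lncRNAs ---
    planted_lnc: dict[str, TranscriptModel] = {}
    for pair in config.planted_pairs:
        if pair.gene_id not in gene_by_id:
            raise ConfigurationError(
                f"planted pair gene {pair.gene_id!r} not generated "
                f"(n_reference_genes={config.n_reference_genes})"
            )
        gene = gene_by_id[pair.gene_id]
        n_ex = int(rng.integers(2, 4))
        if pair.mode == "cis":
            gap = int(rng.integers(200, 15_000))
            start = gene.span[1] + gap + 1
            chrom = gene.chrom
        else:
            idx = chrom_names.index(gene.chrom)
            chrom = chrom_names[(idx + 1) % len(chrom_names)]
            start = cursors[chrom]
            cursors[chrom] += 30_000
        exons = _make_exons(rng, start, n_ex, (100, 301), (200, 1500))
        model = TranscriptModel(
            transcript_id=pair.lnc_id,
            gene_id=pair.lnc_id,
            chrom=chrom,
            strand="+",
            exons=exons,
            class_code="u",
        )
        if pair.mode == "cis":
            gap_actual = model.span[0] - gene.span[1] - 1
            if not 0 <= gap_actual < 20_000:
                raise GenerationError(
                    f"cis placement failed for {pair.lnc_id}: gap {gap_actual}"
                )
            truth.cis_distances[(pair.lnc_id, pair.gene_id)] = gap_actual
        planted_lnc[pair.lnc_id] = model
        truth.true_class[pair.lnc_id] = "lncRNA"
        truth.true_pairs.append(pair)

    # --- remaining novel transcripts ---
    novel: list[TranscriptModel] = list(planted_lnc.values())
    codes = list(config.class_code_mix)
    probs = np.array([config.class_code_mix[c] for c in codes], dtype=float)
    n_rest = config.n_novel_transcripts - len(novel)
    if n_rest < 0:
        raise ConfigurationError(
            "more planted pairs than n_novel_transcripts"
        )
    far_chrom_cursor = {
        c: 6_000_000 + int(rng.integers(0, 100_000)) for c in chrom_names
    }
    for i in range(n_rest):
        nid = _NOVEL_ID.format(i)
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        start = far_chrom_cursor[chrom]
        code = str(rng.choice(codes, p=probs))
        is_coding = rng.random() < config.novel_coding_fraction
        fails = rng.random() < config.structural_fail_fraction
        if fails:
            if rng.random() < 0.5:
                exons = _make_exons(rng, start, 1, (800, 3000), (1, 2))
            else:
                exons = _make_exons(rng, start, 2, (60, 95), (200, 800))
        elif is_coding:
            exons = _make_exons(
                rng, start, int(rng.integers(3, 6)), (250, 601), (200, 2000)
            )
        else:
            exons = _make_exons(
                rng, start, int(rng.integers(2, 5)), (100, 301), (200, 1500)
            )
        model = TranscriptModel(
            transcript_id=nid,
            gene_id=nid,
            chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            exons=exons,
            class_code=code,
        )
        # transcripts too short to host a 300 nt ORF are noncoding-truth
        if model.length < 360:
            is_coding = False
        truth.true_class[nid] = "coding" if is_coding else "lncRNA"
        novel.append(model)
        far_chrom_cursor[chrom] = model.span[1] + 50_000 + int(
            rng.integers(0, 50_000)
        )

    # --- feature table for counts ---
    truth.features = [g.gene_id for g in reference] + [
        t.transcript_id for t in novel
    ]
    for g in reference:
        truth.feature_class[g.gene_id] = "mRNA"
    for t in novel:
        truth.feature_class[t.transcript_id] = (
            "mRNA" if truth.true_class[t.transcript_id] == "coding" else "lncRNA"
        )
    truth.true_de = dict(config.planted_del_ids)
    unknown = set(truth.true_de) - set(truth.features)
    if unknown:
        raise ConfigurationError(
            f"planted DE ids not among features: {sorted(unknown)}"
        )
    return reference, novel, truth


# 61 sense codons with a synthetic usage bias (GC-ending codons preferred)
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]
_CODON_WEIGHTS = np.array(
    [3.0 if c[2] in "GC" else 1.0 for c in _CODONS]
)
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()

#: base composition of noncoding sequences (AT-rich, unlike the codon bias)
_NONCODING_P = {"A": 0.32, "C": 0.18, "G": 0.18, "T": 0.32}


def _random_bases(rng: np.random.Generator, n: int, probs=None) -> str:
    if probs is None:
        probs = _NONCODING_P
    bases = list(probs)
    p = np.array([probs[b] for b in bases])
    return "".join(rng.choice(bases, size=n, p=p)) if n > 0 else ""


def _coding_sequence(
    rng: np.random.Generator, length: int, min_orf: int = 300
) -> str:
    """Sequence of given length with a planted in-frame ORF >= min_orf nt."""
    if length < min_orf + 3:
        raise GenerationError(
            f"transcript length {length} cannot host an ORF of {min_orf} nt"
        )
    max_codons = (length - 3) // 3  # leave room for the stop codon
    lo = min_orf // 3
    n_codons = int(rng.integers(lo, max_codons + 1))
    orf = "ATG" + "".join(
        rng.choice(_CODONS, size=n_codons - 1, p=_CODON_WEIGHTS)
    )
    orf += str(rng.choice(["TAA", "TAG", "TGA"]))
    rest = length - len(orf)
    utr5 = int(rng.integers(0, rest + 1))
    seq = (
        _random_bases(rng, utr5)
        + orf
        + _random_bases(rng, rest - utr5)
    )
    assert len(seq) == length
    return seq


def _noncoding_sequence(
    rng: np.random.Generator, length: int, max_orf: int = 300
) -> str:
    """AT-biased random sequence whose longest ORF is < max_orf nt."""
    seq = _random_bases(rng, length)
    for _ in range(100):
        orf = find_longest_orf(seq)
        if orf.length_nt < max_orf:
            return seq
        # destroy the offending start codon and rescan
        i = orf.start_offset
        seq = seq[:i] + "ATA" + seq[i + 3 :]
    raise GenerationError("could not suppress long ORFs")  # pragma: no cover


def simulate_sequences(
    transcripts: Sequence[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, str]:
    """Spliced sequences matching each transcript's exon-chain length.

    Coding-truth transcripts carry a planted in-frame ORF >= 300 nt built
    from the biased codon table; lncRNA-truth transcripts are AT-biased
    with longest ORF < 300 nt.  Transcripts too short to host the planted
    ORF raise :class:`GenerationError`.
    """
    rng = config.rng(2)
    out: dict[str, str] = {}
    for t in transcripts:
        label = truth.true_class.get(t.transcript_id)
        if label is None:
            raise ValueError(
                f"no truth label for transcript {t.transcript_id}"
            )
        if label == "coding":
            out[t.transcript_id] = _coding_sequence(rng, t.length)
        else:
            out[t.transcript_id] = _noncoding_sequence(rng, t.length)
    return out


def simulate_training_sequences(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Labeled training corpus for the coding-potential classifier.

    ``n_coding`` mRNA-like and ``n_noncoding`` lncRNA-like sequences with
    the same planted contrast used for the novel transcripts.
    """
    rng = config.rng(3)
    coding = [
        (
            f"train_coding_{i:04d}",
            _coding_sequence(rng, int(rng.integers(500, 2501))),
        )
        for i in range(config.n_coding)
    ]
    noncoding = [
        (
            f"train_noncoding_{i:04d}",
            _noncoding_sequence(rng, int(rng.integers(250, 1501))),
        )
        for i in range(config.n_noncoding)
    ]
    return coding, noncoding


def nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mu, alpha) draws with Var = mu + alpha*mu^2 (Poisson at alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def simulate_counts(
    config: SimulationConfig,
    truth: GroundTruth,
    return_means: bool = False,
):
    """NB count matrix and design with planted effects and correlations.

    Per feature, a baseline mean is drawn log-uniformly from
    ``base_mean_range`` and split between groups so the log2 ratio of
    group means equals the planted log2FC.  Planted pairs share a
    per-sample Gaussian latent factor on the log2 scale (sign flipped for
    negative pairs), which induces |Pearson r| >= 0.9 in expectation on
    log-normalized counts at the default latent SD.  Counts are NB with
    dispersion ``nb_dispersion``.
    """
    if config.n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2")
    unknown = set(truth.true_de) - set(truth.features)
    if unknown:
        raise ConfigurationError(
            f"planted DE ids outside feature set: {sorted(unknown)}"
        )
    rng = config.rng(4)
    features = list(truth.features)
    ref_label, con_label = config.groups
    samples = [
        f"{ref_label}_{i + 1}" for i in range(config.n_per_group)
    ] + [f"{con_label}_{i + 1}" for i in range(config.n_per_group)]
    group_of = {
        s: (ref_label if i < config.n_per_group else con_label)
        for i, s in enumerate(samples)
    }
    n_samples = len(samples)
    is_con = np.array([group_of[s] == con_label for s in samples])

    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(features)))
    lfc = np.array([truth.true_de.get(f, 0.0) for f in features])

    # log2 mean per feature per sample
    log2_mu = np.log2(base)[:, None] + np.where(
        is_con[None, :], lfc[:, None] / 2.0, -lfc[:, None] / 2.0
    )

    # shared latent factors for planted pairs
    index_of = {f: i for i, f in enumerate(features)}
    for pair in truth.true_pairs:
        z = rng.normal(0.0, config.latent_sd, size=n_samples)
        li = index_of.get(pair.lnc_id)
        gi = index_of.get(pair.gene_id)
        if li is None or gi is None:
            raise ConfigurationError(
                f"planted pair ids missing from features: {pair}"
            )
        log2_mu[li] += z
        log2_mu[gi] += z if pair.sign == "positive" else -z

    mu = 2.0**log2_mu
    counts = nb_counts(rng, mu, config.nb_dispersion)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=features, columns=samples),
        feature_class=dict(truth.feature_class),
    )
    design = Design(groups=group_of, reference=ref_label, contrast=con_label)
    if return_means:
        return cm, design, pd.DataFrame(mu, index=features, columns=samples)
    return cm, design


def simulate_hit_table(
    candidates: Sequence[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """BLAST-outfmt-6-style hit table exercising all three homology groups.

    Coding-truth candidates get a significant (E <= 1e-5) hit to a
    protein-coding (or occasionally other non-lncRNA) subject; a
    ``lncrna_hit_fraction`` of lncRNA-truth candidates get a significant
    lncRNA-subject hit; the rest get either no rows or only insignificant
    (E > 1e-5) decoy rows.  The planted group per candidate is recorded in
    ``truth.homology_group``.
    """
    rng = config.rng(5)
    rows = []

    def hit_row(qid, sid, evalue, subject_type):
        aln = int(rng.integers(80, 400))
        return {
            "qseqid": qid,
            "sseqid": sid,
            "pident": round(float(rng.uniform(85, 100)), 2),
            "length": aln,
            "mismatch": int(rng.integers(0, 10)),
            "gapopen": int(rng.integers(0, 3)),
            "qstart": 1,
            "qend": aln,
            "sstart": 1,
            "send": aln,
            "evalue": evalue,
            "bitscore": round(float(rng.uniform(50, 500)), 1),
            "subject_type": subject_type,
        }

    for t in candidates:
        tid = t.transcript_id
        label = truth.true_class.get(tid)
        if label is None:
            raise ValueError(f"no truth label for candidate {tid}")
        if label == "coding":
            stype = (
                "non_lncRNA" if rng.random() < 0.15 else "protein_coding"
            )
            evalue = float(10.0 ** rng.uniform(-40, -6))
            rows.append(hit_row(tid, f"NM_{rng.integers(10**5):06d}", evalue, stype))
            truth.homology_group[tid] = 1
        elif rng.random() < config.lncrna_hit_fraction:
            evalue = float(10.0 ** rng.uniform(-30, -6))
            rows.append(
                hit_row(tid, f"NR_{rng.integers(10**5):06d}", evalue, "lncRNA")
            )
            truth.homology_group[tid] = 2
        else:
            if rng.random() < 0.5:  # insignificant decoy hit
                evalue = float(10.0 ** rng.uniform(-4, 0))
                rows.append(
                    hit_row(
                        tid,
                        f"XR_{rng.integers(10**5):06d}",
                        evalue,
                        str(rng.choice(["protein_coding", "lncRNA"])),
                    )
                )
            truth.homology_group[tid] = 3

    columns = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        "subject_type",
    ]
    return pd.DataFrame(rows, columns=columns)


def hit_records(table: pd.DataFrame) -> list[HitRecord]:
    """Convert a hit table to HitRecord objects for the homology stage."""
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
        for r in table.itertuples(index=False)
    ]


def simulate_term_map(
    config: SimulationConfig,
    truth: GroundTruth,
    n_terms: int = 25,
    term_size_range: tuple[int, int] = (5, 40),
) -> list[tuple[str, str, str, str]]:
    """Gene -> term annotation records over the simulated gene universe.

    Genes of planted regulatory pairs are concentrated into the first two
    terms so that enrichment of the recovered target set is detectable.
    """
    rng = config.rng(6)
    genes = [f for f in truth.features if truth.feature_class[f] == "mRNA"]
    namespaces = ["BP", "CC", "MF", "pathway"]
    records = []
    planted_genes = sorted({p.gene_id for p in truth.true_pairs})
    for i in range(n_terms):
        tid = f"TERM:{i:04d}"
        ns = namespaces[i % len(namespaces)]
        size = int(rng.integers(*term_size_range))
        members = set(
            rng.choice(genes, size=min(size, len(genes)), replace=False)
        )
        if i < 2 and planted_genes:
            members |= set(planted_genes)
        for g in sorted(members):
            records.append((g, tid, f"synthetic term {i}", ns))
    return records


def noise_free_pair_fixture(
    seed: int = 0,
    n_cis: int = 3,
    n_trans: int = 4,
    n_decoy_degs: int = 4,
    n_samples: int = 12,
):
    """Deterministic noise-free fixture for exact cis/trans recovery.

    Builds DEL/DEG expression matrices in which each planted pair shares
    one of a set of mutually orthogonal, mean-zero latent profiles (so the
    planted |r| is exactly 1 and cross-pair correlations are exactly 0),
    plus decoy DEGs carrying further orthogonal profiles.  The matching
    annotation places cis pairs with span gaps < 20 kb (one at exactly
    19,999) and trans pairs on different chromosomes.

    Returns ``(del_expr, deg_expr, annotation, planted_pairs)``.
    """
    k = n_cis + n_trans + n_decoy_degs
    if k > n_samples - 1:
        raise ConfigurationError(
            "need n_cis + n_trans + n_decoy_degs <= n_samples - 1 "
            "orthogonal profiles"
        )
    rng = np.random.default_rng([int(seed) % (2**31), 7])
    # orthonormal mean-zero profiles: QR of a centered random matrix,
    # re-centered columns stay orthogonal to the constant vector
    M = rng.normal(size=(n_samples, k))
    M = M - M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    latents = Q[:, :k].T  # k x n_samples, pairwise orthogonal, mean ~ 0
    latents = latents - latents.mean(axis=1, keepdims=True)

    samples = [f"S{i + 1}" for i in range(n_samples)]
    pairs: list[PlantedPair] = []
    del_rows, deg_rows = {}, {}
    annotation: dict[str, TranscriptModel] = {}

    def tx(tid, chrom, start, length=1_000):
        return TranscriptModel(
            transcript_id=tid,
            gene_id=tid,
            chrom=chrom,
            strand="+",
            exons=((start, start + 99), (start + 200, start + length - 1)),
            class_code="u",
        )

    gaps = [19_999] + [int(rng.integers(100, 18_000)) for _ in range(n_cis - 1)]
    for i in range(n_cis + n_trans):
        mode = "cis" if i < n_cis else "trans"
        sign = "positive" if i % 2 == 0 else "negative"
        lid, gid = f"DEL_{i}", f"DEG_{i}"
        z = latents[i]
        del_rows[lid] = 10.0 + 2.0 * z
        deg_rows[gid] = 8.0 + (2.0 * z if sign == "positive" else -2.0 * z)
        if mode == "cis":
            gene_start = 100_000 + 200_000 * i
            gene = tx(gid, "chr1", gene_start)
            gap = gaps[i]
            lnc = tx(lid, "chr1", gene.span[1] + gap + 1)
        else:
            gene = tx(gid, "chr1", 5_000_000 + 200_000 * i)
            lnc = tx(lid, "chr2", 100_000 + 200_000 * i)
        annotation[gid] = gene
        annotation[lid] = lnc
        pairs.append(PlantedPair(lid, gid, sign, mode))
    for j in range(n_decoy_degs):
        gid = f"DEG_decoy_{j}"
        deg_rows[gid] = 9.0 + 2.0 * latents[n_cis + n_trans + j]
        annotation[gid] = tx(gid, "chr3", 100_000 + 200_000 * j)

    del_expr = pd.DataFrame(del_rows, index=samples).T
    deg_expr = pd.DataFrame(deg_rows, index=samples).T
    return del_expr, deg_expr, annotation, pairs


def example_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A ready-to-run configuration with planted DELs, DEGs and pairs.

    Three cis and four trans pairs are planted between novel lncRNAs and
    reference genes; every pair member is also planted differentially
    expressed with |log2FC| = 2, and a handful of additional DEGs/DELs
    carry |log2FC| in [1, 3].
    """
    pairs = (
        PlantedPair("lnc_cis_0", _GENE_ID.format(0), "positive", "cis"),
        PlantedPair("lnc_cis_1", _GENE_ID.format(5), "negative", "cis"),
        PlantedPair("lnc_cis_2", _GENE_ID.format(10), "positive", "cis"),
        PlantedPair("lnc_trans_0", _GENE_ID.format(3), "positive", "trans"),
        PlantedPair("lnc_trans_1", _GENE_ID.format(8), "negative", "trans"),
        PlantedPair("lnc_trans_2", _GENE_ID.format(13), "positive", "trans"),
        PlantedPair("lnc_trans_3", _GENE_ID.format(16), "negative", "trans"),
    )
    planted_de: dict[str, float] = {}
    for p in pairs:
        # opposite-sign fold changes keep the group effect consistent with
        # the planted correlation sign across pooled samples; |log2FC| = 3
        # keeps pair members detectably DE despite the shared-factor
        # within-group variance
        planted_de[p.lnc_id] = 3.0
        planted_de[p.gene_id] = 3.0 if p.sign == "positive" else -3.0
    planted_de[_GENE_ID.format(20)] = 3.0
    planted_de[_GENE_ID.format(21)] = -3.0
    planted_de[_GENE_ID.format(22)] = 1.5
    planted_de[_GENE_ID.format(23)] = -1.5
    defaults = dict(
        seed=seed,
        planted_pairs=pairs,
        planted_del_ids=planted_de,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
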