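"""End-to-end orchestration: simulate -> triage -> classify -> homology ->
differential expression -> target inference -> enrichment.

:func:`run_pipeline` executes the stages in order on the files named by a
:class:`RunConfig`, writes every stage's table next to the outputs
directory, and returns a :class:`dict` run report with the stage-by-stage
funnel counts.  Identical config + seed yields byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import coding, diffexpr, enrichment, homology, io, simulate, targets, triage

__all__ = [
    "RunConfig",
    "Finding",
    "run_pipeline",
    "validate_inputs",
    "simulate_all",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Threshold defaults encode the analysis conventions the pipeline
    implements: class codes {x,o,i,u,j}; >= 200 nt and >= 2 exons;
    longest ORF < 300 nt; homology E <= 1e-5; DE at adjusted p < 0.05 and
    |log2FC| >= 1; pair retention at |r| >= 0.90 and p < 0.01; cis within
    20 kb; enrichment at adjusted p <= 0.05.
    """

    # inputs
    gtf: str = "annotation.gtf"
    fasta: str = "transcripts.fa"
    counts: str = "counts.tsv"
    design: str = "design.tsv"
    hits: str = "hits.tsv"
    term_map: str = "term_map.tsv"
    training_coding_fasta: str = "training_coding.fa"
    training_noncoding_fasta: str = "training_noncoding.fa"
    outdir: str = "results"
    # groups
    reference_group: str = "CPA"
    contrast_group: str = "CPA_TAM"
    # thresholds
    class_codes: tuple[str, ...] = tuple(sorted(triage.DEFAULT_CLASS_CODES))
    min_length: int = 200
    min_exons: int = 2
    orf_threshold_nt: int = 300
    orf_mode: str = "drop_long"
    evalue_max: float = 1e-5
    padj_max: float = 0.05
    min_abs_log2fc: float = 1.0
    min_abs_r: float = 0.90
    trans_p_max: float = 0.01
    cis_max_distance_bp: int = 20_000
    enrichment_padj_max: float = 0.05
    min_term_size: int = 3
    # misc
    seed: int = 0
    classifier_folds: int = 10
    classifier_trees: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("class_codes",):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["class_codes"] = list(data["class_codes"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def resolve(self, base: str | Path) -> "RunConfig":
        """Anchor all relative paths at ``base``."""
        base = Path(base)
        kwargs = {}
        for key in (
            "gtf", "fasta", "counts", "design", "hits", "term_map",
            "training_coding_fasta", "training_noncoding_fasta", "outdir",
        ):
            p = Path(getattr(self, key))
            kwargs[key] = str(p if p.is_absolute() else base / p)
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Finding:
    level: str  # error | warning
    message: str


def validate_inputs(config: RunConfig) -> list[Finding]:
    """Schema checks on the configured inputs; returns findings, never raises."""
    findings: list[Finding] = []

    def error(msg):
        findings.append(Finding("error", msg))

    def warning(msg):
        findings.append(Finding("warning", msg))

    for key in ("gtf", "fasta", "counts", "design", "hits", "term_map"):
        if not Path(getattr(config, key)).exists():
            error(f"{key} file not found: {getattr(config, key)}")
    if findings:
        return findings

    try:
        transcripts = io.read_transcripts_gtf(config.gtf)
    except Exception as exc:  # noqa: BLE001 - reported as finding
        error(f"GTF unreadable: {exc}")
        return findings
    novel = [t for t in transcripts if t.class_code != "="]
    if novel and all(t.class_code == "." for t in novel):
        error("GTF lacks class_code attributes")

    seqs = io.read_fasta(config.fasta)
    novel_ids = {t.transcript_id for t in novel}
    missing = [t for t in novel_ids if t not in seqs]
    if missing:
        warning(
            f"{len(missing)} novel transcripts without FASTA sequence "
            f"(e.g. {sorted(missing)[:3]})"
        )

    counts = io.read_counts(config.counts)
    try:
        design = io.read_design(
            config.design, config.reference_group, config.contrast_group
        )
    except ValueError as exc:
        error(str(exc))
        return findings
    extra = [s for s in counts.columns if s not in design.groups]
    if extra:
        error(f"count columns not in design: {extra}")
    absent = [s for s in design.groups if s not in counts.columns]
    if absent:
        error(f"design samples missing from counts: {absent}")

    try:
        io.read_hit_table(config.hits)
    except ValueError as exc:
        error(str(exc))
    return findings


def _log_stage(report: dict, stage: str, **counts) -> None:
    report["stages"][stage] = counts
    logger.info("stage %s: %s", stage, counts)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the run report (also written to outdir).

    Stage outputs (triage report, predictions, homology groups, DE tables,
    PCA/distance matrices, pair table, enrichment table) are written as
    TSV/JSON under ``config.outdir``.  A failure names the stage in the
    raised exception; outputs of completed stages remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
    }

    def stage(name):
        logger.info("running stage %s", name)
        return name

    current = stage("load")
    try:
        transcripts = io.read_transcripts_gtf(config.gtf)
        sequences = io.read_fasta(config.fasta)
        transcripts = io.attach_sequences(transcripts, sequences, strict=False)
        novel = [t for t in transcripts if t.class_code != "="]
        _log_stage(
            report, "load",
            transcripts=len(transcripts), novel=len(novel),
            sequences=len(sequences),
        )

        current = stage("triage")
        with_seq = [t for t in novel if t.sequence is not None]
        triage_report = triage.run_triage(
            with_seq,
            allowed_codes=set(config.class_codes),
            min_length=config.min_length,
            min_exons=config.min_exons,
            orf_threshold_nt=config.orf_threshold_nt,
            orf_mode=config.orf_mode,
        )
        tr_counts = triage_report.counts
        _log_stage(report, "triage", **tr_counts)
        io.write_json(
            {"status": triage_report.status, "counts": tr_counts},
            outdir / "triage_report.json",
        )

        current = stage("classify")
        training = coding.build_training_set(
            io.read_fasta(config.training_coding_fasta).items(),
            io.read_fasta(config.training_noncoding_fasta).items(),
            provenance=f"{config.training_coding_fasta} + "
            f"{config.training_noncoding_fasta}",
        )
        clf = coding.train_classifier(
            training,
            k_folds=config.classifier_folds,
            seed=config.seed,
            n_estimators=config.classifier_trees,
        )
        candidates = [
            (t.transcript_id, t.sequence) for t in triage_report.retained
        ]
        predictions, lnc_ids = coding.predict(clf, candidates)
        pd.DataFrame(
            predictions, columns=["transcript_id", "label", "p_noncoding"]
        ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        _log_stage(
            report, "classify",
            training_records=len(training.records),
            candidates=len(candidates),
            predicted_lncrna=len(lnc_ids),
            cv_mean_precision=round(clf.mean_cv.get("precision", 0.0), 4),
            cv_mean_recall=round(clf.mean_cv.get("recall", 0.0), 4),
        )

        current = stage("homology")
        hits = io.read_hit_table(config.hits)
        # the hit table may cover transcripts already removed upstream
        lnc_id_set = set(lnc_ids)
        hits = [h for h in hits if h.query_id in lnc_id_set]
        groups = homology.classify_by_homology(
            lnc_ids, hits, evalue_max=config.evalue_max
        )
        pd.DataFrame(
            [(cid, groups.group_of(cid)) for cid in lnc_ids],
            columns=["transcript_id", "group"],
        ).to_csv(outdir / "homology_groups.tsv", sep="\t", index=False)
        novel_lnc_ids = groups.retained
        _log_stage(
            report, "homology",
            group1_excluded=len(groups.group1_excluded),
            group2_known_lncrna=len(groups.group2_known_lncrna),
            group3_no_match=len(groups.group3_no_match),
            retained=len(novel_lnc_ids),
        )

        current = stage("diffexpr")
        counts = io.read_counts(config.counts)
        if counts.empty:
            raise ValueError("counts matrix is empty")
        design = io.read_design(
            config.design, config.reference_group, config.contrast_group
        )
        factors = diffexpr.size_factors(counts)
        results = diffexpr.nb_wald_test(counts, design, factors)
        feature_class = {
            f: ("lncRNA" if f in set(novel_lnc_ids) else "mRNA")
            for f in counts.index
        }
        call = diffexpr.call_de(
            results,
            feature_class,
            padj_max=config.padj_max,
            min_abs_log2fc=config.min_abs_log2fc,
        )
        call.results.to_csv(outdir / "de_results.tsv", sep="\t")
        coords, frac, dist = diffexpr.sample_similarity(counts, factors)
        coords.to_csv(outdir / "pca_coordinates.tsv", sep="\t")
        dist.to_csv(outdir / "sample_distances.tsv", sep="\t")
        dels_up = int((call.dels["direction"] == "up").sum())
        dels_down = int((call.dels["direction"] == "down").sum())
        degs_up = int((call.degs["direction"] == "up").sum())
        degs_down = int((call.degs["direction"] == "down").sum())
        _log_stage(
            report, "diffexpr",
            features=len(results),
            lncrna_features=sum(
                1 for v in feature_class.values() if v == "lncRNA"
            ),
            dels=len(call.dels), dels_up=dels_up, dels_down=dels_down,
            degs=len(call.degs), degs_up=degs_up, degs_down=degs_down,
        )

        current = stage("targets")
        logexpr = diffexpr.log_normalize(counts, factors)
        del_expr = logexpr.loc[call.dels.index]
        deg_expr = logexpr.loc[call.degs.index]
        pairs = targets.infer_trans_targets(
            del_expr,
            deg_expr,
            min_abs_r=config.min_abs_r,
            p_max=config.trans_p_max,
        )
        annotation: dict[str, triage.TranscriptModel] = {}
        for t in transcripts:
            annotation.setdefault(t.gene_id, t)
            annotation.setdefault(t.transcript_id, t)
        pairs = targets.assign_cis(
            pairs, annotation, max_distance_bp=config.cis_max_distance_bp
        )
        summary = targets.summarize_network(pairs)
        targets.pairs_to_frame(pairs).to_csv(
            outdir / "regulatory_pairs.tsv", sep="\t", index=False
        )
        io.write_json(summary.to_dict(), outdir / "network_summary.json")
        _log_stage(report, "targets", **summary.to_dict())

        current = stage("enrichment")
        term_map = io.read_term_map(config.term_map)
        target_genes = sorted({p.deg_id for p in pairs})
        if target_genes:
            enr = enrichment.enrich(
                target_genes,
                term_map,
                padj_max=config.enrichment_padj_max,
                min_term_size=config.min_term_size,
                universe=list(counts.index),
            )
        else:
            enr = pd.DataFrame(
                columns=[
                    "term_id", "name", "namespace", "k", "K", "n", "N",
                    "p_value", "p_adjusted", "enriched",
                ]
            )
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        _log_stage(
            report, "enrichment",
            target_genes=len(target_genes),
            terms_tested=len(enr),
            enriched_terms=int(enr["enriched"].sum()) if len(enr) else 0,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{current}': {exc}") from exc

    io.write_json(report, outdir / "run_report.json")
    return report


def simulate_all(
    config: simulate.SimulationConfig, outdir: str | Path
) -> RunConfig:
    """Generate a complete synthetic input set plus a matching RunConfig.

    Writes annotation.gtf, transcripts.fa, training FASTAs, counts.tsv,
    design.tsv, hits.tsv, term_map.tsv, truth.json and config.yaml into
    ``outdir`` and returns the resolved RunConfig.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, novel, truth = simulate.simulate_annotation(config)
    sequences = simulate.simulate_sequences(novel, truth, config)
    coding_train, noncoding_train = simulate.simulate_training_sequences(config)
    cm, design = simulate.simulate_counts(config, truth)

    # homology hits only make sense for candidates that can reach that
    # stage; generate for all structurally valid lncRNA/coding novels
    hit_table = simulate.simulate_hit_table(novel, truth, config)
    term_records = simulate.simulate_term_map(config, truth)

    io.write_transcripts_gtf(reference + novel, outdir / "annotation.gtf")
    io.write_fasta(sequences, outdir / "transcripts.fa")
    io.write_fasta(dict(coding_train), outdir / "training_coding.fa")
    io.write_fasta(dict(noncoding_train), outdir / "training_noncoding.fa")
    io.write_counts(cm, outdir / "counts.tsv")
    io.write_design(design, outdir / "design.tsv")
    io.write_hit_table(hit_table, outdir / "hits.tsv")
    io.write_term_map(term_records, outdir / "term_map.tsv")
    io.write_json(truth.to_json_dict(), outdir / "truth.json")

    run_config = RunConfig(
        reference_group=config.groups[0],
        contrast_group=config.groups[1],
        seed=config.seed,
    ).resolve(outdir)
    run_config = replace(run_config, outdir=str(outdir / "results"))
    run_config.to_yaml(outdir / "config.yaml")
    return run_config
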