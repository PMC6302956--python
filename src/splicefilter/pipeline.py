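"""Orchestrate the three pipeline stages: prepare, junction analysis, filter.

``run_full`` chains the stages in one call; ``prep``/``junc``/``filter_stage``
expose them separately with file-based hand-off (the junction-analysis stage
writes the full tab file; the filter stage consumes it).  Staged execution
and ``run_full`` produce identical outputs under identical config and seed:
the tab format is lossless for every field the filter stage uses, and all
randomness (SMOTE, forest) flows from the single config seed.

Junction metric computation is partitioned by contig and processed in a
deterministic order, so results are independent of the thread count.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, replace

import numpy as np

from . import alignment_io, classify, genome_metrics, junction_io, junctions
from .alignment_io import Diagnostics, PreparedInput
from .model import (
    FEATURE_NAMES,
    IntronLocus,
    JunctionRecord,
    PipelineConfig,
    TrainingError,
    to_feature_vector,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    all_tab: str
    all_bed: str
    filtered_tab: str
    filtered_bed: str
    report_path: str
    records: dict[IntronLocus, JunctionRecord]
    filtered: dict[IntronLocus, JunctionRecord]
    report: dict


def prep(
    alignment_paths: list[str], genome_path: str, outdir: str
) -> PreparedInput:
    os.makedirs(outdir, exist_ok=True)
    try:
        return alignment_io.prepare(alignment_paths, genome_path, workdir=outdir)
    except Exception as exc:
        raise StageError("prep", exc) from exc


def junc(
    prepared: PreparedInput, config: PipelineConfig, outdir: str
) -> dict[IntronLocus, JunctionRecord]:
    """Analyse all junctions and write the full tab file."""
    os.makedirs(outdir, exist_ok=True)
    try:
        records = analyze_junctions(prepared, config)
    except Exception as exc:
        raise StageError("junc", exc) from exc
    junction_io.write_junctions(records, os.path.join(outdir, "all.tab"), "tab")
    return records


def analyze_junctions(
    prepared: PreparedInput, config: PipelineConfig
) -> dict[IntronLocus, JunctionRecord]:
    """Collapse split reads and compute alignment + per-locus genome metrics."""
    diag = Diagnostics()
    stream = alignment_io.iterate_split_reads(
        prepared,
        min_intron=config.min_intron,
        max_intron=config.max_intron,
        mapq_unique_cutoff=config.mapq_unique_cutoff,
        include_secondary=config.include_secondary,
        diagnostics=diag,
    )
    profiles = junctions.collapse_junctions(stream)
    log.info(
        "collapsed %d split-read records into %d junctions",
        diag.split_records_emitted,
        len(profiles),
    )
    # contig-partitioned, deterministic order: results are independent of
    # how partitions are scheduled across threads
    records: dict[IntronLocus, JunctionRecord] = {}
    for locus in sorted(profiles, key=lambda l: l.key()):
        profile = profiles[locus]
        metrics = junctions.compute_metrics(profile)
        site = genome_metrics.classify_splice_sites(prepared.genome_path, locus)
        hamming = genome_metrics.hamming_scores(
            prepared.genome_path, locus, config.hamming_window
        )
        resolved = replace(locus, strand=site.resolved_strand)
        records[resolved] = JunctionRecord(
            locus=resolved,
            metrics=metrics,
            site_call=site,
            hamming=hamming,
            anchor_left_start=min(s.left_anchor_start for s in profile.supports),
            anchor_right_end=max(s.right_anchor_end for s in profile.supports),
        )
    return records


def complete_features(
    records: dict[IntronLocus, JunctionRecord],
    genome_path: str,
    config: PipelineConfig,
) -> tuple[dict[IntronLocus, JunctionRecord], dict, dict]:
    """Rule-label, fit the genome models, and fill in the model-derived features.

    Returns the completed records plus (positive, negative) key sets and a
    small report of the fitted models.
    """
    positive, negative = classify.build_training_keys(records, config)

    size_model = genome_metrics.fit_intron_size([k.length for k in positive])
    background = genome_metrics.genome_background(genome_path)

    def strand_of(locus: IntronLocus) -> str:
        return records[locus].site_call.resolved_strand

    pwm_kwargs = dict(
        donor_window=config.pwm_donor_window,
        acceptor_window=config.pwm_acceptor_window,
        pseudocount=config.pwm_pseudocount,
        background=background,
    )
    pos_pwm = genome_metrics.train_pwm(
        genome_path, [(k, strand_of(k)) for k in sorted(positive)], **pwm_kwargs
    )
    try:
        neg_pwm = genome_metrics.train_pwm(
            genome_path, [(k, strand_of(k)) for k in sorted(negative)], **pwm_kwargs
        )
    except TrainingError:
        # no strand-resolvable negatives: fall back to a flat model so the
        # splicing-signal feature degrades gracefully instead of aborting
        neg_pwm = genome_metrics.uniform_pwm(
            config.pwm_donor_window, config.pwm_acceptor_window
        )

    for locus, rec in records.items():
        strand = rec.site_call.resolved_strand if rec.site_call else "?"
        rec.intron_score = genome_metrics.intron_size_score(locus.length, size_model)
        rec.pwm_score = genome_metrics.pwm_score(pos_pwm, genome_path, locus, strand)
        rec.splicing_signal = genome_metrics.splicing_signal_score(
            pos_pwm, neg_pwm, genome_path, locus, strand
        )
    model_report = {"intron_l95": size_model.l95}
    return records, {"positive": positive, "negative": negative}, model_report


def filter_stage(
    records: dict[IntronLocus, JunctionRecord],
    genome_path: str,
    config: PipelineConfig,
    outdir: str,
) -> PipelineResult:
    """Self-train, score every junction, and write full + filtered outputs."""
    os.makedirs(outdir, exist_ok=True)
    try:
        records, keys, model_report = complete_features(records, genome_path, config)
        features = {k: to_feature_vector(r) for k, r in records.items()}
        training = classify.build_training_sets(records, config, features)
        forest = classify.train_forest(
            training.balanced_features,
            training.balanced_labels,
            n_trees=config.n_trees,
            seed=config.seed,
        )
        verdicts = classify.score_and_filter(forest, features, config.threshold)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("filter", exc) from exc

    for locus, verdict in verdicts.items():
        records[locus] = records[locus].with_verdict(verdict)
    filtered = {k: r for k, r in records.items() if r.verdict.genuine}

    paths = PipelineResult(
        all_tab=os.path.join(outdir, "all.tab"),
        all_bed=os.path.join(outdir, "all.bed"),
        filtered_tab=os.path.join(outdir, "filtered.tab"),
        filtered_bed=os.path.join(outdir, "filtered.bed"),
        report_path=os.path.join(outdir, "report.json"),
        records=records,
        filtered=filtered,
        report={},
    )
    junction_io.write_junctions(records, paths.all_tab, "tab")
    junction_io.write_junctions(records, paths.all_bed, "bed_exon")
    junction_io.write_junctions(filtered, paths.filtered_tab, "tab")
    junction_io.write_junctions(filtered, paths.filtered_bed, "bed_exon")

    importances = dict(
        zip(FEATURE_NAMES, (float(x) for x in forest.feature_importances_))
    )
    paths.report = {
        "seed": config.seed,
        "threshold": config.threshold,
        "n_junctions": len(records),
        "n_filtered": len(filtered),
        "training_positive": len(keys["positive"]),
        "training_negative": len(keys["negative"]),
        "balanced_class_size": int(np.sum(training.balanced_labels == 1)),
        "feature_importances": importances,
        **model_report,
    }
    with open(paths.report_path, "w") as fh:
        json.dump(paths.report, fh, indent=2, sort_keys=True)
    return paths


def run_full(
    alignment_paths: list[str],
    genome_path: str,
    config: PipelineConfig,
    outdir: str,
) -> PipelineResult:
    """Prepare, analyse and filter in one go."""
    t0 = time.monotonic()
    prepared = prep(alignment_paths, genome_path, os.path.join(outdir, "prepared"))
    log.info("prep done in %.1fs", time.monotonic() - t0)
    records = junc(prepared, config, outdir)
    log.info("junc done in %.1fs", time.monotonic() - t0)
    result = filter_stage(records, genome_path, config, outdir)
    log.info("filter done in %.1fs", time.monotonic() - t0)
    return result


def run_stage(stage: str, config: PipelineConfig, outdir: str, **inputs):
    """Dispatch one stage by name: prep | junc | filter."""
    if stage == "prep":
        return prep(inputs["alignment_paths"], inputs["genome_path"], outdir)
    if stage == "junc":
        prepared = inputs.get("prepared")
        if prepared is None:
            alignment_path = inputs["alignment_path"]
            if not os.path.exists(alignment_path + ".bai"):
                raise StageError(
                    "junc", RuntimeError("input is not prepared (missing index); run prep first")
                )
            prepared = PreparedInput(
                alignment_path=alignment_path,
                genome_path=inputs["genome_path"],
                read_count=0,
                source_count=1,
            )
        return junc(prepared, config, outdir)
    if stage == "filter":
        records = inputs.get("records")
        if records is None:
            records = junction_io.read_junctions(inputs["tab_path"], "tab")
        return filter_stage(records, inputs["genome_path"], config, outdir)
    raise ValueError(f"unknown stage {stage!r}")
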