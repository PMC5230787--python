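"""End-to-end orchestration: measurements -> KEVs -> sequences -> features.

:func:`run_pipeline` wires the stages together exactly as a full
translatome experiment would be analyzed: per-replicate translational
efficiencies, CV screening and the 3-of-5 replicate filter, normalized
KEVs with classes and t-test p-values, start-region SD calls, group
structure logos, and a feature-enrichment summary.  Every stage writes a
TSV under the output directory, a JSON report collects the headline
numbers, and every input gene receives exactly one disposition (a class
or an exclusion reason) — no silent drops.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .config import AnalysisConfig, SimulationConfig
from .enrichment import GeneFeatureRecord, association_test, summarize_group, summary_table
from .logo import background_frequencies, export_logo, logo_matrix, max_information_position
from .simulate import (
    simulate_annotation,
    simulate_start_regions,
    simulate_translatome,
)
from .start_region import StartRegionWindow, detect_sd, extract_window
from .translatome import (
    compute_kevs,
    kev_distribution,
    kev_table,
    replicate_filter,
    summarize_condition,
    translational_efficiency,
)

__all__ = ["PipelineRun", "te_summaries", "run_pipeline", "write_synthetic_inputs"]

logger = logging.getLogger("kevtools")


@dataclass
class PipelineRun:
    """Record of one pipeline execution."""

    config: AnalysisConfig
    input_paths: dict[str, str]
    output_paths: dict[str, str] = field(default_factory=dict)
    counters: dict[str, int] = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    seed: int | None = None


def te_summaries(measurements: pd.DataFrame, config: AnalysisConfig):
    """Per-gene condition summaries and the replicate-filter verdicts.

    Returns ``(summaries, passing, excluded)`` where ``summaries`` maps
    gene_id to its (untreated, treated) pair, ``passing`` is the subset
    passing the replicate filter and ``excluded`` maps failed gene_ids to
    a reason.
    """
    wide = measurements.pivot_table(
        index=["gene_id", "condition", "replicate"],
        columns="fraction", values="intensity", aggfunc="first",
    )
    for fraction in ("free", "polysomal"):
        if fraction not in wide.columns:
            wide[fraction] = np.nan
    te = wide.apply(
        lambda row: translational_efficiency(row["polysomal"], row["free"]), axis=1
    )
    summaries, passing, excluded = {}, {}, {}
    for gene_id in measurements["gene_id"].unique():
        pair = []
        for condition in ("untreated", "treated"):
            try:
                values = np.atleast_1d(te.loc[(gene_id, condition)]).tolist()
            except KeyError:
                values = []
            pair.append(
                summarize_condition(values, config, gene_id=gene_id, condition=condition)
            )
        summaries[gene_id] = (pair[0], pair[1])
        if replicate_filter(pair[0], pair[1], config):
            passing[gene_id] = summaries[gene_id]
        else:
            excluded[gene_id] = (
                f"replicate filter: n_untreated={pair[0].n_used}, "
                f"n_treated={pair[1].n_used} < {config.min_replicates}"
            )
    return summaries, passing, excluded


def _sd_table(windows: list[StartRegionWindow], config: AnalysisConfig) -> pd.DataFrame:
    calls = [detect_sd(w.upstream_seq, config, gene_id=w.gene_id) for w in windows]
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "sd_present": [int(c.present) for c in calls],
            "site_seq": [c.site_seq for c in calls],
            "distance_to_aug": [c.distance_to_aug for c in calls],
            "total_matches": [c.total_matches for c in calls],
            "longest_run": [c.longest_run for c in calls],
        }
    )


def run_pipeline(
    measurements_path: str | Path,
    outdir: str | Path,
    config: AnalysisConfig | None = None,
    *,
    genome_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    annotation_dialect: str = "tsv",
    windows_fasta: str | Path | None = None,
    seed: int | None = None,
) -> PipelineRun:
    """Run every stage on files and write all outputs under ``outdir``.

    Sequence stages need either ``windows_fasta`` (pre-extracted windows,
    e.g. from the simulator) or ``genome_path`` plus an annotation with
    coordinates.  Feature enrichment needs ``annotation_path``.  Stages
    whose inputs are absent are skipped with a log line; a stage failure
    aborts with the stage name in the exception.
    """
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(
        config=config,
        input_paths={
            k: str(v)
            for k, v in {
                "measurements": measurements_path,
                "genome": genome_path,
                "annotation": annotation_path,
                "windows": windows_fasta,
            }.items()
            if v is not None
        },
        seed=seed,
    )

    # --- stage 1: translatome core -------------------------------------
    try:
        measurements = kio.read_measurements(measurements_path)
        summaries, passing, excluded = te_summaries(measurements, config)
        records = list(compute_kevs(passing, config)) if passing else []
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage translatome_core failed: {exc}") from exc
    classes = {r.gene_id: r.class_label for r in records}
    table = kev_table(summaries, records, excluded)
    table_path = outdir / "kev_results.tsv"
    table.to_csv(table_path, sep="\t", index=False, float_format="%.10g")
    run.output_paths["kev_results"] = str(table_path)
    counts = {label: 0 for label in ("sensitive", "average", "resistant")}
    for r in records:
        counts[r.class_label] += 1
    run.counters.update(
        genes_in=len(summaries), genes_passing=len(passing),
        genes_excluded=len(excluded), **{f"n_{k}": v for k, v in counts.items()},
    )
    logger.info(
        "translatome_core: %d genes in, %d passing, %d excluded",
        len(summaries), len(passing), len(excluded),
    )
    histogram = None
    if records:
        hist_counts, edges = kev_distribution(records, config.histogram_bin_width)
        histogram = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist_counts}
        )
        hist_path = outdir / "kev_histogram.tsv"
        histogram.to_csv(hist_path, sep="\t", index=False, float_format="%.10g")
        run.output_paths["kev_histogram"] = str(hist_path)

    # --- stage 2: start regions ----------------------------------------
    windows: list[StartRegionWindow] = []
    features: list[GeneFeatureRecord] = []
    coords = []
    try:
        if annotation_path is not None:
            features, coords = kio.read_annotation(annotation_path, annotation_dialect)
        if windows_fasta is not None:
            windows, _ = kio.read_windows_fasta(windows_fasta, config.window_up)
        elif genome_path is not None and coords:
            genome = kio.read_genome(genome_path)
            windows = [
                extract_window(
                    genome, c.gene_id, c.record_id, c.start_codon_coord, c.strand, config
                )
                for c in coords
            ]
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage start_region failed: {exc}") from exc
    if windows:
        sd = _sd_table(windows, config)
        sd_path = outdir / "sd_calls.tsv"
        sd.to_csv(sd_path, sep="\t", index=False)
        run.output_paths["sd_calls"] = str(sd_path)
        run.counters["sd_positive"] = int(sd["sd_present"].sum())
        logger.info("start_region: %d windows, %d SD-positive",
                    len(windows), run.counters["sd_positive"])
    else:
        logger.info("start_region: no sequence inputs, stage skipped")

    # --- stage 3: structure logos per group ----------------------------
    logo_report = {}
    if windows:
        by_gene = {w.gene_id: w for w in windows}
        try:
            for group in ("sensitive", "resistant"):
                members = [by_gene[g] for g, cls in classes.items()
                           if cls == group and g in by_gene]
                if len(members) < 2:
                    continue
                background = background_frequencies(members)
                columns = logo_matrix(members, background)
                logo_path = outdir / f"logo_{group}.tsv"
                export_logo(columns, logo_path)
                run.output_paths[f"logo_{group}"] = str(logo_path)
                top = max_information_position(columns)
                logo_report[group] = {
                    "n_windows": len(members),
                    "background": list(background.p),
                    "max_information_bits": top.information_bits,
                    "max_information_position": top.position,
                }
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage structure_logo failed: {exc}") from exc

    # --- stage 4: feature enrichment -----------------------------------
    enrichment_report = {}
    if features:
        try:
            by_id = {f.gene_id: f for f in features}
            group_summaries = []
            for group in ("sensitive", "resistant"):
                members = [by_id[g] for g, cls in classes.items()
                           if cls == group and g in by_id]
                group_summaries.append(summarize_group(members, group, config))
            stable = summary_table(group_summaries)
            enrich_path = outdir / "feature_summary.tsv"
            stable.to_csv(enrich_path, sep="\t")
            run.output_paths["feature_summary"] = str(enrich_path)
            s_sens, s_res = group_summaries
            tests = {}
            if s_sens.n_listed and s_res.n_listed:
                odds, p = association_test(
                    [[s_sens.n_distal, s_sens.n_listed - s_sens.n_distal],
                     [s_res.n_distal, s_res.n_listed - s_res.n_distal]]
                )
                tests["distal_in_operon"] = {"odds_ratio": odds, "p_value": p}
            if s_sens.n_total and s_res.n_total:
                odds, p = association_test(
                    [[s_sens.n_short_intergenic, s_sens.n_total - s_sens.n_short_intergenic],
                     [s_res.n_short_intergenic, s_res.n_total - s_res.n_short_intergenic]]
                )
                tests["short_intergenic"] = {"odds_ratio": odds, "p_value": p}
            enrichment_report = {
                "groups": {s.group: dataclasses.asdict(s) for s in group_summaries},
                "tests": tests,
            }
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage feature_enrichment failed: {exc}") from exc

    # --- report ---------------------------------------------------------
    run.report = {
        "counters": run.counters,
        "group_sizes": counts,
        "histogram": histogram.to_dict("list") if histogram is not None else None,
        "logos": logo_report,
        "enrichment": enrichment_report,
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(run.report, indent=2, default=float))
    run.output_paths["report"] = str(report_path)
    if not passing:
        logger.info("run complete: 0 genes analyzed")
    return run


def write_synthetic_inputs(
    sim_config: SimulationConfig,
    outdir: str | Path,
    analysis: AnalysisConfig | None = None,
) -> dict[str, Path]:
    """Generate and write a complete synthetic input set for the pipeline.

    Writes measurements TSV, window FASTA (with planted-SD comments),
    annotation TSV and ground-truth TSVs under ``outdir``; returns the
    paths.  The annotation plants per-class distal enrichment when
    ``sim_config.operon_config.distal_rate_by_class`` says so.
    """
    analysis = analysis or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    measurements, truth = simulate_translatome(sim_config)
    windows, sd_truth = simulate_start_regions(sim_config, analysis)
    annotation = simulate_annotation(
        sim_config, classes=truth.set_index("gene_id")["class_label"]
    )
    paths = {
        "measurements": outdir / "measurements.tsv",
        "windows": outdir / "windows.fasta",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "ground_truth.tsv",
        "sd_truth": outdir / "sd_ground_truth.tsv",
    }
    kio.write_measurements(measurements, paths["measurements"])
    kio.write_windows_fasta(windows, paths["windows"], sd_truth)
    annot = annotation.copy()
    annot.insert(1, "record_id", "chr")
    # synthetic span: 1 kb per gene laid head to tail on the plus strand
    annot.insert(2, "start", [1 + 1000 * i for i in range(len(annot))])
    annot.insert(3, "end", [900 + 1000 * i for i in range(len(annot))])
    kio.write_annotation_tsv(annot, paths["annotation"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    sd_truth.to_csv(paths["sd_truth"], sep="\t", index=False)
    return paths
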