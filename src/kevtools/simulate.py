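"""Synthetic translatome, start-region and annotation generators.

The generators emit data with the statistical structure the analysis
assumes, together with ground-truth tables for recovery tests:

* :func:`simulate_translatome` — per-replicate free/polysomal intensities
  for untreated and treated conditions.  Each gene carries a true log2
  drug-effect value (Gaussian around 0 for "average" genes, shifted by
  ±``effect_log2`` for planted sensitive/resistant genes, median-centered
  so truth lives on the normalized scale).  Intensities get log-normal
  multiplicative noise, optional gross outliers (x/÷ ``outlier_factor``)
  and per-measurement dropout.  Two of five replicates carry dye-swap
  metadata, which never affects values.
* :func:`simulate_start_regions` — 77-nt start-codon windows drawn from a
  background base composition, with SD consensus sites planted at 3-7 nt
  spacing in a configurable fraction of genes.
* :func:`simulate_annotation` — operon position (single/first/distal),
  intergenic distance (short-distance model for distal genes, overlaps
  allowed) and 5'-UTR lengths, with optional per-class distal enrichment
  for power studies.

All outputs are deterministic under a fixed ``config.seed``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig, SimulationConfig
from .start_region import StartRegionWindow

__all__ = [
    "CONDITIONS",
    "FRACTIONS",
    "simulate_translatome",
    "simulate_start_regions",
    "simulate_annotation",
    "windows_from_table",
]

CONDITIONS = ("untreated", "treated")
FRACTIONS = ("free", "polysomal")
_BASES = np.array(["A", "C", "G", "T"])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _true_effects(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    n_sens = int(round(config.frac_sensitive * n))
    n_res = int(round(config.frac_resistant * n))
    planted = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    planted[order[:n_sens]] = "sensitive"
    planted[order[n_sens:n_sens + n_res]] = "resistant"
    log2_kev = rng.normal(0.0, config.log2_kev_sd, size=n)
    log2_kev[planted == "sensitive"] = -config.effect_log2
    log2_kev[planted == "resistant"] = config.effect_log2
    # truth is stated on the normalized scale: median exactly 0
    log2_kev = log2_kev - np.median(log2_kev)
    # class labels follow the thresholds applied to the centered truth, so
    # an "average" draw beyond a threshold is labeled by its value
    labels = np.where(
        2.0 ** log2_kev <= 0.5, "sensitive",
        np.where(2.0 ** log2_kev >= 2.0, "resistant", "average"),
    ).astype(object)
    return pd.DataFrame(
        {
            "gene_id": _gene_ids(n),
            "true_log2_kev": log2_kev,
            "planted": planted,
            "class_label": labels,
        }
    )


def _lognoise(cv: float, rng: np.random.Generator, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def simulate_translatome(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full four-way intensity table plus ground truth.

    Returns ``(measurements, ground_truth)``.  Measurements have one row
    per retained (gene, condition, fraction, replicate) with columns
    ``gene_id, condition, fraction, replicate, dye, intensity``.  For each
    gene the expected (geometric-mean) polysomal/free ratio in the treated
    condition equals the untreated ratio times ``2**true_log2_kev``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _true_effects(config, rng)
    n = config.n_genes
    base = np.exp(rng.normal(np.log(1000.0), 1.0, size=n))  # per-gene abundance scale
    te_untreated = 2.0 ** rng.normal(0.0, 0.5, size=n)
    te_by_cond = {
        "untreated": te_untreated,
        "treated": te_untreated * 2.0 ** truth["true_log2_kev"].to_numpy(),
    }
    # dye swap on the last two replicates: metadata only, no value effect
    swap = {r: r > config.n_replicates - 2 for r in range(1, config.n_replicates + 1)}
    rows = []
    for condition in CONDITIONS:
        for replicate in range(1, config.n_replicates + 1):
            for fraction in FRACTIONS:
                level = base if fraction == "free" else base * te_by_cond[condition]
                intensity = level * _lognoise(config.noise_cv, rng, n)
                if config.outlier_prob > 0:
                    hit = rng.random(n) < config.outlier_prob
                    updown = np.where(rng.random(n) < 0.5, config.outlier_factor,
                                      1.0 / config.outlier_factor)
                    intensity = np.where(hit, intensity * updown, intensity)
                keep = rng.random(n) >= config.missing_prob
                dye = "Cy5/Cy3" if swap[replicate] else "Cy3/Cy5"
                frame = pd.DataFrame(
                    {
                        "gene_id": np.asarray(_gene_ids(n), dtype=object)[keep],
                        "condition": condition,
                        "fraction": fraction,
                        "replicate": replicate,
                        "dye": dye,
                        "intensity": intensity[keep],
                    }
                )
                rows.append(frame)
    measurements = pd.concat(rows, ignore_index=True)
    return measurements, truth


def _plant_site(
    consensus: str, mismatches: int, rng: np.random.Generator
) -> str:
    site = list(consensus)
    if mismatches:
        for pos in rng.choice(len(site), size=mismatches, replace=False):
            choices = [b for b in _BASES if b != site[pos]]
            site[pos] = str(rng.choice(choices))
    return "".join(site)


def simulate_start_regions(
    config: SimulationConfig, analysis: AnalysisConfig | None = None
) -> tuple[list[StartRegionWindow], pd.DataFrame]:
    """Simulate start-region windows with optionally planted SD sites.

    Each gene gets ``window_up + window_down - 3`` nt (start codon already
    removed) drawn i.i.d. from ``config.base_composition`` (A, C, G, T
    order).  With probability ``sd_plant_prob`` the SD consensus (with
    ``sd_plant_mismatches`` random mutations) replaces the upstream bases
    ending ``spacer`` nt before the codon, spacer uniform on
    ``sd_spacer_range``.  Ground truth records the planting and spacer.
    """
    analysis = analysis or AnalysisConfig()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_genes
    up, down = analysis.window_up, analysis.window_down - 3
    lo, hi = config.sd_spacer_range
    if hi + len(analysis.sd_consensus) > up:
        raise ValueError("sd_spacer_range does not fit inside the upstream window")
    p = np.asarray(config.base_composition)
    ids = _gene_ids(n)
    windows, truth_rows = [], []
    for gene_id in ids:
        seq = rng.choice(_BASES, size=up + down, p=p)
        planted = bool(rng.random() < config.sd_plant_prob)
        spacer = None
        if planted:
            spacer = int(rng.integers(lo, hi + 1))
            site = _plant_site(analysis.sd_consensus, config.sd_plant_mismatches, rng)
            end = up - spacer
            seq[end - len(site):end] = list(site)
        s = "".join(seq)
        windows.append(StartRegionWindow(gene_id, s[:up], s[up:], "+"))
        truth_rows.append(
            {"gene_id": gene_id, "sd_planted": planted,
             "sd_spacer": spacer if planted else pd.NA}
        )
    return windows, pd.DataFrame(truth_rows)


def simulate_annotation(
    config: SimulationConfig, classes: pd.Series | dict[str, str] | None = None
) -> pd.DataFrame:
    """Simulate per-gene operon/UTR features; optional per-class enrichment.

    Parameters
    ----------
    classes:
        Optional mapping of gene_id to class label ("sensitive",
        "resistant", ...).  When given and ``operon_config.
        distal_rate_by_class`` names a class, genes of that class become
        distal at the stated rate instead of the global ``frac_distal``
        (the single/first split keeps its relative proportions).

    Returns a frame with columns ``gene_id, listed_in_annotation,
    operon_position, intergenic_distance, utr_length, strand`` —
    the schema consumed by :mod:`kevtools.enrichment`.
    """
    oc = config.operon_config
    rng = np.random.default_rng(config.seed + 2)
    ids = _gene_ids(config.n_genes)
    if classes is not None and not isinstance(classes, dict):
        classes = dict(classes)
    rows = []
    base_probs = np.array([oc.frac_single, oc.frac_first, oc.frac_distal])
    for gene_id in ids:
        probs = base_probs
        cls = classes.get(gene_id) if classes else None
        if cls is not None and cls in oc.distal_rate_by_class:
            distal = oc.distal_rate_by_class[cls]
            rest = oc.frac_single + oc.frac_first
            if rest > 0:
                scale = (1.0 - distal) / rest
                probs = np.array([oc.frac_single * scale, oc.frac_first * scale, distal])
            else:
                probs = np.array([0.0, 0.0, 1.0]) if distal > 0 else base_probs
        position = str(rng.choice(["single", "first", "distal"], p=probs))
        if position == "distal":
            distance = int(rng.geometric(oc.short_distance_p)) + oc.short_distance_shift
        elif position == "first":
            distance = int(rng.geometric(1.0 / oc.long_distance_mean)) + 20
        else:
            distance = None
        if rng.random() < config.leaderless_frac:
            utr = int(rng.integers(0, 8))
        else:
            utr = int(round(2.0 ** rng.normal(config.utr_log2_mean, config.utr_log2_sd)))
        rows.append(
            {
                "gene_id": gene_id,
                "listed_in_annotation": True,
                "operon_position": position,
                "intergenic_distance": distance,
                "utr_length": utr,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    frame = pd.DataFrame(rows)
    frame["intergenic_distance"] = frame["intergenic_distance"].astype("Int64")
    return frame


def windows_from_table(frame: pd.DataFrame, analysis: AnalysisConfig | None = None
                       ) -> list[StartRegionWindow]:
    """Rebuild :class:`StartRegionWindow` objects from a window TSV frame."""
    analysis = analysis or AnalysisConfig()
    up = analysis.window_up
    return [
        StartRegionWindow(
            str(row["gene_id"]), str(row["sequence"])[:up], str(row["sequence"])[up:],
            str(row.get("strand", "+")),
        )
        for _, row in frame.iterrows()
    ]
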