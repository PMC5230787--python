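"""Configuration objects for the analysis and the synthetic-data generator.

Two dataclasses hold every tunable constant of the pipeline:

* :class:`AnalysisConfig` — thresholds of the translatome analysis (CV
  trigger, sensitive/resistant KEV cut-offs, replicate filter, SD consensus
  and scan range, leaderless and intergenic-distance thresholds, window
  geometry around the start codon).
* :class:`SimulationConfig` — the statistical world the synthetic-data
  module draws from (true effect-size distribution, multiplicative noise,
  missingness, gross outliers, base composition, SD planting, operon and
  5'-UTR feature models).

Both can be round-tripped through YAML (:func:`load_config`,
:func:`AnalysisConfig.to_yaml`), with file values overriding defaults
field by field.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "AnalysisConfig",
    "OperonConfig",
    "SimulationConfig",
    "load_config",
]

_DNA = ("A", "C", "G", "T")


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def _finite(name: str, *values: float) -> None:
    for v in values:
        if v is None or not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants of the translatome / start-region analysis.

    Attributes
    ----------
    cv_threshold:
        Coefficient-of-variation (sd/mean) level at or above which a
        gene-condition replicate set is screened for a gross outlier.
    sensitive_max, resistant_min:
        KEV class boundaries; both are inclusive (KEV <= 0.5 sensitive,
        KEV >= 2.0 resistant by default).
    min_replicates, total_replicates:
        A gene is analyzed only if it retains at least ``min_replicates``
        usable translational efficiencies in *both* conditions.
    outlier_k:
        A replicate may be excluded only if it lies more than
        ``outlier_k`` sample standard deviations from the mean of the
        remaining replicates.
    leaderless_strict, leaderless_relaxed:
        5'-UTR length cut-offs (nt) for the strict and relaxed leaderless
        calls.
    intergenic_threshold:
        Intergenic distances below this (nt) are taken as evidence of a
        polycistronic (operonic) arrangement.
    end_tolerance:
        Two mapped 5' ends within this many nt are treated as the same
        transcription start.
    sd_consensus:
        Shine-Dalgarno consensus the detector compares against, 5'->3'.
    sd_min_matches, sd_min_run:
        A candidate site is called present when it has at least
        ``sd_min_matches`` position-wise matches to the consensus or a
        consecutive run of at least ``sd_min_run`` matches.
    sd_scan_min, sd_scan_max:
        Candidate 8-mer 3' ends are scanned from ``sd_scan_min`` to
        ``sd_scan_max`` nt upstream of the start codon.
    window_up, window_down:
        Start-region window geometry: ``window_up`` nt upstream of the
        start codon plus the first ``window_down`` nt of the ORF, with the
        3-nt start codon removed (so ``window_down - 3`` nt are kept).
    histogram_bin_width:
        Bin width (log2 units) of the KEV distribution histogram.
    """

    cv_threshold: float = 0.60
    sensitive_max: float = 0.5
    resistant_min: float = 2.0
    min_replicates: int = 3
    total_replicates: int = 5
    outlier_k: float = 2.0
    leaderless_strict: int = 4
    leaderless_relaxed: int = 7
    intergenic_threshold: int = 15
    end_tolerance: int = 3
    sd_consensus: str = "TAAGGAGG"
    sd_min_matches: int = 5
    sd_min_run: int = 4
    sd_scan_min: int = 2
    sd_scan_max: int = 12
    window_up: int = 40
    window_down: int = 40
    histogram_bin_width: float = 0.25

    def __post_init__(self) -> None:
        _finite("cv_threshold", self.cv_threshold)
        _finite("KEV thresholds", self.sensitive_max, self.resistant_min)
        _require(
            0 < self.sensitive_max < 1 < self.resistant_min,
            "need 0 < sensitive_max < 1 < resistant_min",
        )
        _require(self.cv_threshold > 0, "cv_threshold must be positive")
        _require(
            1 <= self.min_replicates <= self.total_replicates,
            "min_replicates must be in [1, total_replicates]",
        )
        _require(self.outlier_k > 0, "outlier_k must be positive")
        _require(
            0 <= self.leaderless_strict <= self.leaderless_relaxed,
            "leaderless thresholds must satisfy 0 <= strict <= relaxed",
        )
        _require(self.intergenic_threshold > 0, "intergenic_threshold must be positive")
        _require(self.end_tolerance >= 0, "end_tolerance must be >= 0")
        _require(
            len(self.sd_consensus) > 0 and set(self.sd_consensus) <= set(_DNA),
            "sd_consensus must be a non-empty A/C/G/T string",
        )
        _require(
            1 <= self.sd_min_run <= len(self.sd_consensus)
            and 1 <= self.sd_min_matches <= len(self.sd_consensus),
            "SD match thresholds must be within the consensus length",
        )
        _require(
            0 <= self.sd_scan_min <= self.sd_scan_max,
            "need 0 <= sd_scan_min <= sd_scan_max",
        )
        _require(self.window_up > 0 and self.window_down > 3, "window too small")
        _require(self.histogram_bin_width > 0, "histogram_bin_width must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"analysis": dataclasses.asdict(self)}, sort_keys=False)
        )


@dataclass(frozen=True)
class OperonConfig:
    """Operon-position and intergenic-distance model of the simulator.

    ``frac_single + frac_first + frac_distal`` must be 1.  Distal genes draw
    short intergenic distances (geometric, shifted to allow overlaps as
    negative values); first-in-operon genes draw long distances.  Per-class
    distal enrichment can be planted via ``distal_rate_by_class``, mapping a
    class label to a replacement distal fraction.
    """

    frac_single: float = 0.35
    frac_first: float = 0.35
    frac_distal: float = 0.30
    distal_rate_by_class: dict[str, float] = field(default_factory=dict)
    short_distance_p: float = 0.10
    short_distance_shift: int = -4
    long_distance_mean: float = 120.0

    def __post_init__(self) -> None:
        fr = (self.frac_single, self.frac_first, self.frac_distal)
        _finite("operon fractions", *fr)
        _require(all(0 <= f <= 1 for f in fr), "operon fractions must be in [0,1]")
        _require(abs(sum(fr) - 1.0) < 1e-9, "operon fractions must sum to 1")
        _require(0 < self.short_distance_p <= 1, "short_distance_p in (0,1]")
        _require(self.long_distance_mean > 0, "long_distance_mean must be positive")
        for cls, rate in self.distal_rate_by_class.items():
            _require(0 <= rate <= 1, f"distal rate for {cls!r} must be in [0,1]")


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world the synthetic translatome is drawn from.

    Defaults mirror the experimental design being emulated: five biological
    replicates (two of them dye-swapped), multiplicative intensity noise,
    occasional gross outlier measurements, genome background base
    composition near 0.29 A / 0.23 G / 0.22 C / 0.26 T, and SD motifs
    planted 3-7 nt upstream of the start codon.
    """

    n_genes: int = 2801
    n_replicates: int = 5
    frac_sensitive: float = 0.036
    frac_resistant: float = 0.049
    log2_kev_sd: float = 0.55
    effect_log2: float = 2.0
    noise_cv: float = 0.20
    missing_prob: float = 0.05
    outlier_prob: float = 0.01
    outlier_factor: float = 8.0
    seed: int = 0
    # base_composition order is A, C, G, T
    base_composition: tuple[float, float, float, float] = (0.29, 0.22, 0.23, 0.26)
    sd_plant_prob: float = 0.55
    sd_plant_mismatches: int = 0
    sd_spacer_range: tuple[int, int] = (3, 7)
    utr_log2_mean: float = 5.9
    utr_log2_sd: float = 1.0
    leaderless_frac: float = 0.02
    operon_config: OperonConfig = field(default_factory=OperonConfig)

    def __post_init__(self) -> None:
        _require(self.n_genes >= 1, "n_genes must be >= 1")
        _require(self.n_replicates >= 1, "n_replicates must be >= 1")
        probs = (
            self.frac_sensitive,
            self.frac_resistant,
            self.missing_prob,
            self.outlier_prob,
            self.sd_plant_prob,
            self.leaderless_frac,
        )
        _finite("probabilities", *probs)
        _require(all(0 <= p <= 1 for p in probs), "probabilities must be in [0,1]")
        _require(
            self.frac_sensitive + self.frac_resistant <= 1,
            "planted fractions must not exceed 1",
        )
        _finite(
            "dispersion/noise parameters",
            self.log2_kev_sd,
            self.effect_log2,
            self.noise_cv,
            self.outlier_factor,
            self.utr_log2_mean,
            self.utr_log2_sd,
        )
        _require(self.log2_kev_sd >= 0, "log2_kev_sd must be >= 0")
        _require(self.noise_cv >= 0, "noise_cv must be >= 0")
        _require(self.outlier_factor > 1, "outlier_factor must exceed 1")
        _finite("base_composition", *self.base_composition)
        _require(
            len(self.base_composition) == 4
            and all(p >= 0 for p in self.base_composition)
            and abs(sum(self.base_composition) - 1.0) < 1e-9,
            "base_composition must be 4 non-negative values summing to 1",
        )
        lo, hi = self.sd_spacer_range
        _require(0 <= lo <= hi, "sd_spacer_range must be a non-empty interval")
        _require(
            0 <= self.sd_plant_mismatches < 4,
            "sd_plant_mismatches must be in [0, 3]",
        )


def load_config(path: str | Path) -> tuple[AnalysisConfig, SimulationConfig]:
    """Read a YAML config file; missing fields keep their defaults.

    The file may carry ``analysis:`` and/or ``simulation:`` mappings whose
    keys match the dataclass fields; ``simulation.operon_config`` nests an
    :class:`OperonConfig` mapping.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    analysis = AnalysisConfig(**(raw.get("analysis") or {}))
    sim_raw = dict(raw.get("simulation") or {})
    if "operon_config" in sim_raw and isinstance(sim_raw["operon_config"], dict):
        sim_raw["operon_config"] = OperonConfig(**sim_raw["operon_config"])
    for key in ("base_composition", "sd_spacer_range"):
        if key in sim_raw and isinstance(sim_raw[key], list):
            sim_raw[key] = tuple(sim_raw[key])
    simulation = SimulationConfig(**sim_raw)
    return analysis, simulation
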