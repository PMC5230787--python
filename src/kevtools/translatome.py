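"""Translational efficiencies, Kasugamycin effect values and gene classes.

The analysis follows the classic polysome-fractionation design: for every
gene and biological replicate two intensity measurements exist per
condition (untreated / antibiotic-treated), one for the free-mRNA fraction
and one for the polysomal fraction.  The per-replicate translational
efficiency (TE) is the polysomal/free quotient.  Per condition the TEs are
averaged, screened for gross outliers when the coefficient of variation is
high, and the treated/untreated ratio of the two condition means gives the
per-gene drug effect.  After median-centering in log2 space (so an effect
value of 1 means "average drug effect" by construction) genes at least
two-fold below the average effect are classed sensitive and genes at least
two-fold above it resistant.  Effect values are reported as KEVs
(Kasugamycin effect values) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

__all__ = [
    "CLASS_LABELS",
    "GeneConditionSummary",
    "KEVRecord",
    "translational_efficiency",
    "summarize_condition",
    "replicate_filter",
    "compute_kevs",
    "classify",
    "kev_test",
    "kev_distribution",
    "kev_table",
]

CLASS_LABELS = ("sensitive", "average", "resistant", "excluded")


def translational_efficiency(polysomal_intensity: float, free_intensity: float) -> float:
    """Polysomal/free intensity quotient, or NaN when undefined.

    Zero, negative, missing or non-finite intensities make the replicate's
    TE undefined; ``nan`` is returned so the replicate is dropped rather
    than recorded as zero.
    """
    try:
        p = float(polysomal_intensity)
        f = float(free_intensity)
    except (TypeError, ValueError):
        return math.nan
    if not (math.isfinite(p) and math.isfinite(f)) or p <= 0 or f <= 0:
        return math.nan
    return p / f


@dataclass
class GeneConditionSummary:
    """Per-gene, per-condition TE summary after outlier screening.

    ``te_values`` are the retained per-replicate TEs; ``excluded_replicates``
    lists ``(te_value, reason)`` pairs for measurements that were dropped.
    ``usable`` is False when no finite TE existed at all.
    """

    gene_id: str
    condition: str
    te_values: list[float]
    n_used: int
    mean_te: float
    sd_te: float
    cv: float
    excluded_replicates: list[tuple[float, str]] = field(default_factory=list)
    high_cv: bool = False
    usable: bool = True


def _mean_sd_cv(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size >= 2 else 0.0
    cv = sd / mean if mean > 0 else math.inf
    return mean, sd, cv


def summarize_condition(
    te_values: list[float], config: AnalysisConfig, *, gene_id: str = "", condition: str = ""
) -> GeneConditionSummary:
    """Summarize one condition's replicate TEs with CV-triggered outlier removal.

    The mean, sample standard deviation (n-1 denominator) and coefficient
    of variation are computed over all finite TEs.  When the CV reaches
    ``config.cv_threshold`` and at least four values are present, the single
    value whose removal reduces the CV the most is excluded, provided it
    lies more than ``config.outlier_k`` standard deviations from the mean
    of the remaining values.  The rule is applied at most once — a
    reproducible surrogate for removing "obvious outliers" by eye.
    """
    raw = [math.nan if v is None else float(v) for v in te_values]
    finite = np.array([v for v in raw if math.isfinite(v) and v > 0], dtype=float)
    excluded: list[tuple[float, str]] = [
        (v, "undefined TE") for v in raw if not (math.isfinite(v) and v > 0)
    ]
    if finite.size == 0:
        return GeneConditionSummary(
            gene_id, condition, [], 0, math.nan, math.nan, math.nan,
            excluded, high_cv=False, usable=False,
        )

    mean, sd, cv = _mean_sd_cv(finite)
    high_cv = cv >= config.cv_threshold
    if high_cv and finite.size >= 4:
        best_idx, best_cv = -1, cv
        for i in range(finite.size):
            others = np.delete(finite, i)
            _, _, cv_i = _mean_sd_cv(others)
            if cv_i < best_cv:
                best_idx, best_cv = i, cv_i
        if best_idx >= 0:
            others = np.delete(finite, best_idx)
            gap = abs(finite[best_idx] - float(np.mean(others)))
            if gap > config.outlier_k * float(np.std(others, ddof=1)):
                excluded.append((float(finite[best_idx]), "outlier"))
                finite = others
                mean, sd, cv = _mean_sd_cv(finite)
                high_cv = cv >= config.cv_threshold

    return GeneConditionSummary(
        gene_id, condition, finite.tolist(), int(finite.size),
        mean, sd, cv, excluded, high_cv=high_cv, usable=True,
    )


def replicate_filter(
    summary_untreated: GeneConditionSummary,
    summary_treated: GeneConditionSummary,
    config: AnalysisConfig,
) -> bool:
    """True when both conditions retain at least ``min_replicates`` TEs."""
    return (
        summary_untreated.usable
        and summary_treated.usable
        and summary_untreated.n_used >= config.min_replicates
        and summary_treated.n_used >= config.min_replicates
    )


@dataclass
class KEVRecord:
    """Per-gene normalized drug-effect result."""

    gene_id: str
    kev: float
    log2_kev: float
    class_label: str
    p_value: float | None
    n_untreated: int
    n_treated: int


def classify(kev: float, config: AnalysisConfig) -> str:
    """Class label for a KEV; both thresholds are inclusive."""
    if not (isinstance(kev, (int, float)) and math.isfinite(kev) and kev > 0):
        return "excluded"
    if kev <= config.sensitive_max:
        return "sensitive"
    if kev >= config.resistant_min:
        return "resistant"
    return "average"


def kev_test(te_untreated: list[float], te_treated: list[float]) -> float | None:
    """Two-sided Welch t-test on log2 TEs; None when a side has < 2 values.

    The log scale is used because TEs are strictly positive ratios; Welch's
    unequal-variance form avoids assuming the two conditions share a
    replicate variance.
    """
    a = np.log2(np.asarray(te_untreated, dtype=float))
    b = np.log2(np.asarray(te_treated, dtype=float))
    if a.size < 2 or b.size < 2:
        return None
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def compute_kevs(
    summaries: dict[str, tuple[GeneConditionSummary, GeneConditionSummary]],
    config: AnalysisConfig,
) -> list[KEVRecord]:
    """Normalized KEVs for every gene passing the replicate filter.

    Parameters
    ----------
    summaries:
        Mapping ``gene_id -> (untreated summary, treated summary)``; only
        genes that passed :func:`replicate_filter` should be included.

    The raw per-gene ratio is ``mean_te(treated) / mean_te(untreated)``.
    Normalization subtracts the median of the raw log2 ratios from every
    gene, so the median log2 KEV is exactly 0 — the analogue of scaling
    the two channels so that a value of one represents the average drug
    effect.
    """
    if not summaries:
        raise ValueError("compute_kevs requires at least one passing gene")
    gene_ids: list[str] = []
    raw_log2: list[float] = []
    meta: list[tuple[float | None, int, int]] = []
    for gene_id, (su, st) in summaries.items():
        if not (su.mean_te > 0 and st.mean_te > 0):
            continue  # zero/invalid mean TE: cannot form the ratio
        gene_ids.append(gene_id)
        raw_log2.append(math.log2(st.mean_te / su.mean_te))
        meta.append((kev_test(su.te_values, st.te_values), su.n_used, st.n_used))
    if not gene_ids:
        raise ValueError("no gene had positive mean TEs in both conditions")
    centered = np.asarray(raw_log2) - float(np.median(raw_log2))
    records = []
    for gene_id, log2_kev, (p, n_u, n_t) in zip(gene_ids, centered, meta):
        kev = float(2.0 ** log2_kev)
        records.append(
            KEVRecord(gene_id, kev, float(log2_kev), classify(kev, config), p, n_u, n_t)
        )
    return records


def kev_distribution(
    records: list[KEVRecord], bin_width: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin edges) of log2 KEVs.

    Bin edges are aligned to multiples of ``bin_width`` so that 0 always
    falls on an edge-aligned grid; counts sum to the number of records.
    """
    if not records:
        raise ValueError("kev_distribution requires at least one record")
    values = np.array([r.log2_kev for r in records], dtype=float)
    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


def kev_table(
    summaries: dict[str, tuple[GeneConditionSummary, GeneConditionSummary]],
    records: list[KEVRecord],
    excluded: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flat per-gene results table (one row per input gene, no silent drops).

    Mirrors the structure of a per-gene supplementary results sheet:
    retained per-replicate TEs for both conditions, means, sds, CVs,
    exclusion notes, KEV, log2 KEV, class and p-value.  Genes that failed
    the replicate filter appear with class ``excluded`` and their reason.
    """
    by_gene = {r.gene_id: r for r in records}
    rows = []
    for gene_id, (su, st) in summaries.items():
        rec = by_gene.get(gene_id)
        reason = (excluded or {}).get(gene_id, "")
        rows.append(
            {
                "gene_id": gene_id,
                "te_untreated": ";".join(f"{v:.6g}" for v in su.te_values),
                "te_treated": ";".join(f"{v:.6g}" for v in st.te_values),
                "n_untreated": su.n_used,
                "n_treated": st.n_used,
                "mean_te_untreated": su.mean_te,
                "mean_te_treated": st.mean_te,
                "sd_te_untreated": su.sd_te,
                "sd_te_treated": st.sd_te,
                "cv_untreated": su.cv,
                "cv_treated": st.cv,
                "excluded_untreated": ";".join(f"{v:.6g}:{r}" for v, r in su.excluded_replicates),
                "excluded_treated": ";".join(f"{v:.6g}:{r}" for v, r in st.excluded_replicates),
                "kev": rec.kev if rec else math.nan,
                "log2_kev": rec.log2_kev if rec else math.nan,
                "class": rec.class_label if rec else "excluded",
                "p_value": rec.p_value if rec and rec.p_value is not None else math.nan,
                "exclusion_reason": reason if rec is None else "",
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id", kind="stable").reset_index(drop=True)
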