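"""Group-level annotation-feature summaries and association tests.

Compares sensitive vs resistant gene groups over operon-derived features:
fraction of genes lying distal (non-first) in a polycistronic transcript,
fraction with a short intergenic distance to the upstream gene (a proxy
for operonic continuity and hence possible translational coupling),
leaderless counts at the strict/relaxed 5'-UTR thresholds, and mean 5'-UTR
length.  A two-sided Fisher exact test quantifies group x feature
association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

__all__ = [
    "GeneFeatureRecord",
    "GroupSummary",
    "round_percent",
    "summarize_group",
    "summary_table",
    "association_test",
    "intergenic_distance",
]

OPERON_POSITIONS = ("single", "first", "distal", "unknown")


@dataclass(frozen=True)
class GeneFeatureRecord:
    """Annotation-derived features for one gene.

    ``intergenic_distance`` counts the nt between the annotated end of the
    upstream same-strand gene and the annotated start of this gene;
    negative values mean the genes overlap.  ``None`` when no upstream
    same-strand neighbour applies (e.g. single genes).
    ``listed_in_annotation`` marks genes present in the external operon
    annotation; genes absent from it still count in group totals but not
    in operon-position denominators.
    """

    gene_id: str
    listed_in_annotation: bool = True
    operon_position: str = "unknown"
    intergenic_distance: float | None = None
    utr_lengths: tuple[int, ...] = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.operon_position not in OPERON_POSITIONS:
            raise ValueError(
                f"gene {self.gene_id}: operon_position must be one of {OPERON_POSITIONS}"
            )


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_total: int
    n_listed: int
    n_distal: int
    pct_distal: int | None
    n_short_intergenic: int
    pct_short_intergenic: int | None
    n_leaderless_strict: int
    n_leaderless_relaxed: int
    mean_utr_length: float | None


def round_percent(count: int, denominator: int) -> int | None:
    """Percentage rounded half-up to an integer; None for a zero denominator."""
    if denominator == 0:
        return None
    return int(math.floor(100.0 * count / denominator + 0.5))


def intergenic_distance(gene_start: int, upstream_gene_end: int) -> int:
    """Nt between two same-strand neighbours, 1-based inclusive coordinates.

    ``gene_start - upstream_gene_end - 1``; adjacent genes give 0 and
    overlapping genes a negative value.
    """
    return int(gene_start) - int(upstream_gene_end) - 1


def summarize_group(
    records: list[GeneFeatureRecord],
    group: str,
    config: AnalysisConfig | None = None,
) -> GroupSummary:
    """Feature counts and percentages for one gene group.

    Denominators differ by feature: operon position is only known for
    genes listed in the external annotation (``n_listed``), while the
    intergenic-distance criterion comes from the genome annotation and
    uses the full group (``n_total``).  Overlapping genes (negative
    distance) satisfy the short-distance criterion.  Percentages are
    rounded half-up to integers.
    """
    config = config or AnalysisConfig()
    n_total = len(records)
    listed = [r for r in records if r.listed_in_annotation]
    n_distal = sum(1 for r in listed if r.operon_position == "distal")
    n_short = sum(
        1
        for r in records
        if r.intergenic_distance is not None
        and r.intergenic_distance < config.intergenic_threshold
    )
    utrs = [min(r.utr_lengths) for r in records if r.utr_lengths]
    n_strict = sum(1 for u in utrs if u <= config.leaderless_strict)
    n_relaxed = sum(1 for u in utrs if u <= config.leaderless_relaxed)
    return GroupSummary(
        group=group,
        n_total=n_total,
        n_listed=len(listed),
        n_distal=n_distal,
        pct_distal=round_percent(n_distal, len(listed)),
        n_short_intergenic=n_short,
        pct_short_intergenic=round_percent(n_short, n_total),
        n_leaderless_strict=n_strict,
        n_leaderless_relaxed=n_relaxed,
        mean_utr_length=float(np.mean(utrs)) if utrs else None,
    )


def summary_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Feature-by-group table in the style of a published feature summary."""
    rows = {
        "No. genes in group": lambda s: s.n_total,
        "Listed in operon annotation": lambda s: s.n_listed,
        "Distal in polycistronic transcript": lambda s: (
            f"{s.n_distal} ({s.pct_distal}%)" if s.pct_distal is not None else f"{s.n_distal}"
        ),
        "Intergenic distance short": lambda s: (
            f"{s.n_short_intergenic} ({s.pct_short_intergenic}%)"
            if s.pct_short_intergenic is not None
            else f"{s.n_short_intergenic}"
        ),
        "Leaderless (strict)": lambda s: s.n_leaderless_strict,
        "Leaderless (relaxed)": lambda s: s.n_leaderless_relaxed,
        "Average 5'-UTR length [nt]": lambda s: (
            round(s.mean_utr_length) if s.mean_utr_length is not None else ""
        ),
    }
    return pd.DataFrame(
        {s.group: [fn(s) for fn in rows.values()] for s in summaries},
        index=list(rows.keys()),
    )


def association_test(table: list[list[int]] | np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p_value)``.  The odds ratio is the sample
    estimate ``(a*d)/(b*c)``; when any cell is zero, 0.5 is added to every
    cell (Haldane-Anscombe correction) before forming the ratio.  The
    p-value sums hypergeometric probabilities of all tables with the same
    margins that are no more probable than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("association_test requires a 2x2 table")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("counts must be non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    a, b = t[0]
    c, d = t[1]
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds), float(p)
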