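"""Relative-entropy (structure-logo-style) matrices for start-region sets.

For a set of aligned start-region windows the per-position deviation from
the set's own base composition is quantified as the Kullback-Leibler
divergence in bits,

    I(pos) = sum_b q_b(pos) * log2( q_b(pos) / p_b ),

where q is the observed per-position base frequency and p the background
frequency pooled over all positions of all windows in the set.  Letter
heights are signed: ``height_b = sign(q_b - p_b) * q_b * I(pos)``, drawn
upright when a base is over-represented relative to expectation and
inverted when under-represented.  The absolute heights at a position sum
to its information content.

With a uniform background the information reduces to ``2 - H(q)`` — the
familiar Shannon sequence-logo height.

A pseudocount of 0.5 per base is added to the per-position counts and to
the pooled background counts, so small gene sets with empty cells never
produce log(0).  ``N`` bases are excluded from all counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .start_region import StartRegionWindow

__all__ = [
    "BASES",
    "BackgroundModel",
    "LogoColumn",
    "background_frequencies",
    "column_information",
    "logo_matrix",
    "max_information_position",
    "export_logo",
    "read_logo",
]

BASES = ("A", "C", "G", "T")
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class BackgroundModel:
    """Background base probabilities (A, C, G, T), summing to 1."""

    p: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.p) != 4 or any(v <= 0 for v in self.p):
            raise ValueError("background probabilities must be 4 positive values")
        if abs(sum(self.p) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")


@dataclass(frozen=True)
class LogoColumn:
    """One alignment position of the logo matrix.

    ``position`` labels run -window_up..-1 then +4..+(window_down); the
    +1..+3 labels are absent because the start codon was removed from the
    windows.
    """

    position: int
    q: tuple[float, float, float, float]
    information_bits: float
    heights: tuple[float, float, float, float]


def _position_labels(n_up: int, n_down: int) -> list[int]:
    return list(range(-n_up, 0)) + list(range(4, 4 + n_down))


def _counts(windows: list[StartRegionWindow]) -> np.ndarray:
    length = len(windows[0].sequence)
    counts = np.zeros((length, 4))
    index = {b: i for i, b in enumerate(BASES)}
    bad = [w.gene_id for w in windows if len(w.sequence) != length]
    if bad:
        raise ValueError(f"window length mismatch for genes: {', '.join(bad)}")
    for w in windows:
        for pos, base in enumerate(w.sequence):
            i = index.get(base)
            if i is not None:
                counts[pos, i] += 1
    return counts


def background_frequencies(windows: list[StartRegionWindow]) -> BackgroundModel:
    """Pooled base composition of a window set (the logo's expectation).

    Counts are pooled over every position of every window, N excluded,
    with a 0.5 pseudocount per base so no probability is ever zero.
    """
    if not windows:
        raise ValueError("background_frequencies requires at least one window")
    pooled = _counts(windows).sum(axis=0) + PSEUDOCOUNT
    p = pooled / pooled.sum()
    return BackgroundModel(tuple(float(v) for v in p))


def column_information(
    q: tuple[float, float, float, float] | np.ndarray,
    p: tuple[float, float, float, float] | np.ndarray,
) -> tuple[float, tuple[float, float, float, float]]:
    """Relative entropy (bits) and signed letter heights for one position.

    ``0 * log(0)`` is treated as 0.  Heights carry the sign of
    ``q_b - p_b`` (ties count as over-represented so the conservation
    identity sum(|height|) = information always holds).
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0) / p), 0.0)
    info = float(max(terms.sum(), 0.0))
    signs = np.where(q >= p, 1.0, -1.0)
    heights = signs * q * info
    return info, tuple(float(h) for h in heights)


def logo_matrix(
    windows: list[StartRegionWindow], background: BackgroundModel | None = None
) -> list[LogoColumn]:
    """Per-position relative-entropy columns for a set of aligned windows."""
    if len(windows) < 2:
        raise ValueError("logo_matrix requires at least two windows")
    if background is None:
        background = background_frequencies(windows)
    counts = _counts(windows) + PSEUDOCOUNT
    q_all = counts / counts.sum(axis=1, keepdims=True)
    n_up = len(windows[0].upstream_seq)
    n_down = len(windows[0].downstream_seq)
    labels = _position_labels(n_up, n_down)
    p = np.asarray(background.p)
    columns = []
    for label, q in zip(labels, q_all):
        info, heights = column_information(q, p)
        columns.append(LogoColumn(label, tuple(float(v) for v in q), info, heights))
    return columns


def max_information_position(columns: list[LogoColumn]) -> LogoColumn:
    """Column with the highest information; ties go to the most upstream."""
    if not columns:
        raise ValueError("no logo columns")
    return max(columns, key=lambda c: (c.information_bits, -c.position))


def export_logo(columns: list[LogoColumn], path: str | Path) -> pd.DataFrame:
    """Write the logo matrix as TSV; returns the frame that was written.

    Columns: position (codon-removed labelling), q_A..q_T,
    information_bits, height_A..height_T.  The file header records the
    maximum-information position in a ``# max_information`` comment line.
    """
    if not columns:
        raise ValueError("export_logo requires at least one column")
    frame = pd.DataFrame(
        {
            "position": [c.position for c in columns],
            **{f"q_{b}": [c.q[i] for c in columns] for i, b in enumerate(BASES)},
            "information_bits": [c.information_bits for c in columns],
            **{f"height_{b}": [c.heights[i] for c in columns] for i, b in enumerate(BASES)},
        }
    )
    top = max_information_position(columns)
    best_base = BASES[int(np.argmax(np.abs(top.heights)))]
    with open(path, "w") as fh:
        fh.write(
            f"# max_information\t{top.information_bits:.6g} bit for "
            f"{best_base} at {top.position:+d}\n"
        )
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return frame


def read_logo(path: str | Path) -> list[LogoColumn]:
    """Read a matrix written by :func:`export_logo` back into columns."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    columns = []
    for _, row in frame.iterrows():
        columns.append(
            LogoColumn(
                int(row["position"]),
                tuple(float(row[f"q_{b}"]) for b in BASES),
                float(row["information_bits"]),
                tuple(float(row[f"height_{b}"]) for b in BASES),
            )
        )
    return columns
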