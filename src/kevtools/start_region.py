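"""Start-codon-centered sequence windows and Shine-Dalgarno analysis.

A start-region window covers ``window_up`` nt upstream of the start codon
plus the first ``window_down`` nt of the open reading frame, with the 3-nt
start codon itself removed (40 + 37 = 77 nt by default).  Reverse-strand
genes are reverse-complemented before storage, so the window always reads
5'->3' in the mRNA sense.

The SD detector compares candidate 8-mers upstream of the start codon
position-wise (ungapped) against the purine-rich consensus ``TAAGGAGG``
and calls a motif present when the best candidate has at least 5 matches
or a consecutive match run of at least 4.  The criterion is configurable
(:class:`~kevtools.config.AnalysisConfig`); the 5-or-run-4 default
reproduces expert yes/no calls on experimentally mapped 5'-UTRs.

Coordinate convention: 1-based inclusive in all reported fields, 0-based
half-open only inside this module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .config import AnalysisConfig

__all__ = [
    "StartRegionWindow",
    "SDCall",
    "UTRRecord",
    "extract_window",
    "score_sd_site",
    "detect_sd",
    "classify_leaderless",
    "same_5p_end",
]

_START_CODONS = {"ATG", "GTG", "TTG"}


@dataclass(frozen=True)
class StartRegionWindow:
    """77-nt window around a start codon (codon removed).

    ``upstream_seq`` ends at position -1 (immediately 5' of the start
    codon); ``downstream_seq`` begins at position +4 (first base after the
    codon).  ``start_coord`` is the 1-based coordinate, on the forward
    strand of the source record, of the first base of the start codon.
    ``padded`` flags windows that ran off the sequence edge and were filled
    with N.
    """

    gene_id: str
    upstream_seq: str
    downstream_seq: str
    strand: str
    record_id: str = ""
    start_coord: int = 0
    padded: bool = False

    @property
    def sequence(self) -> str:
        return self.upstream_seq + self.downstream_seq


@dataclass(frozen=True)
class SDCall:
    """Best Shine-Dalgarno candidate for one gene.

    ``distance_to_aug`` counts the nt strictly between the site's 3' end
    and the first base of the start codon.
    """

    gene_id: str
    present: bool
    site_seq: str
    distance_to_aug: int | None
    total_matches: int
    longest_run: int
    reason: str = ""


@dataclass(frozen=True)
class UTRRecord:
    gene_id: str
    utr_lengths: tuple[int, ...]
    leaderless_strict: bool
    leaderless_relaxed: bool


def extract_window(
    genome: dict[str, str],
    gene_id: str,
    record_id: str,
    start_coord: int,
    strand: str,
    config: AnalysisConfig | None = None,
) -> StartRegionWindow:
    """Cut the start-region window for one gene out of a genome.

    Parameters
    ----------
    genome:
        Mapping of record id to forward-strand sequence.
    start_coord:
        1-based forward-strand coordinate of the first base of the start
        codon in the gene's reading direction (for a minus-strand gene this
        is the *highest* coordinate of the codon).
    strand:
        ``'+'`` or ``'-'``.

    Windows that would run past a sequence end are padded with ``N`` and
    flagged.  An annotated start codon outside {ATG, GTG, TTG} raises a
    warning, not an error.
    """
    config = config or AnalysisConfig()
    if record_id not in genome:
        raise KeyError(f"gene {gene_id}: record {record_id!r} not in genome")
    if strand not in {"+", "-"}:
        raise ValueError(f"gene {gene_id}: strand must be '+' or '-', got {strand!r}")
    seq = genome[record_id].upper()
    n = len(seq)
    up, down = config.window_up, config.window_down - 3
    s = start_coord - 1  # 0-based index of first codon base in reading direction

    def _slice(lo: int, hi: int) -> tuple[str, bool]:
        pad_left = max(0, -lo)
        pad_right = max(0, hi - n)
        core = seq[max(lo, 0):min(hi, n)]
        return "N" * pad_left + core + "N" * pad_right, (pad_left or pad_right) > 0

    if strand == "+":
        upstream, pad_u = _slice(s - up, s)
        codon = seq[s:s + 3]
        downstream, pad_d = _slice(s + 3, s + 3 + down)
    else:
        upstream_f, pad_u = _slice(s + 1, s + 1 + up)
        codon = str(Seq(seq[max(s - 2, 0):s + 1]).reverse_complement())
        downstream_f, pad_d = _slice(s - 2 - down, s - 2)
        upstream = str(Seq(upstream_f).reverse_complement())
        downstream = str(Seq(downstream_f).reverse_complement())

    if codon not in _START_CODONS:
        warnings.warn(
            f"gene {gene_id}: annotated start codon {codon!r} is not ATG/GTG/TTG",
            stacklevel=2,
        )
    return StartRegionWindow(
        gene_id, upstream, downstream, strand, record_id, start_coord,
        padded=bool(pad_u or pad_d),
    )


def score_sd_site(site_seq: str, consensus: str = "TAAGGAGG") -> tuple[int, int]:
    """Position-wise (ungapped) match count and longest run vs the consensus.

    ``N`` never counts as a match.  The site is aligned to the consensus at
    offset 0; both must have equal length.
    """
    site = site_seq.upper()
    if len(site) != len(consensus):
        raise ValueError(
            f"site length {len(site)} != consensus length {len(consensus)}"
        )
    total = run = best_run = 0
    for a, b in zip(site, consensus):
        if a == b and a != "N":
            total += 1
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0
    return total, best_run


def sd_present(total_matches: int, longest_run: int, config: AnalysisConfig) -> bool:
    return total_matches >= config.sd_min_matches or longest_run >= config.sd_min_run


def detect_sd(
    upstream_seq: str, config: AnalysisConfig | None = None, *, gene_id: str = ""
) -> SDCall:
    """Scan the region upstream of a start codon for the best SD candidate.

    ``upstream_seq`` must end at position -1 (immediately before the start
    codon) — exactly the ``upstream_seq`` of a :class:`StartRegionWindow`
    or a full 5'-UTR.  Candidate 8-mers whose 3' ends lie
    ``sd_scan_min``..``sd_scan_max`` nt upstream of the codon are scored
    with :func:`score_sd_site`; the winner maximizes (total matches,
    longest run, smaller distance).  Sequences too short for even one
    candidate yield ``present=False`` with reason ``"too short"`` —
    leaderless inputs are legitimate.
    """
    config = config or AnalysisConfig()
    seq = upstream_seq.upper()
    k = len(config.sd_consensus)
    best: tuple[int, int, int] | None = None  # (total, run, -distance)
    best_site, best_dist = "", None
    for dist in range(config.sd_scan_min, config.sd_scan_max + 1):
        end = len(seq) - dist
        if end - k < 0:
            break
        site = seq[end - k:end]
        total, run = score_sd_site(site, config.sd_consensus)
        key = (total, run, -dist)
        if best is None or key > best:
            best, best_site, best_dist = key, site, dist
    if best is None:
        return SDCall(gene_id, False, "", None, 0, 0, reason="too short")
    total, run, _ = best
    return SDCall(gene_id, sd_present(total, run, config), best_site, best_dist, total, run)


def classify_leaderless(
    utr_length: int, config: AnalysisConfig | None = None, *, gene_id: str = ""
) -> UTRRecord:
    """Strict/relaxed leaderless flags for one 5'-UTR length.

    Strict means the UTR is at most ``leaderless_strict`` nt (default 4),
    relaxed at most ``leaderless_relaxed`` nt (default 7); strict implies
    relaxed.
    """
    config = config or AnalysisConfig()
    length = int(utr_length)
    if length < 0 or (isinstance(utr_length, float) and not math.isfinite(utr_length)):
        raise ValueError(f"gene {gene_id}: UTR length must be >= 0, got {utr_length}")
    return UTRRecord(
        gene_id,
        (length,),
        leaderless_strict=length <= config.leaderless_strict,
        leaderless_relaxed=length <= config.leaderless_relaxed,
    )


def same_5p_end(len_a: int, len_b: int, config: AnalysisConfig | None = None) -> bool:
    """Whether two mapped 5'-UTR lengths represent the same transcript end.

    Small mapping differences (default tolerance 3 nt) are regarded as
    insignificant; larger differences indicate distinct 5' ends, e.g. two
    promoters or a processing product.
    """
    config = config or AnalysisConfig()
    if len_a < 0 or len_b < 0:
        raise ValueError("UTR lengths must be >= 0")
    return abs(int(len_a) - int(len_b)) <= config.end_tolerance
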