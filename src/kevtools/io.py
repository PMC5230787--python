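"""Readers and writers for the pipeline's file formats.

Measurements travel as TSV (``gene_id, condition, fraction, replicate,
dye, intensity``), genomes as FASTA, gene annotation as GFF3 (gene
features, attributes carrying the feature columns) or an explicit-column
TSV, start-region sequences as FASTA with ``key=value`` description
fields, and every analysis output as TSV with "." decimal separators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import GeneFeatureRecord
from .simulate import CONDITIONS, FRACTIONS
from .start_region import StartRegionWindow

__all__ = [
    "GeneCoordinates",
    "read_measurements",
    "write_measurements",
    "read_genome",
    "write_genome",
    "read_annotation",
    "write_annotation_tsv",
    "write_windows",
    "write_windows_fasta",
    "read_windows_fasta",
    "reference_start_sites",
]

MEASUREMENT_COLUMNS = ["gene_id", "condition", "fraction", "replicate", "dye", "intensity"]
ANNOTATION_COLUMNS = [
    "gene_id", "record_id", "start", "end", "strand",
    "operon_position", "intergenic_distance", "utr_length", "listed_in_annotation",
]


@dataclass(frozen=True)
class GeneCoordinates:
    """1-based inclusive gene span on the forward strand of a record."""

    gene_id: str
    record_id: str
    start: int
    end: int
    strand: str

    @property
    def start_codon_coord(self) -> int:
        """Forward-strand coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement TSV.

    Rejects missing columns (naming them), non-numeric intensities (with
    the offending row number), duplicated (gene, condition, fraction,
    replicate) keys and empty files.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "dye": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    if frame.empty:
        raise ValueError(f"{path}: no measurements")
    numeric = pd.to_numeric(frame["intensity"], errors="coerce")
    bad = frame.index[numeric.isna() & frame["intensity"].notna()]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric intensity in data row {int(bad[0]) + 1}"
        )
    frame["intensity"] = numeric
    frame["replicate"] = frame["replicate"].astype(int)
    for col, allowed in (("condition", CONDITIONS), ("fraction", FRACTIONS)):
        unknown = set(frame[col].unique()) - set(allowed)
        if unknown:
            raise ValueError(f"{path}: unknown {col} value(s): {sorted(unknown)}")
    key = ["gene_id", "condition", "fraction", "replicate"]
    dup = frame[frame.duplicated(key, keep=False)]
    if not dup.empty:
        first = dup.iloc[0]
        raise ValueError(
            f"{path}: duplicated measurement key "
            f"({first['gene_id']}, {first['condition']}, "
            f"{first['fraction']}, {first['replicate']})"
        )
    return frame


def write_measurements(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_genome(path: str | Path) -> dict[str, str]:
    """FASTA -> mapping of record id to uppercase forward-strand sequence."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_genome(genome: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()],
        str(path), "fasta",
    )


def _check_strand(gene_id: str, strand: str) -> str:
    if strand not in {"+", "-"}:
        raise ValueError(f"gene {gene_id}: unknown strand symbol {strand!r}")
    return strand


def _records_from_frame(frame: pd.DataFrame, source: str
                        ) -> tuple[list[GeneFeatureRecord], list[GeneCoordinates]]:
    features, coords = [], []
    for _, row in frame.iterrows():
        gene_id = str(row["gene_id"])
        start, end = int(row["start"]), int(row["end"])
        if end < start:
            raise ValueError(f"{source}: gene {gene_id}: end {end} < start {start}")
        strand = _check_strand(gene_id, str(row["strand"]))
        dist = row.get("intergenic_distance")
        dist = None if pd.isna(dist) else float(dist)
        utr = row.get("utr_length")
        utr_lengths = () if pd.isna(utr) else (int(utr),)
        listed = row.get("listed_in_annotation", True)
        listed = True if pd.isna(listed) else bool(listed)
        position = row.get("operon_position", "unknown")
        position = "unknown" if pd.isna(position) else str(position)
        features.append(
            GeneFeatureRecord(gene_id, listed, position, dist, utr_lengths, strand)
        )
        coords.append(GeneCoordinates(gene_id, str(row["record_id"]), start, end, strand))
    return features, coords


def read_annotation(path: str | Path, dialect: str = "tsv"
                    ) -> tuple[list[GeneFeatureRecord], list[GeneCoordinates]]:
    """Read gene annotation as TSV or GFF3.

    The TSV dialect uses explicit columns (``ANNOTATION_COLUMNS``).  The
    GFF3 dialect reads ``gene`` features; the feature columns travel in
    the attribute field (``operon_position=...;intergenic_distance=...;
    utr_length=...;listed_in_annotation=...``).  Coordinates are 1-based
    inclusive in both dialects.
    """
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t")
        missing = [c for c in ("gene_id", "record_id", "start", "end", "strand")
                   if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
        return _records_from_frame(frame, str(path))
    if dialect != "gff3":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise ValueError(
                f"{path}: gene {feat.id}: end {feat.end} < start {feat.start}"
            )
        attrs = {k: v[0] for k, v in feat.attributes.items()}
        rows.append(
            {
                "gene_id": attrs.get("ID", feat.id),
                "record_id": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand if feat.strand else "?",
                "operon_position": attrs.get("operon_position", "unknown"),
                "intergenic_distance": attrs.get("intergenic_distance", None),
                "utr_length": attrs.get("utr_length", None),
                "listed_in_annotation": attrs.get("listed_in_annotation", "1") != "0",
            }
        )
    if not rows:
        raise ValueError(f"{path}: no gene features")
    frame = pd.DataFrame(rows)
    for col in ("intergenic_distance", "utr_length"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return _records_from_frame(frame, str(path))


def write_annotation_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_windows(windows: list[StartRegionWindow], path: str | Path) -> pd.DataFrame:
    """Window TSV: gene_id, strand, padded flag and the 77-nt sequence."""
    frame = pd.DataFrame(
        {
            "gene_id": [w.gene_id for w in windows],
            "strand": [w.strand for w in windows],
            "padded": [int(w.padded) for w in windows],
            "sequence": [w.sequence for w in windows],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame


def write_windows_fasta(
    windows: list[StartRegionWindow],
    path: str | Path,
    truth: pd.DataFrame | None = None,
) -> None:
    """FASTA of window sequences; planted-SD truth in key=value comments."""
    notes = {}
    if truth is not None:
        for _, row in truth.iterrows():
            planted = bool(row["sd_planted"])
            note = f"sd_planted={int(planted)}"
            if planted and not pd.isna(row["sd_spacer"]):
                note += f" spacer={int(row['sd_spacer'])}"
            notes[str(row["gene_id"])] = note
    records = [
        SeqRecord(Seq(w.sequence), id=w.gene_id, description=notes.get(w.gene_id, ""))
        for w in windows
    ]
    SeqIO.write(records, str(path), "fasta")


def read_windows_fasta(path: str | Path, window_up: int = 40
                       ) -> tuple[list[StartRegionWindow], pd.DataFrame]:
    """Read windows (and any planted-SD comments) back from FASTA."""
    windows, truth_rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        windows.append(
            StartRegionWindow(rec.id, seq[:window_up], seq[window_up:], "+")
        )
        fields = dict(
            part.split("=", 1) for part in rec.description.split()[1:] if "=" in part
        )
        truth_rows.append(
            {
                "gene_id": rec.id,
                "sd_planted": fields.get("sd_planted") == "1",
                "sd_spacer": int(fields["spacer"]) if "spacer" in fields else pd.NA,
            }
        )
    if not windows:
        raise ValueError(f"{path}: no FASTA records")
    return windows, pd.DataFrame(truth_rows)


def reference_start_sites() -> pd.DataFrame:
    """Bundled reference set of experimentally mapped 5' ends.

    Nineteen *E. coli* genes with 5'-RACE-determined 5'-UTR lengths from
    untreated and Kasugamycin-treated cultures, the expert SD yes/no call,
    the SD-site 8-mer and its distance to the start codon, and the
    measured KEV.  Genes with two mapped 5' ends have a second row with
    blank KEV/site fields.
    """
    path = Path(__file__).parent / "data" / "reference_start_sites.tsv"
    return pd.read_csv(path, sep="\t")
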