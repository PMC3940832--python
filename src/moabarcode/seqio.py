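"""Alignment and metadata I/O with reference-coordinate anchoring.

Alignments are equal-length DNA sequences (IUPAC alphabet, ``-`` for gaps)
whose first column is anchored to a 1-based position on a reference
mitogenome, so that alignment columns can be reported as genome coordinates
(e.g. the control-region variant at position 557 of the *Dinornis robustus*
mitogenome, GenBank AY016013.1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide codes plus gap.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")
#: Unambiguous bases: the only characters counted in distances and SNP scans.
UNAMBIGUOUS = frozenset("ACGT")

# Reference anchors on the D. robustus mitogenome used throughout the moa work.
COI_REF_START = 6996
CONTROL_REGION_REF_START = 554
DEFAULT_REF_NAME = "AY016013.1"


class AlignmentShapeError(ValueError):
    """Sequences of unequal length."""


class IdentityError(ValueError):
    """Duplicate or empty sample identifiers."""


class ContentError(ValueError):
    """Characters outside the IUPAC alphabet, or invalid metadata values."""


class SchemaError(ValueError):
    """Metadata table missing a required column."""


@dataclass(frozen=True)
class Alignment:
    """An anchored multiple-sequence alignment.

    Parameters
    ----------
    records
        Ordered ``(sample_id, sequence)`` pairs. Sequences are upper-case
        strings over the IUPAC alphabet plus ``-`` and share one length.
    ref_start
        1-based reference position of alignment column 1.
    ref_name
        Reference sequence identifier (e.g. a GenBank accession).
    """

    records: tuple[tuple[str, str], ...]
    ref_start: int = 1
    ref_name: str = DEFAULT_REF_NAME

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment must contain at least one record")
        if self.ref_start < 1:
            raise ValueError(f"ref_start must be >= 1, got {self.ref_start}")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"sequences have unequal lengths: {sorted(lengths)}")
        if 0 in lengths:
            raise AlignmentShapeError("sequences must be non-empty")
        ids = [sid for sid, _ in self.records]
        if any(not sid for sid in ids):
            raise IdentityError("empty sample id")
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise IdentityError(f"duplicate sample ids: {dupes}")
        for sid, seq in self.records:
            bad = set(seq) - IUPAC_CHARS
            if bad:
                raise ContentError(f"non-IUPAC characters in {sid!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def sequence(self, sample_id: str) -> str:
        for sid, seq in self.records:
            if sid == sample_id:
                return seq
        raise KeyError(sample_id)

    def column(self, col: int) -> str:
        """Bases in 1-based alignment column *col*, in record order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return "".join(seq[col - 1] for _, seq in self.records)

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        wanted = set(sample_ids)
        kept = tuple((sid, seq) for sid, seq in self.records if sid in wanted)
        return Alignment(kept, self.ref_start, self.ref_name)


@dataclass
class SampleMetadata:
    """Per-sample geography, reference taxonomy and phenotype measurements.

    Missing numeric measurements are ``None``; ``island`` is one of
    ``"NorthIsland"``, ``"SouthIsland"``, ``"unknown"``; ``eggshell_class``
    one of ``"I"``, ``"II"``, ``"unknown"``.
    """

    sample_id: str
    location: str = ""
    island: str = "unknown"
    taxon_label: str = ""
    eggshell_thickness: Optional[float] = None
    femur_length: Optional[float] = None
    tibiotarsus_length: Optional[float] = None
    eggshell_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise IdentityError("empty sample_id")
        if self.island not in ("NorthIsland", "SouthIsland", "unknown"):
            raise ContentError(f"bad island {self.island!r}")
        if self.eggshell_class not in ("I", "II", "unknown"):
            raise ContentError(f"bad eggshell_class {self.eggshell_class!r}")
        for name in ("eggshell_thickness", "femur_length", "tibiotarsus_length"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ContentError(f"{name} must be > 0, got {v}")


def read_alignment(path: str | Path, ref_start: int = 1, ref_name: str = DEFAULT_REF_NAME) -> Alignment:
    """Read a FASTA alignment, normalising case and enforcing invariants."""
    records = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    )
    if not records:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    return Alignment(records, ref_start=ref_start, ref_name=ref_name)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in alignment.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def column_to_ref(alignment: Alignment, column: int) -> int:
    """Map a 1-based alignment column to a 1-based reference coordinate.

    The alignment is assumed gapless relative to the reference (amplicons of
    fixed reference spans); internal ``-`` characters are per-sample missing
    data, not reference indels.
    """
    if not 1 <= column <= alignment.length:
        raise IndexError(f"column {column} out of range 1..{alignment.length}")
    return alignment.ref_start + column - 1


def ref_to_column(alignment: Alignment, ref_position: int) -> int:
    """Inverse of :func:`column_to_ref`."""
    col = ref_position - alignment.ref_start + 1
    if not 1 <= col <= alignment.length:
        raise IndexError(
            f"reference position {ref_position} outside "
            f"{alignment.ref_start}..{alignment.ref_start + alignment.length - 1}"
        )
    return col


_METADATA_COLUMNS = {
    "location": "location",
    "island": "island",
    "taxon_label": "taxon_label",
    "eggshell_thickness_mm": "eggshell_thickness",
    "femur_mm": "femur_length",
    "tibiotarsus_mm": "tibiotarsus_length",
    "eggshell_class": "eggshell_class",
}

_ISLAND_ALIASES = {
    "ni": "NorthIsland",
    "northisland": "NorthIsland",
    "north island": "NorthIsland",
    "si": "SouthIsland",
    "southisland": "SouthIsland",
    "south island": "SouthIsland",
    "": "unknown",
    "unknown": "unknown",
}


def _parse_float(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if not s:
        return None
    return float(s)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a delimited metadata table (tab or comma separated, with header).

    Required column: ``sample_id``. Recognised optional columns: location,
    island, taxon_label, eggshell_thickness_mm, femur_mm, tibiotarsus_mm,
    eggshell_class. Empty numeric cells become missing values.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise SchemaError(f"metadata file {path} lacks a sample_id column")
    out: list[SampleMetadata] = []
    for _, row in df.iterrows():
        island_raw = str(row.get("island", "")).strip().lower()
        island = _ISLAND_ALIASES.get(island_raw, None)
        if island is None:
            raise ContentError(f"unrecognised island value {row['island']!r}")
        cls = str(row.get("eggshell_class", "")).strip() or "unknown"
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]).strip(),
                location=str(row.get("location", "")).strip(),
                island=island,
                taxon_label=str(row.get("taxon_label", "")).strip(),
                eggshell_thickness=_parse_float(row.get("eggshell_thickness_mm")),
                femur_length=_parse_float(row.get("femur_mm")),
                tibiotarsus_length=_parse_float(row.get("tibiotarsus_mm")),
                eggshell_class=cls,
            )
        )
    return out


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path, sep: str = "\t") -> None:
    rows = []
    for m in metadata:
        rows.append(
            {
                "sample_id": m.sample_id,
                "location": m.location,
                "island": m.island,
                "taxon_label": m.taxon_label,
                "eggshell_thickness_mm": "" if m.eggshell_thickness is None else m.eggshell_thickness,
                "femur_mm": "" if m.femur_length is None else m.femur_length,
                "tibiotarsus_mm": "" if m.tibiotarsus_length is None else m.tibiotarsus_length,
                "eggshell_class": m.eggshell_class,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def join_metadata(alignment: Alignment, metadata: Iterable[SampleMetadata]) -> dict[str, SampleMetadata]:
    """Join metadata to alignment samples by exact sample_id.

    Metadata rows without a matching sequence trigger a warning, not an error.
    """
    by_id = {m.sample_id: m for m in metadata}
    aln_ids = set(alignment.sample_ids)
    orphans = sorted(set(by_id) - aln_ids)
    if orphans:
        warnings.warn(f"metadata rows with no matching sequence: {orphans}", stacklevel=2)
    return {sid: by_id[sid] for sid in alignment.sample_ids if sid in by_id}
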