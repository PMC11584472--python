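"""Sequence, alignment, metadata and column-map I/O.

The analysis operates on a family of homologous membrane-protein sequences:
an unaligned FASTA (one record per species), a pre-built gapped alignment of
the same records, and a small metadata table assigning each sequence id to a
species and a vertebrate clade (amphibian, reptile, bird, mammal).  Region
coordinates are always expressed on one ungapped *reference* sequence
(typically the human orthologue); :class:`ColumnMap` translates between
reference residue numbering and alignment columns.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentShapeError, ParseError, ValidationError

logger = logging.getLogger("memevo")

#: The 20 canonical one-letter amino-acid codes.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)
#: Ambiguity codes tolerated only under ``permissive=True``; they are always
#: excluded from frequency denominators downstream.
AMBIGUOUS_SET = frozenset("BJOUXZ")
GAP = "-"

CLADES = ("amphibian", "reptile", "bird", "mammal", "other")
#: Thermal class is derived from clade: ectotherms (cold-blooded) are
#: amphibians and reptiles, endotherms (warm-blooded) birds and mammals.
THERMAL_BY_CLADE = {
    "amphibian": "cold",
    "reptile": "cold",
    "bird": "warm",
    "mammal": "warm",
    "other": "n/a",
}


@dataclass
class ProteinRecord:
    """One protein sequence with its species annotation.

    ``sequence`` may contain ``-`` gap characters only when the record lives
    inside an :class:`AlignedSet`; use :meth:`ungapped` to recover the plain
    sequence.
    """

    id: str
    sequence: str
    species: str = ""
    clade: str = "other"

    @property
    def thermal_class(self) -> str:
        return THERMAL_BY_CLADE[self.clade]

    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignedSet:
    """A gapped multiple alignment plus the id of the reference record."""

    records: list[ProteinRecord]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"aligned sequences have unequal lengths: {sorted(lengths)}"
            )
        if self.reference_id is not None and self.get(self.reference_id) is None:
            raise ValidationError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def get(self, record_id: str) -> ProteinRecord | None:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        return None

    def reference(self) -> ProteinRecord:
        if self.reference_id is None:
            raise ValidationError("AlignedSet has no reference_id set")
        rec = self.get(self.reference_id)
        assert rec is not None
        return rec


@dataclass(frozen=True)
class ColumnMap:
    """Bijection between non-gap reference positions and alignment columns.

    ``ref_to_col[p]`` gives the alignment column (1-based) holding reference
    residue ``p``; ``col_to_ref`` is the inverse on mapped columns.
    """

    ref_to_col: dict[int, int]
    col_to_ref: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.col_to_ref:
            object.__setattr__(
                self, "col_to_ref", {c: p for p, c in self.ref_to_col.items()}
            )

    def __len__(self) -> int:
        return len(self.ref_to_col)

    def columns_for(self, positions: Iterable[int]) -> list[int]:
        """Map reference positions to columns; unknown positions raise KeyError."""
        return [self.ref_to_col[p] for p in positions]


def _validate_sequence(seq: str, record_id: str, aligned: bool, permissive: bool) -> str:
    seq = seq.upper().replace(".", GAP)
    allowed = set(AA_SET)
    if aligned:
        allowed.add(GAP)
    if permissive:
        allowed |= AMBIGUOUS_SET
    for offset, ch in enumerate(seq):
        if ch not in allowed:
            raise ParseError(
                f"record {record_id!r}: invalid residue {ch!r} at offset {offset + 1}"
            )
    return seq


def read_fasta(
    path: str | Path,
    aligned: bool = False,
    permissive: bool = False,
    reference_id: str | None = None,
) -> list[ProteinRecord] | AlignedSet:
    """Read a protein FASTA file.

    Parameters
    ----------
    aligned:
        If true, gap characters are allowed, equal lengths are enforced, and
        an :class:`AlignedSet` is returned instead of a list of records.
    permissive:
        Tolerate ambiguity codes (B/J/O/U/X/Z).  They never enter frequency
        denominators downstream.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _validate_sequence(str(rec.seq), rec.id, aligned, permissive)
        if not seq:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    if aligned:
        return AlignedSet(records=records, reference_id=reference_id)
    return records


def write_fasta(records: Sequence[ProteinRecord] | AlignedSet, path: str | Path) -> None:
    if isinstance(records, AlignedSet):
        records = records.records
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the id→(species, clade) table; TSV or CSV chosen by extension.

    Returns a DataFrame with columns ``id, species, clade, thermal_class``.
    Unknown clade labels and duplicate ids raise :class:`ValidationError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"id", "species", "clade"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: metadata missing columns {sorted(missing)}")
    df["clade"] = df["clade"].str.strip().str.lower()
    bad = sorted(set(df["clade"]) - set(CLADES))
    if bad:
        raise ValidationError(f"{path}: unknown clade labels {bad}")
    dups = df["id"][df["id"].duplicated()].tolist()
    if dups:
        raise ValidationError(f"{path}: duplicate ids {sorted(set(dups))}")
    df["thermal_class"] = df["clade"].map(THERMAL_BY_CLADE)
    return df[["id", "species", "clade", "thermal_class"]]


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    meta.to_csv(path, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL)


def attach_metadata(
    records: Sequence[ProteinRecord], meta: pd.DataFrame
) -> list[ProteinRecord]:
    """Annotate records in place with species/clade from a metadata table.

    Ids present in the metadata but absent from the record set (or vice
    versa) are logged as warnings, not errors, so a partial table can still
    drive a run.
    """
    by_id = meta.set_index("id")
    seen = set()
    for rec in records:
        seen.add(rec.id)
        if rec.id in by_id.index:
            rec.species = str(by_id.at[rec.id, "species"])
            rec.clade = str(by_id.at[rec.id, "clade"])
        else:
            logger.warning("no metadata for sequence %r; clade left as 'other'", rec.id)
    for mid in by_id.index:
        if mid not in seen:
            logger.warning("metadata id %r not present in the sequence set", mid)
    return list(records)


def build_column_map(aln: AlignedSet, reference_id: str) -> ColumnMap:
    """Map each non-gap residue of the reference record to its column.

    The map is strictly increasing in both coordinates and bijective on
    non-gap reference residues; an all-gap reference yields an empty map with
    a warning.
    """
    rec = aln.get(reference_id)
    if rec is None:
        raise ValidationError(f"reference id {reference_id!r} not in alignment")
    ref_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(rec.sequence, start=1):
        if ch != GAP:
            pos += 1
            ref_to_col[pos] = col
    if not ref_to_col:
        logger.warning("reference %r is all gaps; column map is empty", reference_id)
    return ColumnMap(ref_to_col=ref_to_col)
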