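"""HGVS-p mutation parsing and region-overlap (Venn) accounting.

Somatic-mutation catalogs (COSMIC-style exports) list protein-level changes
as HGVS-p strings: ``p.R842K`` (missense), ``p.S902*`` (nonsense),
``p.Y905=`` (coding-silent; whitespace around ``=`` is tolerated).  Each
record is mapped by position onto the LWI regions and cholesterol-motif
spans of the reference protein, yielding a 2x2 overlap summary (the Venn
diagram cells) plus per-region and per-motif counts.

The counting unit is the distinct protein-level change (so ``p.S902*`` and
``p.S902L`` are two entries at one position); position-level unique counts
are reported alongside.  Duplicate raw strings — the same change observed
in several tumour samples — are de-duplicated with a logged count by
default (``dedupe=False`` keeps them).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError, ParseError, ValidationError
from .motifs import MotifMatch
from .seq_io import AA_SET, GAP, ProteinRecord
from .topology import LWIRegion

logger = logging.getLogger("memevo")

_HGVS_RE = re.compile(r"^p\.\(?([A-Z])(\d+)\s*(=|\*|[A-Z])\s*\)?$")

MISSENSE, NONSENSE, SILENT = "missense", "nonsense", "silent"


@dataclass
class MutationRecord:
    raw: str
    position: int = 0
    ref_aa: str = ""
    alt_type: str = ""  # missense / nonsense / silent
    alt_aa: str | None = None
    valid: bool = False
    reason: str = ""

    def format(self) -> str:
        """Canonical HGVS-p string (round-trips through :func:`parse_hgvs_p`)."""
        if not self.valid:
            raise InputError(f"cannot format invalid record {self.raw!r}: {self.reason}")
        if self.alt_type == MISSENSE:
            return f"p.{self.ref_aa}{self.position}{self.alt_aa}"
        suffix = "*" if self.alt_type == NONSENSE else "="
        return f"p.{self.ref_aa}{self.position}{suffix}"


def parse_hgvs_p(raw: str) -> MutationRecord:
    """Parse one HGVS-p string; malformed input yields ``valid=False``.

    Records are never silently dropped: the caller can count and log
    invalid entries.
    """
    rec = MutationRecord(raw=raw)
    s = raw.strip()
    if not s.startswith("p."):
        rec.reason = "missing 'p.' prefix"
        return rec
    m = _HGVS_RE.match(s)
    if not m:
        rec.reason = "unrecognized HGVS-p syntax"
        return rec
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if ref not in AA_SET:
        rec.reason = f"invalid reference residue {ref!r}"
        return rec
    if pos < 1:
        rec.reason = f"position must be >= 1, got {pos}"
        return rec
    rec.ref_aa, rec.position = ref, pos
    if alt == "*":
        rec.alt_type = NONSENSE
    elif alt == "=":
        rec.alt_type = SILENT
    else:
        if alt not in AA_SET:
            rec.reason = f"invalid substituted residue {alt!r}"
            return rec
        rec.alt_type, rec.alt_aa = MISSENSE, alt
    rec.valid = True
    return rec


def parse_catalog(raw_entries: Iterable[str]) -> list[MutationRecord]:
    records = [parse_hgvs_p(str(r)) for r in raw_entries]
    n_invalid = sum(not r.valid for r in records)
    if n_invalid:
        logger.warning("%d of %d catalog entries failed to parse", n_invalid, len(records))
    return records


def read_mutation_catalog(
    path: str | Path, column: str | None = None
) -> list[MutationRecord]:
    """Read a delimited catalog with one HGVS-p column.

    ``column`` names the HGVS-p column; when omitted, the first column in
    which a majority of values start with ``p.`` is used (tolerant of
    COSMIC-style extra columns).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    if column is None:
        for c in df.columns:
            vals = df[c].dropna().astype(str)
            if len(vals) and (vals.str.startswith("p.").mean() > 0.5):
                column = c
                break
        if column is None:
            raise ParseError(f"{path}: no column with HGVS-p entries found")
    elif column not in df.columns:
        raise ParseError(f"{path}: column {column!r} not present")
    return parse_catalog(df[column].dropna())


def validate_against_reference(m: MutationRecord, seq: ProteinRecord) -> bool:
    """Check the record's reference residue against the protein sequence.

    Mismatches are reported (logged) but not fatal; a position beyond the
    sequence marks the record invalid with a reason.
    """
    s = seq.sequence
    if GAP in s:
        raise InputError("validate_against_reference expects an ungapped sequence")
    if not m.valid:
        return False
    if m.position > len(s):
        m.valid = False
        m.reason = f"position {m.position} beyond sequence length {len(s)}"
        return False
    ok = s[m.position - 1] == m.ref_aa
    if not ok:
        logger.warning(
            "%s: reference residue mismatch (catalog %s, sequence %s at %d)",
            m.raw, m.ref_aa, s[m.position - 1], m.position,
        )
    return ok


@dataclass
class OverlapSummary:
    """Venn cells of catalog vs motif spans and LWI regions.

    Invariants (checked): ``n_in_both <= min(n_in_motif, n_in_lwi)`` and
    ``n_total = n_in_neither + n_in_motif + n_in_lwi - n_in_both``.
    """

    n_total: int
    n_in_motif: int
    n_in_lwi: int
    n_in_both: int
    n_in_neither: int
    members: dict[str, list[str]] = field(default_factory=dict)
    n_duplicates: int = 0
    n_invalid: int = 0

    def __post_init__(self) -> None:
        if self.n_in_both > min(self.n_in_motif, self.n_in_lwi):
            raise ValidationError("overlap cell exceeds a marginal count")
        if self.n_total != self.n_in_neither + self.n_in_motif + self.n_in_lwi - self.n_in_both:
            raise ValidationError("Venn identity violated")

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_in_motif": self.n_in_motif,
            "n_in_lwi": self.n_in_lwi,
            "n_in_both": self.n_in_both,
            "n_in_neither": self.n_in_neither,
            "n_duplicates": self.n_duplicates,
            "n_invalid": self.n_invalid,
            "members": self.members,
        }


def _in_any_region(pos: int, regions: Sequence[LWIRegion]) -> bool:
    return any(pos in r for r in regions)


def _in_any_motif(pos: int, motifs: Sequence[MotifMatch]) -> bool:
    return any(m.start <= pos <= m.end for m in motifs)


def overlap_summary(
    muts: Sequence[MutationRecord],
    regions: Sequence[LWIRegion],
    motifs: Sequence[MotifMatch],
    dedupe: bool = True,
) -> OverlapSummary:
    """Count catalog entries by membership in motif spans and LWI regions.

    A mutation is ``in_motif`` if its position lies within any motif span
    and ``in_lwi`` if within any LWI region; silent and nonsense records are
    retained.  Invalid records are excluded from the cells but counted.
    """
    valid = [m for m in muts if m.valid]
    n_invalid = len(muts) - len(valid)
    n_dup = 0
    if dedupe:
        seen: dict[str, MutationRecord] = {}
        for m in valid:
            key = m.format()
            if key in seen:
                n_dup += 1
            else:
                seen[key] = m
        valid = list(seen.values())
        if n_dup:
            logger.info("de-duplicated %d repeated catalog entries", n_dup)
    members: dict[str, list[str]] = {"both": [], "motif_only": [], "lwi_only": [], "neither": []}
    for m in valid:
        in_m = _in_any_motif(m.position, motifs)
        in_l = _in_any_region(m.position, regions)
        cell = "both" if (in_m and in_l) else "motif_only" if in_m else "lwi_only" if in_l else "neither"
        members[cell].append(m.format())
    n_both = len(members["both"])
    return OverlapSummary(
        n_total=len(valid),
        n_in_motif=n_both + len(members["motif_only"]),
        n_in_lwi=n_both + len(members["lwi_only"]),
        n_in_both=n_both,
        n_in_neither=len(members["neither"]),
        members=members,
        n_duplicates=n_dup,
        n_invalid=n_invalid,
    )


def region_mutation_rates(
    muts: Sequence[MutationRecord],
    regions: Sequence[LWIRegion],
    protein_length: int,
) -> dict:
    """Fraction of unique mutated positions falling inside LWI regions.

    Reports the LWI vs non-LWI split of mutated positions together with the
    residue-count denominators (unique LWI residues vs the rest of the
    protein) and per-region counts.
    """
    max_end = max((r.end for r in regions), default=0)
    if protein_length < max_end:
        raise InputError(f"protein_length {protein_length} < last region end {max_end}")
    positions = sorted({m.position for m in muts if m.valid})
    lwi_positions = {p for r in regions for p in r.positions}
    in_lwi = [p for p in positions if p in lwi_positions]
    n = len(positions)
    per_region = {
        r.label: sum(1 for p in positions if p in r) for r in regions
    }
    return {
        "n_mutated_positions": n,
        "lwi_fraction_of_mutations": 100.0 * len(in_lwi) / n if n else float("nan"),
        "nonlwi_fraction_of_mutations": 100.0 * (n - len(in_lwi)) / n if n else float("nan"),
        "lwi_residue_count": len(lwi_positions),
        "nonlwi_residue_count": protein_length - len(lwi_positions),
        "per_region_counts": per_region,
    }


def motif_mutation_counts(
    muts: Sequence[MutationRecord], motifs: Sequence[MotifMatch], names: Sequence[str] | None = None
) -> dict[str, int]:
    """Distinct-change counts per motif span (names default to kind+ordinal)."""
    valid = {m.format(): m for m in muts if m.valid}
    counts: dict[str, int] = {}
    ordered = sorted(motifs, key=lambda m: (m.kind, m.start, m.end))
    ordinals: dict[str, int] = {}
    for idx, motif in enumerate(ordered):
        if names is not None:
            name = names[idx]
        else:
            ordinals[motif.kind] = ordinals.get(motif.kind, 0) + 1
            name = f"{motif.kind}{ordinals[motif.kind]}"
        counts[name] = sum(
            1 for m in valid.values() if motif.start <= m.position <= motif.end
        )
    return counts


def annotate_catalog(
    muts: Sequence[MutationRecord],
    regions: Sequence[LWIRegion],
    motifs: Sequence[MotifMatch],
) -> pd.DataFrame:
    """Per-mutation annotated table (validity, region/motif membership)."""
    rows = []
    for m in muts:
        rows.append(
            {
                "raw": m.raw,
                "valid": m.valid,
                "reason": m.reason,
                "position": m.position if m.valid else pd.NA,
                "ref_aa": m.ref_aa,
                "alt_type": m.alt_type,
                "alt_aa": m.alt_aa if m.alt_aa else "",
                "in_lwi": _in_any_region(m.position, regions) if m.valid else False,
                "in_motif": _in_any_motif(m.position, motifs) if m.valid else False,
            }
        )
    return pd.DataFrame(rows)
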