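"""Transmembrane topology and lipid-water-interface (LWI) region derivation.

A polytopic membrane protein is described by an ordered list of TM helix
spans on the reference sequence plus the membrane side of its N terminus
(``inner`` = cytoplasmic, ``outer`` = extracellular).  The lipid-water
interface is operationalized as the ``flank_width`` residues (default 5,
roughly 6-10 Å of an extended chain) immediately flanking each end of each
TM helix.  Each TM segment therefore contributes an N-side flank and a
C-side flank; the membrane leaflet a flank touches follows deterministically
from the N-terminus side because the chain alternates sides at every
membrane crossing.

Flanks of neighbouring helices separated by short loops may overlap; they
are reported individually (region-residue *slots*), with unique residue
counts available separately.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import InputError, TruncationError, ValidationError
from .seq_io import GAP, ColumnMap, ProteinRecord

logger = logging.getLogger("memevo")

SIDES = ("inner", "outer")


def _flip(side: str) -> str:
    return "outer" if side == "inner" else "inner"


@dataclass(frozen=True)
class TMSegment:
    """One membrane-spanning helix, 1-based inclusive coordinates."""

    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"TM{self.index}: start {self.start} > end {self.end}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Topology:
    segments: tuple[TMSegment, ...]
    n_terminus_side: str
    protein_length: int

    def __post_init__(self) -> None:
        if self.n_terminus_side not in SIDES:
            raise ValidationError(f"n_terminus_side must be inner/outer, got {self.n_terminus_side!r}")
        segs = tuple(sorted(self.segments, key=lambda s: s.index))
        object.__setattr__(self, "segments", segs)
        prev_end = 0
        for i, seg in enumerate(segs, start=1):
            if seg.index != i:
                raise ValidationError(f"TM indices must be 1..n without gaps (got {seg.index} at rank {i})")
            if seg.start <= prev_end:
                raise ValidationError(f"TM{seg.index} overlaps or precedes TM{seg.index - 1}")
            prev_end = seg.end
        if segs and segs[-1].end > self.protein_length:
            raise ValidationError(
                f"TM{segs[-1].index} ends at {segs[-1].end} beyond protein length {self.protein_length}"
            )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def side_before(self, tm_index: int) -> str:
        """Membrane side of the chain immediately N-terminal of TM ``tm_index``."""
        side = self.n_terminus_side
        for _ in range(tm_index - 1):
            side = _flip(side)
        return side


@dataclass(frozen=True)
class LWIRegion:
    """A lipid-water-interface flank of one TM helix.

    ``positions`` are consecutive 1-based residue positions on the reference,
    strictly outside the parent TM span (unless derived with
    ``lwi_inside_tm=True``).  ``leaflet`` names the membrane boundary the
    flank sits at (inner = cytoplasmic, outer = extracellular).
    """

    tm_index: int
    terminus: str  # "N" or "C"
    leaflet: str  # "inner" or "outer"
    positions: tuple[int, ...]
    label: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.terminus not in ("N", "C"):
            raise ValidationError(f"terminus must be N or C, got {self.terminus!r}")
        if self.leaflet not in SIDES:
            raise ValidationError(f"leaflet must be inner/outer, got {self.leaflet!r}")
        if not self.positions:
            raise ValidationError("LWI region has no positions")
        for a, b in zip(self.positions, self.positions[1:]):
            if b != a + 1:
                raise ValidationError(f"LWI positions not consecutive: {self.positions}")
        if not self.label:
            object.__setattr__(self, "label", f"TM{self.tm_index}-{self.terminus}")

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class PositionMembership:
    position: int
    in_tm: bool
    in_lwi: bool
    lwi_labels: tuple[str, ...]
    leaflets: tuple[str, ...]


def derive_lwi_regions(
    topo: Topology,
    flank_width: int = 5,
    allow_truncated: bool = False,
    lwi_inside_tm: bool = False,
) -> list[LWIRegion]:
    """Derive the two LWI flank regions of every TM segment.

    For each TM helix the N flank is the ``flank_width`` residues immediately
    preceding its start and the C flank the ``flank_width`` residues
    immediately following its end (with ``lwi_inside_tm=True``, the terminal
    ``flank_width`` residues *of* the helix instead, for sensitivity
    analysis).  Leaflets: the N flank of TM *i* lies on the side the chain
    occupies before crossing (``topo.side_before(i)``), the C flank on the
    opposite side.

    A flank extending past either end of the protein raises
    :class:`TruncationError` unless ``allow_truncated`` is set, in which case
    it is shortened and flagged.
    """
    if flank_width < 1:
        raise InputError(f"flank_width must be >= 1, got {flank_width}")
    regions: list[LWIRegion] = []
    for seg in topo.segments:
        side_n = topo.side_before(seg.index)
        side_c = _flip(side_n)
        if lwi_inside_tm:
            n_span = (seg.start, min(seg.end, seg.start + flank_width - 1))
            c_span = (max(seg.start, seg.end - flank_width + 1), seg.end)
        else:
            n_span = (seg.start - flank_width, seg.start - 1)
            c_span = (seg.end + 1, seg.end + flank_width)
        for terminus, leaflet, (lo, hi) in (
            ("N", side_n, n_span),
            ("C", side_c, c_span),
        ):
            clipped_lo, clipped_hi = max(1, lo), min(topo.protein_length, hi)
            truncated = (clipped_lo, clipped_hi) != (lo, hi)
            if truncated and not allow_truncated:
                raise TruncationError(
                    f"TM{seg.index}-{terminus} flank {lo}..{hi} extends outside "
                    f"1..{topo.protein_length}; pass allow_truncated to shorten it"
                )
            if clipped_lo > clipped_hi:
                logger.warning("TM%d-%s flank lies entirely outside the protein; dropped", seg.index, terminus)
                continue
            regions.append(
                LWIRegion(
                    tm_index=seg.index,
                    terminus=terminus,
                    leaflet=leaflet,
                    positions=tuple(range(clipped_lo, clipped_hi + 1)),
                    truncated=truncated,
                )
            )
    return regions


def classify_position(
    pos: int, topo: Topology, regions: Sequence[LWIRegion]
) -> PositionMembership:
    """Interval-containment membership of one reference position.

    Positions inside two overlapping LWI flanks report both labels.
    """
    if not 1 <= pos <= topo.protein_length:
        raise InputError(f"position {pos} outside 1..{topo.protein_length}")
    in_tm = any(pos in seg for seg in topo.segments)
    labels = tuple(r.label for r in regions if pos in r)
    leaflets = tuple(r.leaflet for r in regions if pos in r)
    return PositionMembership(
        position=pos,
        in_tm=in_tm,
        in_lwi=bool(labels),
        lwi_labels=labels,
        leaflets=leaflets,
    )


def region_residues(region: LWIRegion, record: ProteinRecord) -> str:
    """Residues of ``record`` (ungapped, reference numbering) at the region."""
    seq = record.sequence
    if GAP in seq:
        raise InputError("region_residues expects an ungapped sequence")
    if region.end > len(seq):
        raise InputError(
            f"region {region.label} ends at {region.end} beyond sequence length {len(seq)}"
        )
    return "".join(seq[p - 1] for p in region.positions)


def project_region_residues(
    region: LWIRegion, cmap: ColumnMap, gapped_sequence: str
) -> str:
    """Project a reference region through the column map onto an orthologue.

    Returns the orthologue's residues at the alignment columns of the
    region's reference positions, N→C; columns where the orthologue is
    gapped are dropped (logged).
    """
    cols = cmap.columns_for(region.positions)
    residues = []
    for col in cols:
        ch = gapped_sequence[col - 1]
        if ch == GAP:
            logger.debug("region %s column %d is a gap in the orthologue; dropped", region.label, col)
            continue
        residues.append(ch)
    return "".join(residues)


def unique_region_positions(regions: Sequence[LWIRegion]) -> list[int]:
    """Sorted unique residue positions covered by any region (overlap collapsed)."""
    return sorted({p for r in regions for p in r.positions})


def total_region_slots(regions: Sequence[LWIRegion]) -> int:
    """Total region-residue slots, counting overlapping flanks per region."""
    return sum(len(r.positions) for r in regions)


# ---------------------------------------------------------------------------
# I/O: topology as TSV (with header keys in comments) or JSON; regions as TSV.

def read_topology(path: str | Path) -> Topology:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        segs = tuple(
            TMSegment(index=int(s["tm_index"]), start=int(s["start"]), end=int(s["end"]))
            for s in data["segments"]
        )
        return Topology(
            segments=segs,
            n_terminus_side=data["n_terminus_side"],
            protein_length=int(data["protein_length"]),
        )
    header: dict[str, str] = {}
    rows: list[tuple[int, int, int]] = []
    col_names: list[str] | None = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                header[key.strip()] = val.strip()
            continue
        fields = line.split("\t")
        if col_names is None:
            col_names = [f.strip().lower() for f in fields]
            continue
        rec = dict(zip(col_names, fields))
        rows.append((int(rec["tm_index"]), int(rec["start"]), int(rec["end"])))
    if "n_terminus_side" not in header or "protein_length" not in header:
        raise ValidationError(
            f"{path}: topology TSV needs '# n_terminus_side=...' and '# protein_length=...' header lines"
        )
    segs = tuple(TMSegment(index=i, start=s, end=e) for i, s, e in rows)
    return Topology(
        segments=segs,
        n_terminus_side=header["n_terminus_side"],
        protein_length=int(header["protein_length"]),
    )


def write_topology(topo: Topology, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = {
            "n_terminus_side": topo.n_terminus_side,
            "protein_length": topo.protein_length,
            "segments": [
                {"tm_index": s.index, "start": s.start, "end": s.end}
                for s in topo.segments
            ],
        }
        path.write_text(json.dumps(data, indent=2) + "\n")
        return
    lines = [
        f"# n_terminus_side={topo.n_terminus_side}",
        f"# protein_length={topo.protein_length}",
        "tm_index\tstart\tend",
    ]
    lines += [f"{s.index}\t{s.start}\t{s.end}" for s in topo.segments]
    path.write_text("\n".join(lines) + "\n")


def regions_to_frame(regions: Sequence[LWIRegion]) -> pd.DataFrame:
    """Regions as a BED-like table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in regions],
            "tm_index": [r.tm_index for r in regions],
            "terminus": [r.terminus for r in regions],
            "leaflet": [r.leaflet for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "truncated": [r.truncated for r in regions],
        }
    )
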