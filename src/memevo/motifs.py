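"""Cholesterol-recognition motif scanning (CRAC, CARC, CCM).

Cholesterol-interacting stretches of membrane proteins are commonly
described by three loose consensus patterns over three anchor residues
separated by variable-length wildcard gaps:

* CRAC  (cholesterol recognition amino-acid consensus), read N→C:
  ``[L/V] - X(1-5) - Y - X(1-5) - [R/K]``
* CARC, the CRAC pattern read in the opposite chain direction:
  ``[R/K] - X(1-5) - Y - X(1-5) - [L/V]``
* CCM (cholesterol consensus motif):
  ``[R/K] - X(2-6) - [I/V/L] - X(3) - [W/Y]``

Because the gaps are variable, occurrences overlap and nest freely; a
leftmost-greedy regular-expression search misses many of them.  The scanner
here enumerates *every* admissible anchor triple (first, central, last) and
every admissible gap-length combination, then optionally collapses the
matches to unique (start, end) spans — the reporting unit used for motif
counting — or unique anchor triples.

Anchor classes are configurable: some of the literature widens the CARC
central anchor to ``[Y/F]``; the default here is the strict ``Y``.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError, ValidationError
from .seq_io import GAP, ProteinRecord
from .topology import LWIRegion, Topology

MOTIF_KINDS = ("CRAC", "CARC", "CCM")
COLLAPSE_MODES = ("spans", "anchors", "none")


@dataclass(frozen=True)
class MotifPattern:
    """A three-anchor consensus with variable wildcard gaps.

    ``gap1`` / ``gap2`` are inclusive (min, max) bounds on the number of
    wildcard residues between first/central and central/last anchors.
    """

    kind: str
    first: frozenset[str]
    gap1: tuple[int, int]
    central: frozenset[str]
    gap2: tuple[int, int]
    last: frozenset[str]

    def __post_init__(self) -> None:
        for lo, hi in (self.gap1, self.gap2):
            if lo > hi or lo < 0:
                raise ValidationError(f"{self.kind}: bad gap range ({lo}, {hi})")
        if not (self.first and self.central and self.last):
            raise ValidationError(f"{self.kind}: anchor classes must be non-empty")

    @property
    def min_span(self) -> int:
        return 3 + self.gap1[0] + self.gap2[0]

    @property
    def max_span(self) -> int:
        return 3 + self.gap1[1] + self.gap2[1]


def crac_pattern() -> MotifPattern:
    return MotifPattern("CRAC", frozenset("LV"), (1, 5), frozenset("Y"), (1, 5), frozenset("RK"))


def carc_pattern(central: str = "Y") -> MotifPattern:
    """CARC consensus; ``central='YF'`` enables the widened variant."""
    if central not in ("Y", "YF"):
        raise ValidationError(f"carc central class must be 'Y' or 'YF', got {central!r}")
    return MotifPattern("CARC", frozenset("RK"), (1, 5), frozenset(central), (1, 5), frozenset("LV"))


def ccm_pattern() -> MotifPattern:
    return MotifPattern("CCM", frozenset("RK"), (2, 6), frozenset("IVL"), (3, 3), frozenset("WY"))


def default_patterns(carc_central: str = "Y") -> dict[str, MotifPattern]:
    return {
        "CRAC": crac_pattern(),
        "CARC": carc_pattern(carc_central),
        "CCM": ccm_pattern(),
    }


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence; 1-based inclusive span equal to its anchor span."""

    kind: str
    start: int
    end: int
    anchors: tuple[int, int, int]
    subsequence: str
    localization: frozenset[str] = frozenset()

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, lo: int, hi: int) -> bool:
        return self.start <= hi and lo <= self.end


def _class_positions(seq: str, residue_class: frozenset[str]) -> list[int]:
    return [i for i, ch in enumerate(seq, start=1) if ch in residue_class]


def scan_motifs(
    seq: ProteinRecord | str,
    pattern: MotifPattern,
    collapse: str = "spans",
) -> list[MotifMatch]:
    """Enumerate all occurrences of ``pattern`` in an ungapped sequence.

    Every anchor triple (i, j, k) with ``seq[i] ∈ first``, ``seq[j] ∈
    central``, ``seq[k] ∈ last`` and both gap lengths within the pattern's
    ranges is a match — overlapping and nested occurrences included.  With
    three fixed anchors the gap lengths are determined by the triple, so
    ``collapse='none'`` and ``collapse='anchors'`` both report one match per
    admissible triple; ``collapse='spans'`` (the default motif-counting
    unit) merges matches sharing a (start, end) span, keeping the triple
    with the most central middle anchor as representative.

    Results are sorted by (start, end, anchors).
    """
    if collapse not in COLLAPSE_MODES:
        raise InputError(f"collapse must be one of {COLLAPSE_MODES}, got {collapse!r}")
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    if GAP in s:
        raise InputError("scan_motifs requires an ungapped sequence")
    firsts = _class_positions(s, pattern.first)
    centrals = _class_positions(s, pattern.central)
    lasts = _class_positions(s, pattern.last)
    (g1lo, g1hi), (g2lo, g2hi) = pattern.gap1, pattern.gap2

    matches: list[MotifMatch] = []
    for j in centrals:
        # first anchor i satisfies g1lo <= j - i - 1 <= g1hi
        i_lo, i_hi = j - 1 - g1hi, j - 1 - g1lo
        k_lo, k_hi = j + 1 + g2lo, j + 1 + g2hi
        i_candidates = firsts[bisect_left(firsts, i_lo) : bisect_right(firsts, i_hi)]
        k_candidates = lasts[bisect_left(lasts, k_lo) : bisect_right(lasts, k_hi)]
        for i in i_candidates:
            for k in k_candidates:
                matches.append(
                    MotifMatch(
                        kind=pattern.kind,
                        start=i,
                        end=k,
                        anchors=(i, j, k),
                        subsequence=s[i - 1 : k],
                    )
                )
    if collapse == "spans":
        by_span: dict[tuple[int, int], MotifMatch] = {}
        for m in sorted(
            matches, key=lambda m: abs(2 * m.anchors[1] - (m.start + m.end))
        ):
            by_span.setdefault(m.span, m)
        matches = list(by_span.values())
    matches.sort(key=lambda m: (m.start, m.end, m.anchors))
    return matches


def scan_all(
    seq: ProteinRecord | str,
    kinds: Iterable[str] = MOTIF_KINDS,
    collapse: str = "spans",
    carc_central: str = "Y",
) -> list[MotifMatch]:
    """Scan one sequence for several motif kinds; concatenated, kind-sorted."""
    patterns = default_patterns(carc_central)
    out: list[MotifMatch] = []
    for kind in kinds:
        if kind not in patterns:
            raise InputError(f"unknown motif kind {kind!r}")
        out.extend(scan_motifs(seq, patterns[kind], collapse=collapse))
    return out


def localize_motifs(
    matches: Sequence[MotifMatch],
    topo: Topology,
    regions: Sequence[LWIRegion],
) -> list[MotifMatch]:
    """Tag each match with the region classes its span overlaps (≥1 residue).

    Tags are ``TM``, ``LWI_inner``, ``LWI_outer``; a match overlapping none
    of them is tagged ``other``.
    """
    out = []
    for m in matches:
        tags: set[str] = set()
        if any(m.overlaps(seg.start, seg.end) for seg in topo.segments):
            tags.add("TM")
        for r in regions:
            if m.overlaps(r.start, r.end):
                tags.add(f"LWI_{r.leaflet}")
        if not tags:
            tags.add("other")
        out.append(replace(m, localization=frozenset(tags)))
    return out


def motif_region_coordinates(matches: Sequence[MotifMatch]) -> pd.DataFrame:
    """Report table with per-kind ordinals in N→C order (CARC1, CARC2, ...).

    Ordinals follow start position, ties broken by end position, so
    overlapping occurrences keep distinct consecutive ordinals.
    """
    rows = []
    counters: dict[str, int] = {}
    for m in sorted(matches, key=lambda m: (m.kind, m.start, m.end)):
        counters[m.kind] = counters.get(m.kind, 0) + 1
        rows.append(
            {
                "kind": m.kind,
                "ordinal": counters[m.kind],
                "name": f"{m.kind}{counters[m.kind]}",
                "start": m.start,
                "end": m.end,
                "subsequence": m.subsequence,
                "localization": ",".join(sorted(m.localization)) if m.localization else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["kind", "ordinal", "name", "start", "end", "subsequence", "localization"],
    )
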