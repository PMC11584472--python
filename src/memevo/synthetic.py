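"""Synthetic protein families with planted structure, for end-to-end testing.

The generator emits a vertebrate-like family of homologous membrane-protein
sequences with the statistical structure the analysis pipeline assumes:

* a fixed TM topology shared by all species (indel-free by default, so
  reference positions equal alignment columns; an optional indel mode
  inserts reference-gap columns to exercise the column map);
* TM columns nearly invariant (low substitution rate), loop columns
  evolving at a configurable rate relative to a background composition;
* LWI flank columns drawn i.i.d. per species from clade-specific residue
  distributions, which is how exclusion / positive-selection /
  negative-selection / conserved frequency trends are planted — the clade
  signal lives in per-column target distributions, not in a phylogenetic
  simulation, because the downstream analysis consumes frequencies, not
  trees;
* cholesterol-recognition motifs planted verbatim in the reference at known
  coordinates and held invariant across species;
* HGVS-p mutation catalogs whose Venn-cell membership (LWI / motif / both /
  neither) matches requested counts exactly.

Every output is reproducible bit-for-bit from the spec and seed, and every
planted feature is recorded in a ground-truth object so tests can assert
recovery by the corresponding pipeline stage.

The default family emulates the study conditions of a TRPM8-style analysis:
67 species (8 amphibians, 12 reptiles, 17 birds, 30 mammals), a
1104-residue protein with six TM helices and a cytoplasmic N terminus,
inner-LWI composition with positive-charge excess over negative
(≈ 17.8% vs ≈ 10.7% targets), Ala/Cys excluded from all LWI columns, and
literature-style trends (e.g. Val positively and Ile negatively selected at
the outer interface, His positively and Arg negatively at the inner).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError
from .frequencies import NATURAL_FREQUENCIES
from .motifs import MotifMatch, default_patterns
from .mutations import MutationRecord
from .seq_io import AA_ALPHABET, GAP, AlignedSet, ProteinRecord
from .topology import LWIRegion, TMSegment, Topology, derive_lwi_regions

DEFAULT_CLADE_SIZES = {"amphibian": 8, "reptile": 12, "bird": 17, "mammal": 30}
DEFAULT_TM_SEGMENTS = ((701, 721), (737, 757), (773, 793), (809, 829), (845, 865), (881, 901))
DEFAULT_PROTEIN_LENGTH = 1104

#: Residues drawn for TM cores (membrane-compatible, strongly hydrophobic).
TM_CORE_RESIDUES = "LIVFAM"
_CLADES = ("amphibian", "reptile", "bird", "mammal")


@dataclass(frozen=True)
class PlantedMotif:
    kind: str
    start: int
    end: int
    subsequence: str = ""


@dataclass(frozen=True)
class PlantedTrend:
    amino_acid: str
    region_class: str  # inner_LWI / outer_LWI
    category: str  # excluded / positive_selection / negative_selection / conserved
    clade_values: tuple[float, ...] | None = None  # weights per clade, A→R→B→M


def _default_lwi_plan() -> dict[str, dict]:
    """Per-leaflet base weights and planted trends for the default family.

    Weights are relative (normalized per clade after planting); zeros are
    exclusions and stay exactly zero.
    """
    inner_base = {
        "R": 0.0, "K": 6.0, "H": 0.0, "D": 10.7, "E": 0.0,
        "L": 11.0, "Y": 7.3, "W": 2.0, "M": 3.5, "G": 10.0,
        "S": 11.0, "T": 10.0, "V": 7.0,
        "A": 0.0, "C": 0.0, "Q": 0.0, "P": 0.0, "N": 0.0, "I": 0.0, "F": 0.0,
    }
    inner_trends = [
        PlantedTrend("H", "inner_LWI", "positive_selection", (1.0, 2.0, 3.0, 4.0)),
        PlantedTrend("R", "inner_LWI", "negative_selection", (12.0, 10.5, 9.0, 7.5)),
    ]
    inner_conserved = ["K", "D", "L", "Y", "W", "M", "G", "S", "T", "V"]
    inner_excluded = ["A", "C", "E", "Q", "P", "N", "I", "F"]

    outer_base = {
        "R": 8.5, "K": 6.5, "D": 3.3, "E": 3.3,
        "L": 8.0, "Y": 5.0, "W": 3.0, "F": 6.0, "G": 9.0,
        "S": 7.0, "T": 8.0, "P": 7.0, "N": 4.0, "Q": 3.0,
        "V": 0.0, "I": 0.0,
        "H": 0.0, "A": 0.0, "M": 0.0, "C": 0.0,
    }
    outer_trends = [
        PlantedTrend("V", "outer_LWI", "positive_selection", (2.0, 4.0, 6.5, 9.0)),
        PlantedTrend("I", "outer_LWI", "negative_selection", (8.0, 6.0, 4.0, 2.5)),
    ]
    outer_conserved = ["R", "K", "D", "E", "L", "Y", "W", "F", "G", "S", "T", "P", "N", "Q"]
    outer_excluded = ["H", "A", "M", "C"]
    return {
        "inner": {"base": inner_base, "trends": inner_trends,
                  "conserved": inner_conserved, "excluded": inner_excluded},
        "outer": {"base": outer_base, "trends": outer_trends,
                  "conserved": outer_conserved, "excluded": outer_excluded},
    }


def _default_planted_motifs() -> tuple[PlantedMotif, ...]:
    # All in loop / terminal regions of the default topology.
    return (
        PlantedMotif("CARC", 101, 110),
        PlantedMotif("CRAC", 301, 309),
        PlantedMotif("CCM", 501, 509),
        PlantedMotif("CARC", 951, 959),
    )


@dataclass
class FamilySpec:
    """Everything needed to generate one synthetic family, reproducibly."""

    n_per_clade: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLADE_SIZES))
    protein_length: int = DEFAULT_PROTEIN_LENGTH
    tm_segments: tuple[tuple[int, int], ...] = DEFAULT_TM_SEGMENTS
    n_terminus_side: str = "inner"
    flank_width: int = 5
    lwi_plan: dict = field(default_factory=_default_lwi_plan)
    planted_motifs: tuple[PlantedMotif, ...] = field(default_factory=_default_planted_motifs)
    loop_sub_rate: float = 0.10
    tm_sub_rate: float = 0.02
    n_indel_columns: int = 0
    seed: int = 0


@dataclass
class GroundTruth:
    topology: Topology
    regions: list[LWIRegion]
    planted_motifs: list[PlantedMotif]
    planted_trends: list[PlantedTrend]
    clade_distributions: dict[str, dict[str, np.ndarray]]  # leaflet -> clade -> probs
    loop_sub_rate: float
    tm_sub_rate: float
    background: dict[str, float]
    reference_id: str
    seed: int


def _background_probs() -> np.ndarray:
    w = np.array([NATURAL_FREQUENCIES[a] for a in AA_ALPHABET], dtype=float)
    return w / w.sum()


def _clade_distributions(plan: Mapping[str, dict]) -> dict[str, dict[str, np.ndarray]]:
    """Normalize base weights + planted clade values into per-clade probs."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for leaflet, block in plan.items():
        base: Mapping[str, float] = block["base"]
        trends: Sequence[PlantedTrend] = block["trends"]
        missing = set(AA_ALPHABET) - set(base)
        if missing:
            raise GenerationError(f"{leaflet} LWI plan missing residues {sorted(missing)}")
        planted = {t.amino_acid: t.clade_values for t in trends}
        out[leaflet] = {}
        for ci, clade in enumerate(_CLADES):
            w = np.array(
                [planted[a][ci] if a in planted else base[a] for a in AA_ALPHABET],
                dtype=float,
            )
            if w.sum() <= 0:
                raise GenerationError(f"{leaflet} LWI weights for clade {clade} sum to 0")
            out[leaflet][clade] = w / w.sum()
    return out


def _build_motif_sequence(motif: PlantedMotif, rng: np.random.Generator) -> str:
    """Concrete subsequence realizing a motif kind over an exact span.

    Wildcard positions are filled with residues outside every anchor class
    of the pattern so the planted span is guaranteed, and spurious nested
    anchors are kept rare (not impossible — the scanner must tolerate them).
    """
    patterns = default_patterns()
    if motif.kind not in patterns:
        raise GenerationError(f"unknown motif kind {motif.kind!r}")
    pat = patterns[motif.kind]
    span = motif.end - motif.start + 1
    total_gap = span - 3
    g2 = pat.gap2[0]
    g1 = total_gap - g2
    if not (pat.gap1[0] <= g1 <= pat.gap1[1]):
        # shift some gap into the second interval if allowed
        for g2_try in range(pat.gap2[0], pat.gap2[1] + 1):
            g1_try = total_gap - g2_try
            if pat.gap1[0] <= g1_try <= pat.gap1[1]:
                g1, g2 = g1_try, g2_try
                break
        else:
            raise GenerationError(
                f"{motif.kind} cannot span {span} residues "
                f"(needs {pat.min_span}..{pat.max_span})"
            )
    anchor_classes = pat.first | pat.central | pat.last
    wildcard_pool = [a for a in "GSTNQDEP" if a not in anchor_classes] or ["G"]
    def wild(n: int) -> str:
        return "".join(rng.choice(wildcard_pool, size=n))
    first = str(rng.choice(sorted(pat.first)))
    central = str(rng.choice(sorted(pat.central)))
    last = str(rng.choice(sorted(pat.last)))
    return first + wild(g1) + central + wild(g2) + last


def generate_family(
    spec: FamilySpec,
) -> tuple[AlignedSet, pd.DataFrame, Topology, GroundTruth]:
    """Generate one family: alignment, metadata table, topology, ground truth.

    The reference record is the first mammal (id ``mammal_01``); with the
    default indel-free mode its residue numbering equals alignment columns.
    """
    if spec.n_per_clade.get("mammal", 0) < 1:
        raise GenerationError("the family needs at least one mammal (the reference record)")
    rng = np.random.default_rng(spec.seed)
    segments = tuple(
        TMSegment(index=i, start=s, end=e)
        for i, (s, e) in enumerate(spec.tm_segments, start=1)
    )
    topo = Topology(
        segments=segments,
        n_terminus_side=spec.n_terminus_side,
        protein_length=spec.protein_length,
    )
    regions = derive_lwi_regions(topo, flank_width=spec.flank_width)
    L = spec.protein_length

    # classify positions: 0 loop, 1 TM, 2 LWI (leaflet recorded separately)
    kind = np.zeros(L + 1, dtype=np.int8)  # 1-based, index 0 unused
    leaflet_at: dict[int, str] = {}
    for seg in segments:
        kind[seg.start : seg.end + 1] = 1
    for r in regions:
        for p in r.positions:
            if kind[p] == 1:
                raise GenerationError(f"LWI region {r.label} intersects a TM span")
            kind[p] = 2
            leaflet_at[p] = r.leaflet

    # planted motifs must sit in loop territory (LWI/TM columns follow their
    # own distributions and would destroy the motif)
    motif_positions: dict[int, str] = {}
    realized: list[PlantedMotif] = []
    for motif in spec.planted_motifs:
        if motif.start < 1 or motif.end > L:
            raise GenerationError(f"planted {motif.kind} at {motif.start}-{motif.end} outside 1..{L}")
        seq = motif.subsequence or _build_motif_sequence(motif, rng)
        if len(seq) != motif.end - motif.start + 1:
            raise GenerationError(
                f"planted {motif.kind} subsequence length {len(seq)} != span {motif.start}-{motif.end}"
            )
        for offset, ch in enumerate(seq):
            p = motif.start + offset
            if kind[p] != 0:
                raise GenerationError(
                    f"planted {motif.kind} at {motif.start}-{motif.end} collides with a "
                    f"{'TM' if kind[p] == 1 else 'LWI'} column at {p}"
                )
            if p in motif_positions and motif_positions[p] != ch:
                raise GenerationError(
                    f"planted motifs conflict at position {p} "
                    f"({motif_positions[p]!r} vs {ch!r})"
                )
            motif_positions[p] = ch
        realized.append(replace(motif, subsequence=seq))

    bg = _background_probs()
    aa = np.array(list(AA_ALPHABET))
    dists = _clade_distributions(spec.lwi_plan)

    # reference sequence (mammal)
    ref = np.empty(L + 1, dtype="<U1")
    for p in range(1, L + 1):
        if p in motif_positions:
            ref[p] = motif_positions[p]
        elif kind[p] == 1:
            ref[p] = rng.choice(list(TM_CORE_RESIDUES))
        elif kind[p] == 2:
            ref[p] = rng.choice(aa, p=dists[leaflet_at[p]]["mammal"])
        else:
            ref[p] = rng.choice(aa, p=bg)

    records: list[ProteinRecord] = []
    meta_rows = []
    for clade in _CLADES:
        n = spec.n_per_clade.get(clade, 0)
        for i in range(1, n + 1):
            sid = f"{clade}_{i:02d}"
            is_ref = clade == "mammal" and i == 1
            seq = np.empty(L + 1, dtype="<U1")
            for p in range(1, L + 1):
                if p in motif_positions:
                    seq[p] = ref[p]  # planted motifs held invariant
                elif kind[p] == 2:
                    seq[p] = rng.choice(aa, p=dists[leaflet_at[p]][clade])
                elif kind[p] == 1:
                    if is_ref or rng.random() >= spec.tm_sub_rate:
                        seq[p] = ref[p]
                    else:
                        seq[p] = rng.choice(list(TM_CORE_RESIDUES))
                else:
                    if is_ref or rng.random() >= spec.loop_sub_rate:
                        seq[p] = ref[p]
                    else:
                        seq[p] = rng.choice(aa, p=bg)
            records.append(
                ProteinRecord(
                    id=sid,
                    sequence="".join(seq[1:]),
                    species=f"{clade.capitalize()} species {i}",
                    clade=clade,
                )
            )
            meta_rows.append({"id": sid, "species": records[-1].species, "clade": clade})

    reference_id = "mammal_01"
    if spec.n_indel_columns > 0:
        records = _insert_indel_columns(records, reference_id, spec.n_indel_columns, kind, rng, bg, aa)

    aln = AlignedSet(records=records, reference_id=reference_id)
    meta = pd.DataFrame(meta_rows)
    meta["thermal_class"] = meta["clade"].map(
        {"amphibian": "cold", "reptile": "cold", "bird": "warm", "mammal": "warm"}
    )
    trends: list[PlantedTrend] = []
    for leaflet, block in spec.lwi_plan.items():
        rc = f"{leaflet}_LWI"
        trends.extend(block["trends"])
        trends.extend(PlantedTrend(a, rc, "excluded") for a in block["excluded"])
        trends.extend(PlantedTrend(a, rc, "conserved") for a in block["conserved"])
    truth = GroundTruth(
        topology=topo,
        regions=regions,
        planted_motifs=realized,
        planted_trends=trends,
        clade_distributions=dists,
        loop_sub_rate=spec.loop_sub_rate,
        tm_sub_rate=spec.tm_sub_rate,
        background=dict(zip(AA_ALPHABET, bg)),
        reference_id=reference_id,
        seed=spec.seed,
    )
    return aln, meta, topo, truth


def _insert_indel_columns(
    records: list[ProteinRecord],
    reference_id: str,
    n_columns: int,
    kind: np.ndarray,
    rng: np.random.Generator,
    bg: np.ndarray,
    aa: np.ndarray,
) -> list[ProteinRecord]:
    """Insert columns that are gaps in the reference (insertions elsewhere).

    Chosen loop positions acquire one extra column to their right; the
    reference receives ``-`` there while every other record receives a
    background-drawn residue.  This makes reference numbering differ from
    column numbering, exercising the column map.
    """
    L = len(records[0].sequence)
    loop_positions = [p for p in range(1, L + 1) if kind[p] == 0]
    sites = sorted(rng.choice(loop_positions, size=n_columns, replace=False))
    out = []
    for rec in records:
        chunks, prev = [], 0
        for s in sites:
            chunks.append(rec.sequence[prev:s])
            chunks.append(GAP if rec.id == reference_id else str(rng.choice(aa, p=bg)))
            prev = s
        chunks.append(rec.sequence[prev:])
        out.append(replace(rec, sequence="".join(chunks)))
    return out


def generate_mutation_catalog(
    regions: Sequence[LWIRegion],
    motifs: Sequence[MotifMatch] | Sequence[PlantedMotif],
    reference: ProteinRecord,
    n_in_lwi: int,
    n_in_motif: int,
    n_in_both: int,
    n_outside: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Emit an HGVS-p catalog with exact Venn-cell membership.

    ``n_in_lwi`` / ``n_in_motif`` are the *total* LWI and motif counts (each
    including the ``n_in_both`` intersection).  One distinct position per
    entry; entries are missense changes consistent with the reference
    sequence.  Infeasible requests (cell larger than the available position
    pool, or ``n_in_both`` exceeding a marginal) raise
    :class:`GenerationError`.
    """
    if n_in_both > min(n_in_lwi, n_in_motif):
        raise GenerationError(
            f"n_in_both={n_in_both} exceeds a marginal "
            f"(n_in_lwi={n_in_lwi}, n_in_motif={n_in_motif})"
        )
    if min(n_in_lwi, n_in_motif, n_in_both, n_outside) < 0:
        raise GenerationError("cell counts must be non-negative")
    rng = np.random.default_rng(seed)
    L = len(reference.sequence)
    lwi = {p for r in regions for p in r.positions if p <= L}
    mot = {
        p
        for m in motifs
        for p in range(m.start, m.end + 1)
        if p <= L
    }
    pools = {
        "both": sorted(lwi & mot),
        "lwi_only": sorted(lwi - mot),
        "motif_only": sorted(mot - lwi),
        "neither": sorted(set(range(1, L + 1)) - lwi - mot),
    }
    wanted = {
        "both": n_in_both,
        "lwi_only": n_in_lwi - n_in_both,
        "motif_only": n_in_motif - n_in_both,
        "neither": n_outside,
    }
    rows, truth = [], {k: [] for k in wanted}
    for cell, count in wanted.items():
        if count > len(pools[cell]):
            raise GenerationError(
                f"cell {cell!r}: requested {count} positions but only "
                f"{len(pools[cell])} available"
            )
        chosen = rng.choice(pools[cell], size=count, replace=False) if count else []
        for p in sorted(int(x) for x in chosen):
            ref_aa = reference.sequence[p - 1]
            alt = str(rng.choice([a for a in AA_ALPHABET if a != ref_aa]))
            hgvs = f"p.{ref_aa}{p}{alt}"
            rows.append({"hgvs": hgvs, "position": p, "cell": cell})
            truth[cell].append(hgvs)
    df = pd.DataFrame(rows, columns=["hgvs", "position", "cell"])
    return df, truth


def conserved_control_fixture(
    n_sequences: int = 12, length: int = 103, seed: int = 7
) -> AlignedSet:
    """A synthetic near-invariant alignment (histone-H4-like control).

    Histone H4 is the classic almost perfectly conserved protein used as the
    low-divergence control in conservation box plots; this fixture emulates
    that behaviour with a 103-residue family in which each non-reference
    sequence carries at most one substitution.  It is generated, not a real
    histone alignment.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ALPHABET))
    base = rng.choice(aa, p=_background_probs(), size=length)
    records = []
    for i in range(n_sequences):
        seq = base.copy()
        if i > 0 and rng.random() < 0.5:
            p = int(rng.integers(0, length))
            seq[p] = rng.choice([a for a in AA_ALPHABET if a != seq[p]])
        records.append(
            ProteinRecord(id=f"h4like_{i + 1:02d}", sequence="".join(seq), species=f"control {i + 1}")
        )
    return AlignedSet(records=records, reference_id=records[0].id)


def shuffled_columns(aln: AlignedSet, seed: int = 0) -> AlignedSet:
    """Randomize each column's residues across positions within sequences.

    Permutes the residues of every sequence independently, destroying
    column-wise conservation while keeping composition — the matched
    negative control for divergence comparisons.
    """
    rng = np.random.default_rng(seed)
    records = []
    for rec in aln.records:
        chars = np.array(list(rec.sequence))
        rng.shuffle(chars)
        records.append(replace(rec, sequence="".join(chars)))
    return AlignedSet(records=records, reference_id=aln.reference_id)
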