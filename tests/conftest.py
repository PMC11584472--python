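"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import pytest

from memevo import (
    AlignedSet,
    FamilySpec,
    ProteinRecord,
    TMSegment,
    Topology,
    build_column_map,
    derive_lwi_regions,
    generate_family,
    region_frequencies,
)


# ---------------------------------------------------------------------------
# Oracles (deliberately dumb; independent of the implementation they check)

def brute_force_motif_triples(seq: str, pattern) -> set[tuple[int, int, int]]:
    """All admissible anchor triples by O(n^3) enumeration over positions."""
    n = len(seq)
    (g1lo, g1hi), (g2lo, g2hi) = pattern.gap1, pattern.gap2
    found = set()
    for i, j, k in itertools.combinations(range(1, n + 1), 3):
        if (
            seq[i - 1] in pattern.first
            and seq[j - 1] in pattern.central
            and seq[k - 1] in pattern.last
            and g1lo <= j - i - 1 <= g1hi
            and g2lo <= k - j - 1 <= g2hi
        ):
            found.add((i, j, k))
    return found


def brute_force_membership(pos: int, intervals) -> bool:
    return any(lo <= pos <= hi for lo, hi in intervals)


def exact_mann_whitney_p(x, y, alternative="two-sided") -> float:
    """Exact two-sample U-test p by enumerating all label assignments."""
    pooled = sorted(x + y)
    ranks = {}
    # no ties assumed by callers
    for r, v in enumerate(pooled, start=1):
        ranks[v] = r
    n1 = len(x)

    def u_of(sample):
        r1 = sum(ranks[v] for v in sample)
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(x)
    n = len(pooled)
    us = [u_of(list(c)) for c in itertools.combinations(pooled, n1)]
    total = len(us)
    if alternative == "less":
        return sum(u <= u_obs for u in us) / total
    if alternative == "greater":
        return sum(u >= u_obs for u in us) / total
    lo = sum(u <= u_obs for u in us) / total
    hi = sum(u >= u_obs for u in us) / total
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------
# Fixtures

@pytest.fixture
def toy_topology() -> Topology:
    """Two TM helices, cytoplasmic N terminus, comfortable flank room."""
    return Topology(
        segments=(TMSegment(1, 11, 30), TMSegment(2, 46, 65)),
        n_terminus_side="inner",
        protein_length=100,
    )


@pytest.fixture
def six_tm_topology() -> Topology:
    starts = [701, 737, 773, 809, 845, 881]
    return Topology(
        segments=tuple(TMSegment(i + 1, s, s + 20) for i, s in enumerate(starts)),
        n_terminus_side="inner",
        protein_length=1104,
    )


@pytest.fixture
def toy_alignment() -> AlignedSet:
    """Three sequences, reference with internal gaps (hand-checkable)."""
    return AlignedSet(
        records=[
            ProteinRecord(id="ref", sequence="A-CDE-FG"),
            ProteinRecord(id="s2", sequence="AACDEEFG"),
            ProteinRecord(id="s3", sequence="AAC-EEFG"),
        ],
        reference_id="ref",
    )


@pytest.fixture(scope="session")
def default_family():
    """The default synthetic family (67 species, 6 TM, planted structure)."""
    return generate_family(FamilySpec(seed=1))


@pytest.fixture(scope="session")
def default_family_freqs(default_family):
    aln, meta, topo, truth = default_family
    cmap = build_column_map(aln, truth.reference_id)
    return region_frequencies(aln, truth.regions, topo, cmap)
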