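"""Residue-frequency profiles per region class and clade, and trend calls.

For every species the residues falling in a region class (inner LWI, outer
LWI, total LWI, N/C-side LWI, TM, full length) are collected through the
column map and converted to per-amino-acid percentages (gaps and ambiguity
codes excluded from the denominator).  Species-level percentages — not
pooled residues — are the units for all downstream statistics, matching the
per-species dots of the usual frequency scatter plots; pooled percentages
are available via ``pooled=True``.

Evolutionary trends along the clade order amphibian → reptile → bird →
mammal are classified per amino acid and region class:

* ``excluded``            — frequency 0 in every species;
* ``positive_selection``  — significant Spearman correlation (frequency vs
  clade rank) with positive sign;
* ``negative_selection``  — the same with negative sign;
* ``conserved``           — no significant trend and the coefficient of
  variation of clade means ≤ ``cv_max``;
* ``variable``            — everything else.

Non-excluded residues are further tagged ``above``/``below``/``equal``
relative to a background ("natural") composition, with a relative tolerance
band.  These criteria are this package's operationalization of what is
usually judged by eye from frequency plots; every threshold is a parameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conservation import MannWhitneyResult, mann_whitney_u
from .errors import InputError, ValidationError
from .seq_io import AA_ALPHABET, AA_SET, GAP, AlignedSet, ColumnMap
from .topology import LWIRegion, Topology

logger = logging.getLogger("memevo")

REGION_CLASSES = (
    "inner_LWI",
    "outer_LWI",
    "total_LWI",
    "N_LWI",
    "C_LWI",
    "TM",
    "full_length",
)

CLADE_ORDER = ("amphibian", "reptile", "bird", "mammal")

#: Background amino-acid composition (percent) — average over the manually
#: curated UniProtKB/Swiss-Prot protein database (release statistics).  Used
#: as the default "natural frequency" baseline; replaceable via the
#: ``natural`` argument of the trend classifiers.
NATURAL_FREQUENCIES: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.65, "T": 5.36, "W": 1.10, "Y": 2.92, "V": 6.85,
}


@dataclass(frozen=True)
class ResidueClassScheme:
    """Hydropathy and charge classes of the 20 residues.

    The hydropathy split follows the membrane-protein frequency-analysis
    convention this pipeline reproduces: Trp, Phe, Tyr, Leu, Ile, Cys, Met
    hydrophobic; Ala, Arg, Asn, Asp, Gln, His, Pro, Ser, Thr, Lys, Gly, Val
    hydrophilic; Glu unassigned by default (``glu_hydrophilic=True`` folds
    it into the hydrophilic class).  Charge: R/K/H positive, D/E negative.
    """

    hydrophobic: frozenset[str] = frozenset("WFYLICM")
    hydrophilic: frozenset[str] = frozenset("ARNDQHPSTKGV")
    positive: frozenset[str] = frozenset("RKH")
    negative: frozenset[str] = frozenset("DE")

    def __post_init__(self) -> None:
        if self.hydrophobic & self.hydrophilic:
            raise ValidationError("hydrophobic and hydrophilic classes overlap")
        if self.positive & self.negative:
            raise ValidationError("positive and negative classes overlap")
        if not (self.hydrophobic | self.hydrophilic) <= AA_SET:
            raise ValidationError("hydropathy classes contain non-canonical residues")

    @property
    def unassigned_hydropathy(self) -> frozenset[str]:
        return AA_SET - self.hydrophobic - self.hydrophilic

    @classmethod
    def with_glu_hydrophilic(cls) -> "ResidueClassScheme":
        return cls(hydrophilic=frozenset("ARNDQHPSTKGVE"))


def region_class_positions(
    regions: Sequence[LWIRegion], topo: Topology
) -> dict[str, list[int]]:
    """Reference positions per region class.

    Overlapping flanks contribute their positions once per region (slot
    counting), so ``total_LWI`` of a 6-TM topology with 5-residue flanks
    always has 60 slots even when neighbouring flanks overlap.
    """
    inner = [p for r in regions if r.leaflet == "inner" for p in r.positions]
    outer = [p for r in regions if r.leaflet == "outer" for p in r.positions]
    n_side = [p for r in regions if r.terminus == "N" for p in r.positions]
    c_side = [p for r in regions if r.terminus == "C" for p in r.positions]
    tm = [p for seg in topo.segments for p in range(seg.start, seg.end + 1)]
    return {
        "inner_LWI": inner,
        "outer_LWI": outer,
        "total_LWI": inner + outer,
        "N_LWI": n_side,
        "C_LWI": c_side,
        "TM": tm,
        "full_length": list(range(1, topo.protein_length + 1)),
    }


def region_frequencies(
    aln: AlignedSet,
    regions: Sequence[LWIRegion],
    topo: Topology,
    cmap: ColumnMap,
    region_classes: Iterable[str] = REGION_CLASSES,
) -> pd.DataFrame:
    """Per-species residue percentages for each region class.

    Returns a tidy frame with columns ``region_class, id, species, clade,
    aa, count, pct, n_residues``; for every (region class, species) the 20
    percentages sum to 100 (gaps/ambiguity codes excluded from the
    denominator).  A species whose region maps entirely to gaps is excluded
    from that region class with a warning.
    """
    class_pos = region_class_positions(regions, topo)
    rows = []
    for region_class in region_classes:
        if region_class not in class_pos:
            raise InputError(f"unknown region class {region_class!r}")
        cols = cmap.columns_for(class_pos[region_class])
        for rec in aln.records:
            counts = {aa: 0 for aa in AA_ALPHABET}
            n = 0
            for c in cols:
                ch = rec.sequence[c - 1]
                if ch in AA_SET:
                    counts[ch] += 1
                    n += 1
            if n == 0:
                logger.warning(
                    "species %r has only gaps in region class %s; excluded",
                    rec.id, region_class,
                )
                continue
            for aa in AA_ALPHABET:
                rows.append(
                    {
                        "region_class": region_class,
                        "id": rec.id,
                        "species": rec.species,
                        "clade": rec.clade,
                        "aa": aa,
                        "count": counts[aa],
                        "pct": 100.0 * counts[aa] / n,
                        "n_residues": n,
                    }
                )
    return pd.DataFrame(rows)


def pooled_frequencies(freqs: pd.DataFrame) -> pd.DataFrame:
    """Pool residues across species per region class (alternative units)."""
    g = freqs.groupby(["region_class", "aa"], as_index=False)["count"].sum()
    totals = g.groupby("region_class")["count"].transform("sum")
    g["pct"] = 100.0 * g["count"] / totals
    return g


@dataclass(frozen=True)
class TrendCall:
    amino_acid: str
    region_class: str
    category: str  # excluded / positive_selection / negative_selection / conserved / variable
    natural_rel: str  # above / below / equal / n/a
    rho: float
    p_value: float
    clade_means: dict[str, float]
    grand_mean: float
    natural_freq: float
    note: str = ""


def classify_trend(
    per_species: pd.DataFrame,
    natural_freq: float,
    clade_order: Sequence[str] = CLADE_ORDER,
    alpha: float = 0.05,
    cv_max: float = 0.5,
    natural_tol: float = 0.20,
    amino_acid: str = "",
    region_class: str = "",
) -> TrendCall:
    """Classify one residue's frequency trend across the clade order.

    ``per_species`` needs columns ``clade`` and ``pct`` (one row per
    species).  The trend test is a Spearman correlation between per-species
    percentage and clade rank; it requires at least two clades with two or
    more species each, otherwise it is skipped (noted) and only the
    exclusion/conservation rules apply.
    """
    present = per_species[per_species["clade"].isin(clade_order)]
    values = present["pct"].to_numpy(dtype=float)
    if len(values) == 0:
        raise InputError("classify_trend received no species rows")
    clade_means = {
        clade: float(grp["pct"].mean())
        for clade, grp in present.groupby("clade")
    }
    clade_means = {c: clade_means[c] for c in clade_order if c in clade_means}
    grand_mean = float(values.mean())

    if np.all(values == 0):
        return TrendCall(
            amino_acid, region_class, "excluded", "n/a",
            rho=float("nan"), p_value=float("nan"),
            clade_means=clade_means, grand_mean=0.0, natural_freq=natural_freq,
        )

    note = ""
    rho, p = float("nan"), float("nan")
    sizes = present.groupby("clade").size()
    testable = (sizes >= 2).sum() >= 2
    missing = [c for c in clade_order if c not in clade_means]
    if missing:
        note = f"missing clades {missing}; trend test skipped"
        testable = False
    if testable:
        ranks = present["clade"].map({c: i for i, c in enumerate(clade_order)})
        if np.ptp(values) > 0:
            rho, p = stats.spearmanr(ranks.to_numpy(), values)
            rho, p = float(rho), float(p)
        else:
            rho, p = 0.0, 1.0
    elif not note:
        note = "too few species per clade; trend test skipped"

    if testable and not math.isnan(p) and p < alpha and rho != 0:
        category = "positive_selection" if rho > 0 else "negative_selection"
    else:
        means = np.array(list(clade_means.values()))
        cv = float(means.std(ddof=0) / means.mean()) if means.mean() > 0 else float("inf")
        category = "conserved" if cv <= cv_max else "variable"

    if natural_freq > 0 and abs(grand_mean - natural_freq) <= natural_tol * natural_freq:
        natural_rel = "equal"
    elif grand_mean > natural_freq:
        natural_rel = "above"
    else:
        natural_rel = "below"

    return TrendCall(
        amino_acid, region_class, category, natural_rel,
        rho=rho, p_value=p, clade_means=clade_means,
        grand_mean=grand_mean, natural_freq=natural_freq, note=note,
    )


def classify_all_trends(
    freqs: pd.DataFrame,
    region_classes: Iterable[str] = ("inner_LWI", "outer_LWI", "total_LWI"),
    natural: Mapping[str, float] = NATURAL_FREQUENCIES,
    **params,
) -> pd.DataFrame:
    """Trend calls for every amino acid in each requested region class."""
    rows = []
    for region_class in region_classes:
        sub = freqs[freqs["region_class"] == region_class]
        if sub.empty:
            raise InputError(f"no frequency rows for region class {region_class!r}")
        for aa in AA_ALPHABET:
            call = classify_trend(
                sub[sub["aa"] == aa][["clade", "pct"]],
                natural_freq=natural[aa],
                amino_acid=aa,
                region_class=region_class,
                **params,
            )
            rows.append(
                {
                    "region_class": region_class,
                    "aa": aa,
                    "category": call.category,
                    "natural_rel": call.natural_rel,
                    "rho": call.rho,
                    "p_value": call.p_value,
                    "grand_mean": call.grand_mean,
                    "natural_freq": call.natural_freq,
                    **{f"mean_{c}": call.clade_means.get(c, float("nan")) for c in CLADE_ORDER},
                    "note": call.note,
                }
            )
    return pd.DataFrame(rows)


def class_ratios(freqs: pd.DataFrame, scheme: ResidueClassScheme | None = None) -> pd.DataFrame:
    """Charge and hydropathy class totals and ratios per (region, species).

    Ratios are reported in both orientations, explicitly named
    (``pos_neg_ratio`` = positive/negative, ``neg_pos_ratio`` the inverse,
    likewise hydropathy); a zero denominator yields NaN.
    """
    scheme = scheme or ResidueClassScheme()
    rows = []
    for (region_class, sid), grp in freqs.groupby(["region_class", "id"]):
        pct = dict(zip(grp["aa"], grp["pct"]))
        pos = sum(pct.get(a, 0.0) for a in scheme.positive)
        neg = sum(pct.get(a, 0.0) for a in scheme.negative)
        pho = sum(pct.get(a, 0.0) for a in scheme.hydrophobic)
        phi = sum(pct.get(a, 0.0) for a in scheme.hydrophilic)
        una = sum(pct.get(a, 0.0) for a in scheme.unassigned_hydropathy)
        clade = grp["clade"].iloc[0]
        rows.append(
            {
                "region_class": region_class,
                "id": sid,
                "clade": clade,
                "positive_pct": pos,
                "negative_pct": neg,
                "pos_neg_ratio": pos / neg if neg > 0 else float("nan"),
                "neg_pos_ratio": neg / pos if pos > 0 else float("nan"),
                "hydrophobic_pct": pho,
                "hydrophilic_pct": phi,
                "unassigned_pct": una,
                "phob_phil_ratio": pho / phi if phi > 0 else float("nan"),
                "phil_phob_ratio": phi / pho if pho > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


GROUPINGS: dict[str, tuple[frozenset[str], frozenset[str], tuple[str, str]]] = {
    "cold_vs_warm": (frozenset({"amphibian", "reptile"}), frozenset({"bird", "mammal"}), ("cold", "warm")),
    "bird_vs_mammal": (frozenset({"bird"}), frozenset({"mammal"}), ("bird", "mammal")),
    "reptile_vs_bird": (frozenset({"reptile"}), frozenset({"bird"}), ("reptile", "bird")),
}


def significance_stars(p: float) -> str:
    """Star labels matching the frequency-plot legend convention."""
    if math.isnan(p):
        return "n/a"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "**"
    return "ns"


@dataclass(frozen=True)
class GroupCompareResult:
    grouping: str
    amino_acid: str
    region_class: str
    group_names: tuple[str, str]
    means: tuple[float, float]
    n: tuple[int, int]
    U: float
    p: float
    stars: str
    skipped: bool = False


def group_compare(
    freqs: pd.DataFrame,
    grouping: str,
    amino_acid: str,
    region_class: str,
) -> GroupCompareResult:
    """Two-sided Mann-Whitney comparison of per-species frequencies.

    Groups are defined by clade membership (e.g. ectotherm amphibian+reptile
    vs endotherm bird+mammal).  A group with fewer than two species skips
    the test with a warning (p = NaN).
    """
    if grouping not in GROUPINGS:
        raise InputError(f"unknown grouping {grouping!r}; choose from {sorted(GROUPINGS)}")
    clades_a, clades_b, names = GROUPINGS[grouping]
    sub = freqs[(freqs["region_class"] == region_class) & (freqs["aa"] == amino_acid)]
    a = sub[sub["clade"].isin(clades_a)]["pct"].tolist()
    b = sub[sub["clade"].isin(clades_b)]["pct"].tolist()
    if len(a) < 2 or len(b) < 2:
        logger.warning(
            "grouping %s for %s/%s: a group has <2 species; test skipped",
            grouping, amino_acid, region_class,
        )
        return GroupCompareResult(
            grouping, amino_acid, region_class, names,
            means=(float(np.mean(a)) if a else float("nan"),
                   float(np.mean(b)) if b else float("nan")),
            n=(len(a), len(b)), U=float("nan"), p=float("nan"),
            stars="n/a", skipped=True,
        )
    res: MannWhitneyResult = mann_whitney_u(a, b, alternative="two-sided")
    return GroupCompareResult(
        grouping, amino_acid, region_class, names,
        means=(float(np.mean(a)), float(np.mean(b))),
        n=(len(a), len(b)), U=res.U, p=res.p, stars=significance_stars(res.p),
    )
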