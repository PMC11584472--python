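"""Region frequency tables, trend classification, ratios, group tests."""

import numpy as np
import pandas as pd
import pytest

from memevo import (
    AlignedSet,
    ProteinRecord,
    ResidueClassScheme,
    TMSegment,
    Topology,
    build_column_map,
    class_ratios,
    classify_all_trends,
    classify_trend,
    derive_lwi_regions,
    group_compare,
    region_frequencies,
)
from memevo.frequencies import NATURAL_FREQUENCIES, pooled_frequencies, significance_stars

AA = "ACDEFGHIKLMNPQRSTVWY"


def _single_region_family(lwi_residues: str):
    """One species whose single 5-residue inner flank holds lwi_residues."""
    topo = Topology(
        segments=(TMSegment(1, 11, 20),), n_terminus_side="inner", protein_length=30
    )
    regs = derive_lwi_regions(topo)
    seq = "A" * 5 + lwi_residues + "L" * 10 + "GGGGG" + "A" * 5
    aln = AlignedSet(records=[ProteinRecord(id="s1", sequence=seq, clade="mammal")], reference_id="s1")
    cmap = build_column_map(aln, "s1")
    return aln, regs, topo, cmap


class TestRegionFrequencies:
    def test_charge_classes_on_known_region(self):
        aln, regs, topo, cmap = _single_region_family("RRKDE")
        freqs = region_frequencies(aln, regs, topo, cmap, region_classes=["inner_LWI"])
        ratios = class_ratios(freqs)
        row = ratios.iloc[0]
        assert row["positive_pct"] == pytest.approx(60.0)
        assert row["negative_pct"] == pytest.approx(40.0)

    def test_percentages_sum_to_100_per_species(self, default_family_freqs):
        sums = default_family_freqs.groupby(["region_class", "id"])["pct"].sum()
        assert np.allclose(sums, 100.0)

    def test_gap_only_species_excluded(self):
        topo = Topology(segments=(TMSegment(1, 11, 20),), n_terminus_side="inner", protein_length=30)
        regs = derive_lwi_regions(topo)
        ref = "A" * 30
        gappy = "A" * 5 + "-" * 5 + "A" * 20  # all-gap inner flank
        aln = AlignedSet(
            records=[ProteinRecord(id="ref", sequence=ref), ProteinRecord(id="g", sequence=gappy)],
            reference_id="ref",
        )
        cmap = build_column_map(aln, "ref")
        freqs = region_frequencies(aln, regs, topo, cmap, region_classes=["inner_LWI"])
        assert set(freqs["id"]) == {"ref"}

    def test_pooled_frequencies_sum_to_100(self, default_family_freqs):
        pooled = pooled_frequencies(default_family_freqs)
        sums = pooled.groupby("region_class")["pct"].sum()
        assert np.allclose(sums, 100.0)

    def test_class_totals_partition(self, default_family_freqs):
        scheme = ResidueClassScheme()
        ratios = class_ratios(default_family_freqs, scheme)
        total = ratios["hydrophobic_pct"] + ratios["hydrophilic_pct"] + ratios["unassigned_pct"]
        assert np.allclose(total, 100.0)
        assert (ratios["positive_pct"] + ratios["negative_pct"] <= 100.0 + 1e-9).all()


def _species_table(clade_values, n_per_clade=6, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for clade, v in zip(("amphibian", "reptile", "bird", "mammal"), clade_values):
        for _ in range(n_per_clade):
            rows.append({"clade": clade, "pct": max(0.0, v + rng.normal(0, noise))})
    return pd.DataFrame(rows)


class TestClassifyTrend:
    def test_all_zero_is_excluded(self):
        call = classify_trend(_species_table([0, 0, 0, 0]), natural_freq=1.38)
        assert call.category == "excluded"
        assert call.natural_rel == "n/a"

    def test_monotone_increase_is_positive_selection(self):
        call = classify_trend(_species_table([0, 2, 5, 8], noise=0.5, seed=1), natural_freq=5.0)
        assert call.category == "positive_selection"
        assert call.rho > 0 and call.p_value < 0.05

    def test_monotone_decrease_is_negative_selection(self):
        call = classify_trend(_species_table([8, 5, 2, 0.5], noise=0.5, seed=2), natural_freq=5.0)
        assert call.category == "negative_selection"

    def test_flat_at_natural_is_conserved_equal(self):
        call = classify_trend(_species_table([5, 5, 5, 5]), natural_freq=5.0)
        assert call.category == "conserved"
        assert call.natural_rel == "equal"

    def test_natural_rel_above_below(self):
        above = classify_trend(_species_table([9, 9, 9, 9]), natural_freq=5.0)
        below = classify_trend(_species_table([1, 1, 1, 1]), natural_freq=5.0)
        assert above.natural_rel == "above" and below.natural_rel == "below"

    def test_spearman_matches_direct_computation(self):
        """Spearman on the constructed table equals a direct rank correlation."""
        from scipy import stats as ss
        tbl = _species_table([0, 2, 5, 8], noise=1.0, seed=3)
        call = classify_trend(tbl, natural_freq=5.0)
        ranks = tbl["clade"].map({"amphibian": 0, "reptile": 1, "bird": 2, "mammal": 3})
        rho, p = ss.spearmanr(ranks, tbl["pct"])
        assert call.rho == pytest.approx(float(rho))
        assert call.p_value == pytest.approx(float(p))

    def test_missing_clade_skips_trend_test(self):
        tbl = _species_table([3, 3, 3, 3]).query("clade != 'bird'")
        call = classify_trend(tbl, natural_freq=3.0)
        assert "missing clades" in call.note
        assert call.category in ("conserved", "variable")

    def test_permuted_labels_type_I_rate_near_alpha(self):
        """Directional calls on label-permuted flat data occur at rate ≈ α."""
        rng = np.random.default_rng(99)
        n_sim, hits = 200, 0
        for _ in range(n_sim):
            tbl = _species_table([5, 5, 5, 5], noise=1.0, seed=int(rng.integers(2**31)))
            tbl["clade"] = rng.permutation(tbl["clade"].to_numpy())
            call = classify_trend(tbl, natural_freq=5.0, alpha=0.05)
            hits += call.category in ("positive_selection", "negative_selection")
        assert hits / n_sim < 0.12  # ≈ 0.05 with binomial slack


class TestPlantedTrendRecovery:
    def test_at_least_90pct_of_planted_calls_recovered(self, default_family, default_family_freqs):
        aln, meta, topo, truth = default_family
        calls = classify_all_trends(default_family_freqs).set_index(["region_class", "aa"])
        planted = truth.planted_trends
        hits = sum(
            calls.loc[(p.region_class, p.amino_acid), "category"] == p.category
            for p in planted
        )
        assert hits / len(planted) >= 0.90


class TestRatios:
    def test_simple_ratio(self):
        aln, regs, topo, cmap = _single_region_family("RRKKD")
        freqs = region_frequencies(aln, regs, topo, cmap, region_classes=["inner_LWI"])
        row = class_ratios(freqs).iloc[0]
        assert row["pos_neg_ratio"] == pytest.approx(4.0)
        assert row["neg_pos_ratio"] == pytest.approx(0.25)

    def test_zero_denominator_is_nan(self):
        aln, regs, topo, cmap = _single_region_family("RRKKK")
        row = class_ratios(region_frequencies(aln, regs, topo, cmap, region_classes=["inner_LWI"])).iloc[0]
        assert np.isnan(row["pos_neg_ratio"])

    def test_glu_unassigned_by_default(self):
        scheme = ResidueClassScheme()
        assert scheme.unassigned_hydropathy == frozenset({"E"})
        assert "E" in ResidueClassScheme.with_glu_hydrophilic().hydrophilic


class TestGroupCompare:
    def test_identical_groups_high_p(self):
        rows = []
        for clade in ("amphibian", "reptile", "bird", "mammal"):
            for i in range(5):
                rows.append({"region_class": "inner_LWI", "aa": "L", "clade": clade, "pct": float(i)})
        freqs = pd.DataFrame(rows)
        res = group_compare(freqs, "cold_vs_warm", "L", "inner_LWI")
        assert res.p > 0.9

    def test_planted_val_shift_detected_with_direction(self, default_family_freqs):
        """Outer-LWI Val rises from ectotherms to endotherms by construction."""
        res = group_compare(default_family_freqs, "cold_vs_warm", "V", "outer_LWI")
        assert res.means[1] > res.means[0]
        assert res.p < 1e-3
        assert res.stars in ("**", "****")

    def test_bird_vs_mammal_on_planted_outer_val(self, default_family_freqs):
        res = group_compare(default_family_freqs, "bird_vs_mammal", "V", "outer_LWI")
        assert res.means[1] > res.means[0]
        assert res.p < 0.05

    def test_small_group_skipped(self):
        freqs = pd.DataFrame(
            [
                {"region_class": "inner_LWI", "aa": "L", "clade": "bird", "pct": 1.0},
                {"region_class": "inner_LWI", "aa": "L", "clade": "mammal", "pct": 2.0},
                {"region_class": "inner_LWI", "aa": "L", "clade": "mammal", "pct": 3.0},
            ]
        )
        res = group_compare(freqs, "bird_vs_mammal", "L", "inner_LWI")
        assert res.skipped and np.isnan(res.p)


def test_star_mapping():
    assert significance_stars(5e-5) == "****"
    assert significance_stars(5e-4) == "**"
    assert significance_stars(0.03) == "ns"


def test_natural_frequencies_are_percentages():
    assert sum(NATURAL_FREQUENCIES.values()) == pytest.approx(100.0, abs=0.5)
    assert set(NATURAL_FREQUENCIES) == set(AA)
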