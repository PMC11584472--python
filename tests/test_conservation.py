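"""p-distance, bootstrap divergence, logo information, rank tests."""

import math

import numpy as np
import pytest

from memevo import (
    AlignedSet,
    InputError,
    ProteinRecord,
    bootstrap_divergence,
    column_profiles,
    conserved_control_fixture,
    information_content,
    kruskal_wallis,
    mann_whitney_u,
    pairwise_p_distance,
    shuffled_columns,
)
from conftest import exact_mann_whitney_p


class TestPDistance:
    def test_identical_sequences(self):
        assert pairwise_p_distance("ACDE", "ACDE") == 0.0

    def test_simple_mismatch_fraction(self):
        assert pairwise_p_distance("AAAA", "AAAT") == 0.25

    def test_gap_columns_excluded_both_sides(self):
        assert pairwise_p_distance("AA-A", "AAAA") == 0.0
        assert pairwise_p_distance("AA-T", "AAAA") == pytest.approx(1 / 3)

    def test_no_comparable_columns_is_nan(self):
        assert math.isnan(pairwise_p_distance("--", "AA"))

    def test_length_mismatch_raises(self):
        with pytest.raises(InputError):
            pairwise_p_distance("AAA", "AAAA")

    def test_column_subset(self):
        assert pairwise_p_distance("AAAT", "AAAA", columns=[1, 2]) == 0.0
        assert pairwise_p_distance("AAAT", "AAAA", columns=[4]) == 1.0


def _aln(*seqs):
    return AlignedSet(records=[ProteinRecord(id=f"s{i}", sequence=s) for i, s in enumerate(seqs)])


class TestBootstrapDivergence:
    def test_invariant_columns_give_zero(self):
        aln = _aln("ACDEF", "ACDEF", "ACDEF")
        prof = bootstrap_divergence(aln, [1, 2, 3, 4, 5], n_replicates=50, seed=0)
        assert np.all(prof.replicates == 0.0)

    def test_totally_divergent_pair_gives_one(self):
        aln = _aln("AAAA", "CCCC")
        prof = bootstrap_divergence(aln, [1, 2, 3, 4], n_replicates=50, seed=0)
        assert np.all(prof.replicates == 1.0)

    def test_reproducible_for_fixed_seed(self):
        aln = _aln("ACDEFGHIKL", "ACDEFGHIKV", "MCDEFGHIKL")
        a = bootstrap_divergence(aln, list(range(1, 11)), n_replicates=200, seed=9)
        b = bootstrap_divergence(aln, list(range(1, 11)), n_replicates=200, seed=9)
        assert np.array_equal(a.replicates, b.replicates)
        c = bootstrap_divergence(aln, list(range(1, 11)), n_replicates=200, seed=10)
        assert not np.array_equal(a.replicates, c.replicates)

    def test_replicates_bounded_and_median_converges(self):
        aln = _aln("ACDEFGHIKL", "ACDEFGHIKV", "MCDEFGHIVL", "ACWEFGHIKL")
        small = bootstrap_divergence(aln, list(range(1, 11)), n_replicates=100, seed=3)
        large = bootstrap_divergence(aln, list(range(1, 11)), n_replicates=10_000, seed=4)
        assert np.all((small.replicates >= 0) & (small.replicates <= 1))
        assert abs(small.median - large.median) < 0.05

    def test_matches_closed_form_expectation(self, default_family):
        """Loop-column divergence ≈ closed-form mean mismatch probability.

        Under the generator's loop model each non-reference species keeps
        the reference residue with probability 1−r and otherwise draws from
        the background; the expected pairwise mismatch for a column with
        reference residue a follows in closed form from that mixture.
        """
        aln, _, topo, truth = default_family
        r = truth.loop_sub_rate
        bg = truth.background
        lwi = {p for reg in truth.regions for p in reg.positions}
        tm = {p for s in topo.segments for p in range(s.start, s.end + 1)}
        planted = {
            p for m in truth.planted_motifs for p in range(m.start, m.end + 1)
        }
        loop_cols = [
            p for p in range(1, topo.protein_length + 1)
            if p not in lwi and p not in tm and p not in planted
        ]
        ref = aln.reference().sequence
        expected_cols = []
        for p in loop_cols:
            a = ref[p - 1]
            # both-species residue distribution: (1-r) at a plus r * bg
            same = sum(
                ((1 - r if x == a else 0.0) + r * bg[x]) ** 2 for x in bg
            )
            expected_cols.append(1 - same)
        # restrict to non-reference sequences: reference pairs mismatch less
        sub = AlignedSet(records=[rec for rec in aln.records if rec.id != truth.reference_id])
        prof = bootstrap_divergence(sub, loop_cols, n_replicates=300, seed=5)
        assert prof.median == pytest.approx(float(np.mean(expected_cols)), rel=0.05)

    def test_empty_columns_rejected(self):
        with pytest.raises(InputError):
            bootstrap_divergence(_aln("AC", "AC"), [], n_replicates=10, seed=0)

    def test_conserved_control_below_randomized(self):
        fixture = conserved_control_fixture()
        cols = list(range(1, fixture.n_columns + 1))
        low = bootstrap_divergence(fixture, cols, n_replicates=200, seed=0)
        high = bootstrap_divergence(shuffled_columns(fixture, seed=1), cols, n_replicates=200, seed=0)
        assert low.median < 0.02
        assert high.median > 10 * low.median


class TestInformationContent:
    def test_single_residue_column_is_max(self):
        assert information_content({"L": 12}) == pytest.approx(math.log2(20))

    def test_uniform_over_20_is_zero(self):
        assert information_content({aa: 1 for aa in "ACDEFGHIKLMNPQRSTVWY"}) == pytest.approx(0.0)

    def test_half_half_column(self):
        assert information_content({"L": 5, "V": 5}) == pytest.approx(math.log2(20) - 1)

    def test_all_gap_column_nan(self):
        assert math.isnan(information_content({}))

    def test_monotone_in_mixing(self):
        """Mixing a second residue into a conserved column lowers content."""
        prev = information_content({"L": 10, "V": 0})
        for k in range(1, 6):
            cur = information_content({"L": 10 - k, "V": k})
            assert cur < prev
            prev = cur

    def test_column_profiles_counts_sum(self):
        aln = _aln("AC-E", "ACDE", "AC-E")
        df = column_profiles(aln).set_index("column")
        assert df.loc[3, "gap_count"] == 2
        aa_cols = list("ACDEFGHIKLMNPQRSTVWY")
        assert (df[aa_cols].sum(axis=1) + df["gap_count"] == 3).all()


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.U == 0
        assert res.p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    def test_exact_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(11)
        for _ in range(12):
            n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = list(vals[:n1]), list(vals[n1:])
            res = mann_whitney_u(x, y, alternative=alternative)
            assert res.method == "exact"
            assert res.p == pytest.approx(exact_mann_whitney_p(x, y, alternative))

    def test_identical_samples_high_p(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p >= 0.99

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        y = rng.normal(50, 1, 50)
        res = mann_whitney_u(x, y)
        assert res.method == "asymptotic"
        assert res.p < 1e-4

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_hand_ranked_three_by_three(self):
        """Disjoint triples 1-3/4-6/7-9: H = 12/(N(N+1)) Σ n(R̄−(N+1)/2)² = 7.2."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.H == pytest.approx(7.2)

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.H == 0.0 and res.p == 1.0

    def test_disjoint_supports_significant(self):
        g = [list(np.arange(20)), list(np.arange(100, 120)), list(np.arange(200, 220))]
        assert kruskal_wallis(g).p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            kruskal_wallis([[1, 2], []])
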