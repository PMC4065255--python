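"""SFS construction, Tajima's D, Fay-Wu H, misorientation, empirical rank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popsweep import coalescent as co
from popsweep.alignio import HaplotypeAlignment
from popsweep.sfs import (
    build_sfs,
    empirical_rank,
    fay_wu_h_from_counts,
    fay_wu_h_norm,
    misorientation_probability,
    neutrality_test,
    pi_from_counts,
    tajimas_d,
    tajimas_d_from_counts,
)

from oracles import fold_spectrum, tajimas_d_independent


def _aln(rows, outgroup=None):
    ids = [f"s{i}" for i in range(len(rows))]
    if outgroup is not None:
        rows = rows + [outgroup]
        ids = ids[:-0] if False else ids + ["og"]
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    return HaplotypeAlignment(ids, matrix,
                              outgroup_id="og" if outgroup else None)


class TestBuildSfs:
    def test_outgroup_matching_major_allele_polarizes_minor_as_derived(self):
        aln = _aln(["A", "A", "A", "G"], outgroup="A")
        sfs = build_sfs(aln)
        assert sfs.xi[1] == 1
        assert sfs.status == ["polarized"]

    def test_third_outgroup_allele_goes_folded_only(self):
        aln = _aln(["A", "A", "A", "G"], outgroup="C")
        sfs = build_sfs(aln)
        assert sfs.xi.sum() == 0
        assert sfs.eta[1] == 1
        assert sfs.status == ["unpolarizable"]

    def test_no_outgroup_and_unfolded_requested_errors(self):
        aln = _aln(["A", "G"])
        with pytest.raises(ValueError, match="outgroup"):
            build_sfs(aln)

    def test_triallelic_sites_excluded(self):
        aln = _aln(["A", "C", "G", "G"], outgroup="G")
        sfs = build_sfs(aln)
        assert sfs.S == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_folding_identity_on_random_alignments(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.choice(["A", "G"], size=(10, 200), p=[0.8, 0.2])
        out = rng.choice(["A", "G", "C"], size=200, p=[0.7, 0.2, 0.1])
        matrix = np.vstack([rows, out[None, :]])
        ids = [f"s{i}" for i in range(10)] + ["og"]
        aln = HaplotypeAlignment(ids, matrix, outgroup_id="og")
        sfs = build_sfs(aln)
        # polarized part must satisfy eta_i = xi_i + xi_{n-i}
        folded = fold_spectrum(sfs.xi, sfs.n)
        np.testing.assert_array_equal(sfs.folded_from_unfolded(), folded)
        # total spectrum accounts for every biallelic segregating site
        assert sfs.eta.sum() == sfs.S


class TestTajimasD:
    def test_zero_numerator_gives_zero(self):
        n, S = 12, 9
        a1 = co.harmonic(n)
        assert tajimas_d(S / a1, S, n) == pytest.approx(0.0)

    def test_all_singletons_negative(self):
        counts = np.ones(8, dtype=int)
        assert tajimas_d_from_counts(counts, 10) < 0

    def test_undefined_at_zero_s(self):
        assert tajimas_d(0.0, 0, 10) is None

    @given(st.integers(3, 40), st.integers(1, 60), st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_implementation(self, n, S, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        counts = rng.integers(1, n, size=S)
        ours = tajimas_d_from_counts(counts, n)
        if ours is None:  # degenerate: zero variance (e.g. n=3, S=1)
            return
        theirs = tajimas_d_independent(pi_from_counts(counts, n), S, n)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_invariant_to_site_order(self, rng):
        counts = rng.integers(1, 15, size=30)
        assert tajimas_d_from_counts(counts, 15) == pytest.approx(
            tajimas_d_from_counts(counts[::-1], 15))


class TestFayWuH:
    def test_high_frequency_derived_excess_strongly_negative(self):
        n = 20
        counts = np.full(15, n - 1)
        assert fay_wu_h_from_counts(counts, n) < -2

    def test_singleton_spectrum_positive(self):
        # theta_L < theta_pi when all derived alleles are singletons
        n, S = 20, 15
        counts = np.ones(S, dtype=int)
        h = fay_wu_h_from_counts(counts, n)
        assert h > 0

    def test_mean_near_zero_under_neutral_null(self):
        # fixed-S conditioning shifts the mean slightly positive (~0.098
        # at n=20, S=30); the check allows for Monte-Carlo error
        rng = np.random.default_rng(99)
        counts = co.fixed_s_counts(20, 30, 5000, rng)
        vals = np.array([fay_wu_h_from_counts(c, 20) for c in counts])
        sem = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean()) <= 0.1 + 2 * sem

    def test_invariant_to_monomorphic_sites(self):
        counts = np.array([1, 5, 19, 3, 0, 20, 0])
        with_mono = fay_wu_h_from_counts(counts, 20)
        without = fay_wu_h_from_counts(counts[(counts > 0) & (counts < 20)], 20)
        assert with_mono == pytest.approx(without)

    def test_undefined_without_polarized_sites(self):
        assert fay_wu_h_from_counts(np.array([], dtype=int), 10) is None


class TestMisorientation:
    def test_zero_divergence(self):
        assert misorientation_probability(0.0) == 0.0

    def test_formula_at_three_percent(self):
        assert misorientation_probability(0.03) == pytest.approx(0.01 / 0.98)

    def test_small_divergence_magnitude(self):
        # at d ~ 0.3% the misorientation probability is ~0.1%
        p = misorientation_probability(0.003)
        assert 0.0005 < p < 0.002

    def test_saturation_error(self):
        with pytest.raises(ValueError, match="saturat"):
            misorientation_probability(0.8)


class TestEmpiricalRank:
    def test_most_negative_is_rank_one(self):
        res = empirical_rank(-2.08, [-1.9, -1.2, 0.3, 1.1])
        assert res.rank == 1

    def test_tie_with_minimum_reported(self):
        res = empirical_rank(-2.0, [-2.0, -1.0, 0.0])
        assert res.rank == 1
        assert res.n_tied == 1

    def test_median_of_eleven_is_fiftieth_percentile(self):
        vals = list(range(11))
        res = empirical_rank(5, vals)
        assert res.percentile == pytest.approx(50.0)


class TestNeutralityTest:
    def test_rejection_rate_self_consistent(self):
        """|D| rejection at the simulated 5% two-tailed cutoff is ~5%."""
        rng = np.random.default_rng(5)
        n, S = 20, 30
        counts = co.fixed_s_counts(n, S, 3000, rng)
        vals = np.array([tajimas_d_from_counts(c, n) for c in counts])
        lo, hi = np.quantile(vals, [0.025, 0.975])
        fresh = co.fixed_s_counts(n, S, 1500, rng)
        fvals = np.array([tajimas_d_from_counts(c, n) for c in fresh])
        rate = np.mean((fvals < lo) | (fvals > hi))
        se = np.sqrt(0.05 * 0.95 / 1500)
        assert abs(rate - 0.05) < 4 * se

    def test_extreme_value_small_p(self):
        res = neutrality_test("D", -3.5, 20, 30, replicates=500, seed=1)
        assert res.p_value < 0.05

    def test_p_in_unit_interval_and_seed_recorded(self):
        res = neutrality_test("H", 0.1, 10, 12, replicates=300, seed=7)
        assert 0 < res.p_value <= 1
        assert res.seed == 7
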