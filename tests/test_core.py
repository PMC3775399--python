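"""Closed-form statistics: worked values, singularities and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ffst
from ffst import (
    ConsistencyError,
    DomainError,
    FFSTParams,
    GelOverflowError,
    SingularityError,
)
from ffst import core

GM = 1.0 - math.exp(-2.0)


class TestNumberAvgDP:
    @pytest.mark.parametrize(
        "beta, f, exact, expected",
        [
            (1.0, None, False, 2.0),          # gel point, large-f limit
            (0.0, None, False, 1.0),          # no links: all monomers
            (1.0, 3, True, 4.0),              # f=3, alpha=0.5 exact
            (0.1, None, False, 1.053),        # pre-gel, printed to 3 d.p.
        ],
    )
    def test_values(self, beta, f, exact, expected):
        value = core.number_avg_dp(beta, f, exact=exact)
        assert round(value, 3) == pytest.approx(expected, abs=5e-4)

    def test_pole_names_tree_ceiling(self):
        with pytest.raises(SingularityError, match="beta_m"):
            core.number_avg_dp(2.0)
        with pytest.raises(SingularityError):
            core.number_avg_dp(1.4, 3, exact=True)  # f*alpha = 2.1

    def test_negative_beta_rejected(self):
        with pytest.raises(DomainError):
            core.number_avg_dp(-0.1)

    @given(st.floats(min_value=0.0, max_value=1.98))
    @settings(max_examples=60, derandomize=True)
    def test_at_least_one_unit(self, beta):
        assert core.number_avg_dp(beta) >= 1.0


class TestWeightAvgDP:
    @pytest.mark.parametrize(
        "beta, k, f, exact, expected",
        [
            (1.0, 34, None, False, 36.0),     # gel point, k-fold compounding
            (0.0, 17, None, False, 1.0),
            (1.0, 25, 3, True, 40.0),         # f=3, alpha=0.5 exact
            (0.1, 34, None, False, 1.111),    # printed to 3 d.p.
        ],
    )
    def test_values(self, beta, k, f, exact, expected):
        value = core.weight_avg_dp(beta, k, f, exact=exact)
        assert round(value, 3) == pytest.approx(expected, abs=5e-4)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            core.weight_avg_dp(-0.5, 3)
        with pytest.raises(DomainError):
            core.weight_avg_dp(0.5, -1)

    def test_overflow_reported(self):
        with pytest.raises(GelOverflowError):
            core.weight_avg_dp(10.0, 500)

    @pytest.mark.parametrize("beta", [0.1 * i for i in range(1, 20) if i != 10])
    @pytest.mark.parametrize("k", [0, 3, 17, 40])
    def test_geometric_form_matches_explicit_sum(self, beta, k):
        """The compact geometric closed form equals the term-by-term sum."""
        explicit = 1.0 + beta * sum(beta**i for i in range(k + 1))
        assert core.weight_avg_dp(beta, k) == pytest.approx(explicit, rel=1e-9)

    @pytest.mark.parametrize("k", [0, 5, 34])
    def test_gel_point_limit(self, k):
        """beta -> 1 limit of the geometric form is the exact 1 + f*alpha*(k+1)."""
        at_gel = core.weight_avg_dp(1.0, k)
        assert at_gel == 1.0 + (k + 1)
        near_gel = core.weight_avg_dp(1.0 - 1e-9, k)
        assert near_gel == pytest.approx(at_gel, rel=1e-6)

    def test_strictly_increasing_in_k(self):
        values = [core.weight_avg_dp(0.7, k) for k in range(10)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_exhausts_system_at_tree_ceiling(self):
        """At beta_m = 2 with k = log2(N) - 2 the weight average reaches N."""
        N = 2**40
        k = int(math.log2(N)) - 2
        assert core.weight_avg_dp(2.0, k) == pytest.approx(N, rel=1e-9)

    @given(st.floats(min_value=0.0, max_value=1.9), st.integers(0, 40))
    @settings(max_examples=80, derandomize=True)
    def test_monotone_in_beta(self, beta, k):
        lo = core.weight_avg_dp(beta, k)
        hi = core.weight_avg_dp(min(beta + 0.01, 1.95), k)
        assert hi >= lo - 1e-12


class TestDispersity:
    @pytest.mark.parametrize("xn, xw, expected", [(2, 36, 18), (4, 40, 10), (7, 7, 1)])
    def test_values(self, xn, xw, expected):
        assert core.dispersity(xn, xw) == pytest.approx(expected)

    def test_nonpositive_xn_rejected(self):
        with pytest.raises(DomainError):
            core.dispersity(0.0, 5.0)

    @given(st.floats(min_value=0.0, max_value=0.999), st.integers(0, 40))
    @settings(max_examples=80, derandomize=True)
    def test_pregel_dispersity_at_least_one(self, beta, k):
        averages = core.dp_averages(beta, k)
        assert averages.r >= 1.0 - 1e-12


class TestGenerationSolver:
    def test_human_scale_values(self):
        assert core.solve_generations(1e11) == pytest.approx(34.54, abs=5e-3)
        assert core.solve_generations(1e11, corrected=True) == pytest.approx(34.33, abs=5e-3)

    def test_smallest_system(self):
        assert core.solve_generations(4) == pytest.approx(0.0, abs=1e-12)

    def test_corrected_below_uncorrected(self):
        for N in (1e4, 1e7, 1e11):
            assert core.solve_generations(N, corrected=True) < core.solve_generations(N)

    def test_too_small_for_correction(self):
        with pytest.raises(DomainError):
            core.solve_generations(4, corrected=True)

    @given(st.floats(min_value=4.0, max_value=1e15))
    @settings(max_examples=60, derandomize=True)
    def test_roundtrip(self, N):
        k = core.solve_generations(N)
        assert 2.0 ** (k + 2) == pytest.approx(N, rel=1e-9)

    def test_finite_f_solver(self):
        # f=3, N=1e4: continuous solution just below 25
        assert core.solve_generations_finite(1e4, 3) == pytest.approx(24.8, abs=0.05)

    def test_table_conventions(self):
        assert core.table_k(1e11) == 34
        assert core.table_k(1e4, 3) == 25


class TestBetaMax:
    @pytest.mark.parametrize("N, expected", [(1e11, 2 - 2e-11), (1, 0.0), (2, 1.0)])
    def test_values(self, N, expected):
        assert core.beta_max(N) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_below_one_rejected(self):
        with pytest.raises(DomainError):
            core.beta_max(0)


class TestMonomerFraction:
    def test_limit_values(self):
        assert round(core.monomer_weight_fraction(beta=1.0, limit=True), 3) == 0.368
        assert round(core.monomer_weight_fraction(beta=2.0, limit=True), 3) == 0.135

    def test_no_reaction(self):
        assert core.monomer_weight_fraction(0.0, 12345) == 1.0

    def test_exact_matches_limit_at_large_f(self):
        exact = core.monomer_weight_fraction(2e-4, 10**4)
        limit = core.monomer_weight_fraction(beta=(10**4 - 1) * 2e-4, limit=True)
        assert exact == pytest.approx(limit, abs=1e-4)

    def test_alpha_domain(self):
        with pytest.raises(DomainError):
            core.monomer_weight_fraction(1.2, 4)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=40, derandomize=True)
    def test_decreasing_in_alpha(self, alpha):
        w = core.monomer_weight_fraction(alpha, 10)
        assert 0.0 <= w <= 1.0
        assert core.monomer_weight_fraction(min(alpha + 0.05, 1.0), 10) <= w + 1e-12


class TestSolGel:
    def test_gel_fraction_values(self):
        assert round(core.gel_fraction(2.0), 3) == 0.865
        assert core.gel_fraction(0.0) == 0.0
        assert core.gel_fraction(math.log(1e11)) == pytest.approx(1 - 1e-11, rel=1e-12)

    def test_gel_fraction_monotone_bounded(self):
        grid = [core.gel_fraction(0.25 * i) for i in range(50)]
        assert all(0.0 <= g <= 1.0 for g in grid)
        assert all(b > a for a, b in zip(grid, grid[1:]))

    def test_negative_beta_rejected(self):
        with pytest.raises(DomainError):
            core.gel_fraction(-1.0)

    def test_mix_pure_sol_equals_sol_phase(self):
        mixed = core.sol_gel_mix(
            1.0, 0.0, xn_sol=3.0, xn_gel=100.0, xw_sol=5.0, xw_gel=900.0,
            beta_sol=0.5, beta_gel=2.3,
        )
        assert mixed.xn == pytest.approx(3.0)
        assert mixed.xw == pytest.approx(5.0)
        assert mixed.beta == pytest.approx(0.5)

    def test_number_average_mixes_harmonically(self):
        # molecule counting: s/xn' + g/xn'' molecules per unit mass
        mixed = core.sol_gel_mix(0.25, 0.75, xn_sol=1.0, xn_gel=3.0)
        assert mixed.xn == pytest.approx(1.0 / (0.25 / 1.0 + 0.75 / 3.0))

    def test_gel_phase_beta_at_tree_ceiling(self):
        # monomeric sol at beta = 2: the gel carries 2/(1 - e^-2) link-ends/unit
        assert core.gel_phase_beta(2.0, math.exp(-2.0)) == pytest.approx(
            2.0 / (1.0 - math.exp(-2.0)), rel=1e-12
        )
        assert round(core.gel_phase_beta(2.0, math.exp(-2.0)), 4) == 2.3130

    def test_mix_consistency_errors(self):
        with pytest.raises(ConsistencyError):
            core.sol_gel_mix(0.7, 0.2, beta_sol=0.0, beta_gel=2.0)
        with pytest.raises(DomainError):
            core.sol_gel_mix(0.5, 0.5, xn_sol=0.0, xn_gel=2.0)


class TestRedundancy:
    def test_tree_ceiling_redundancy_equals_system_size(self):
        result = core.redundancy(1000, 2.0)
        assert result.D == 1000
        assert result.total_linkages == 2000

    def test_gel_point_has_no_redundancy(self):
        assert core.redundancy(500, 1.0).D == 0.0

    def test_saturated_neuron(self):
        result = core.redundancy(10, 8000.0)
        assert result.D == 7999 * 10
        assert result.D == result.total_linkages - 10

    def test_pregel_warns(self):
        with pytest.warns(UserWarning):
            result = core.redundancy(10, 0.5)
        assert result.D == -5.0


class TestFFSTParams:
    def test_beta_derived_from_alpha(self):
        params = FFSTParams(N=10**4, f=3, alpha=0.5)
        assert params.beta == 1.0
        assert params.beta_c == 1.0

    def test_alpha_derived_from_beta(self):
        params = FFSTParams(f=10**4, beta=2.0)
        assert params.alpha == pytest.approx(2.0 / 9999)

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ConsistencyError):
            FFSTParams(f=3, alpha=0.5, beta=1.5)

    def test_tree_ceiling(self):
        assert FFSTParams(N=2).beta_m == 1.0
        assert FFSTParams().beta_m == 2.0

    def test_beta_above_site_capacity_rejected(self):
        with pytest.raises(DomainError):
            FFSTParams(f=3, beta=2.5)

    def test_package_reexports(self):
        assert ffst.number_avg_dp is core.number_avg_dp
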