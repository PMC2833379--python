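"""Rate laws, relaxation eigenvalues, populations and thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldkin import (
    ExperimentConditions,
    RateLaw,
    equilibrium_populations,
    make_three_state_scheme,
    make_two_state_scheme,
    rate_at_denaturant,
    thermo_summary,
    three_state_relaxation_rates,
    two_state_kobs,
)
from foldkin.models import FOLDING, UNFOLDING, pre_equilibrium_slow_rate

RT = ExperimentConditions().RT


class TestRateLaw:
    def test_zero_denaturant_identity(self):
        law = RateLaw(253.9, 0.75, FOLDING)
        assert rate_at_denaturant(law, 0.0) == pytest.approx(253.9, rel=1e-12)

    @pytest.mark.parametrize(
        "rate0, m, direction, D",
        [
            (1574.0, 1.23, FOLDING, 2.0),
            (1.26, 0.45, UNFOLDING, 8.0),
            (50.0, 0.0, FOLDING, 5.0),
        ],
    )
    def test_exponential_denaturant_dependence(self, rate0, m, direction, D):
        sign = -1.0 if direction == FOLDING else 1.0
        expected = rate0 * math.exp(sign * m * D / RT)
        assert rate_at_denaturant(RateLaw(rate0, m, direction), D) == pytest.approx(
            expected, rel=1e-12
        )

    def test_negative_denaturant_rejected(self):
        with pytest.raises(ValueError):
            rate_at_denaturant(RateLaw(100.0, 1.0, FOLDING), -0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RateLaw(0.0, 1.0, FOLDING)
        with pytest.raises(ValueError):
            RateLaw(1.0, -0.5, FOLDING)
        with pytest.raises(ValueError):
            RateLaw(1.0, 0.5, "sideways")


def _scheme_from_rates(k_ui, k_iu, k_in, k_ni, m=(1.2, 3.0, 0.75, 0.45)):
    return make_three_state_scheme(k_ui, m[0], k_iu, m[1], k_in, m[2], k_ni, m[3])


def _eig_slow_fast(k_ui, k_iu, k_in, k_ni):
    """Independent oracle: numerical eigendecomposition of the rate matrix."""
    A = np.array(
        [
            [-k_ui, k_iu, 0.0],
            [k_ui, -(k_iu + k_in), k_ni],
            [0.0, k_in, -k_ni],
        ]
    )
    lams = np.sort(np.abs(np.linalg.eigvals(A)))
    return lams[2], lams[1]  # fast, slow (lams[0] ~ 0)


class TestThreeStateRelaxation:
    def test_disconnected_native_state(self):
        # with k_IN = k_NI -> 0 the slow phase vanishes and the fast one is s
        sch = _scheme_from_rates(100.0, 100.0, 1e-12, 1e-12)
        fast, slow = three_state_relaxation_rates(sch, 0.0)
        assert fast == pytest.approx(200.0, rel=1e-9)
        assert slow == pytest.approx(0.0, abs=1e-9)

    def test_wild_type_rates_match_eigensolver(self):
        k = (1574.0, 1574.0 / 222.2, 253.9, 1.26)
        sch = _scheme_from_rates(*k)
        fast, slow = three_state_relaxation_rates(sch, 0.0)
        ref_fast, ref_slow = _eig_slow_fast(*k)
        assert fast == pytest.approx(ref_fast, rel=1e-9)
        assert slow == pytest.approx(ref_slow, rel=1e-9)

    def test_agrees_with_eigensolver_over_random_schemes(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = 10.0 ** rng.uniform(-2, 4, size=4)
            sch = _scheme_from_rates(*k)
            fast, slow = three_state_relaxation_rates(sch, 0.0)
            ref_fast, ref_slow = _eig_slow_fast(*k)
            assert abs(fast / ref_fast - 1) < 1e-9
            assert abs(slow / ref_slow - 1) < 1e-9

    def test_slow_rate_converges_to_pre_equilibrium_limit(self):
        base = (1574.0, 7.08, 253.9, 1.26)
        for scale, tol in [(1e2, 1e-1), (1e4, 1e-3)]:
            k = (base[0] * scale / 1e2, base[1] * scale / 1e2, base[2], base[3])
            sch = _scheme_from_rates(*k)
            _, slow = three_state_relaxation_rates(sch, 0.0)
            approx = pre_equilibrium_slow_rate(sch, 0.0)
            assert abs(slow / approx - 1) < tol

    def test_pre_equilibrium_holds_at_100x_separation(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            k_in, k_ni = 10.0 ** rng.uniform(-1, 2, size=2)
            fast_scale = 100.0 * (k_in + k_ni)
            k_ui = fast_scale * 10.0 ** rng.uniform(0, 1)
            k_iu = fast_scale * 10.0 ** rng.uniform(0, 1)
            sch = _scheme_from_rates(k_ui, k_iu, k_in, k_ni)
            _, slow = three_state_relaxation_rates(sch, 0.0)
            K = k_ui / k_iu
            approx = k_in * K / (1 + K) + k_ni
            assert abs(slow / approx - 1) < 0.01

    def test_requires_three_state_scheme(self):
        sch = make_two_state_scheme(279.4, 3.27, 3.40, 0.68)
        with pytest.raises(ValueError):
            three_state_relaxation_rates(sch, 0.0)


class TestTwoStateKobs:
    def test_sum_of_branch_rates_at_zero_denaturant(self):
        sch = make_two_state_scheme(279.4, 3.27, 3.40, 0.68)
        assert two_state_kobs(sch, 0.0) == pytest.approx(282.8, abs=0.01)

    def test_symmetric_scheme_minimised_at_zero(self):
        sch = make_two_state_scheme(10.0, 1.5, 10.0, 1.5)
        D = np.linspace(0.0, 8.0, 50)
        kobs = two_state_kobs(sch, D)
        assert np.argmin(kobs) == 0

    def test_unfolding_branch_dominates_at_high_denaturant(self):
        sch = make_two_state_scheme(279.4, 3.27, 3.40, 0.68)
        D = 8.0
        k_nu = rate_at_denaturant(RateLaw(3.40, 0.68, UNFOLDING), D)
        k_un = rate_at_denaturant(RateLaw(279.4, 3.27, FOLDING), D)
        assert k_un < k_nu / 100
        assert two_state_kobs(sch, D) == pytest.approx(k_nu, rel=0.01)

    def test_log_kobs_is_convex_in_denaturant(self):
        sch = make_two_state_scheme(279.4, 3.27, 3.40, 0.68)
        D = np.linspace(0.0, 9.0, 200)
        lnk = np.log(two_state_kobs(sch, D))
        assert np.all(np.diff(lnk, 2) > -1e-12)


class TestEquilibriumPopulations:
    def test_native_dominates_for_stable_protein(self, wt_scheme):
        pU, pI, pN = equilibrium_populations(wt_scheme, 0.0)
        assert pN > 0.99
        # direct Boltzmann oracle
        th = thermo_summary(wt_scheme)
        w = np.array([1.0, math.exp(-th.dG_UI / RT), math.exp(-th.dG_UN / RT)])
        assert pN == pytest.approx(w[2] / w.sum(), rel=1e-12)

    def test_symmetric_scheme_gives_equal_thirds(self):
        sch = make_three_state_scheme(100.0, 1.0, 100.0, 1.0, 5.0, 0.5, 5.0, 0.5)
        pops = equilibrium_populations(sch, 0.0)
        for p in pops:
            assert p == pytest.approx(1 / 3, rel=1e-12)

    def test_populations_sum_to_one(self, wt_scheme):
        D = np.linspace(0.0, 9.0, 40)
        pU, pI, pN = equilibrium_populations(wt_scheme, D)
        assert np.allclose(pU + pI + pN, 1.0, atol=1e-12)

    def test_detailed_balance_matches_thermo(self, wt_scheme):
        pU, pI, pN = equilibrium_populations(wt_scheme, 0.0)
        th = thermo_summary(wt_scheme)
        assert math.log(pI / pU) == pytest.approx(-th.dG_UI / RT, rel=1e-9)
        assert math.log(pN / pU) == pytest.approx(-th.dG_UN / RT, rel=1e-9)

    def test_two_state_midpoint_has_equal_populations(self):
        sch = make_two_state_scheme(279.4, 3.27, 3.40, 0.68)
        th = thermo_summary(sch)
        D_mid = -th.dG_UN / th.M_UN
        pU, pI, pN = equilibrium_populations(sch, D_mid)
        assert pU == pytest.approx(pN, rel=1e-9)
        assert pI == 0.0


class TestThermoSummary:
    def test_wild_type_free_energies(self, wt_scheme):
        """K_UI = 222.2 and k_IN/k_NI = 253.9/1.26 give the published dG values."""
        th = thermo_summary(wt_scheme)
        assert th.dG_UI == pytest.approx(-RT * math.log(222.2), rel=1e-12)
        assert th.dG_UI == pytest.approx(-12.71, abs=0.05)
        assert th.dG_UN == pytest.approx(-25.19, abs=0.05)

    def test_wild_type_beta_values(self, wt_scheme):
        th = thermo_summary(wt_scheme)
        assert th.beta_I == pytest.approx(4.19 / 5.39, rel=1e-12)
        assert th.beta_I == pytest.approx(0.78, abs=0.01)
        assert th.beta_TS2 == pytest.approx(0.92, abs=0.01)

    def test_unit_equilibrium_constant_gives_zero_dG(self):
        sch = make_three_state_scheme(50.0, 1.0, 50.0, 1.0, 5.0, 0.5, 1.0, 0.5)
        assert thermo_summary(sch).dG_UI == pytest.approx(0.0, abs=1e-12)

    def test_free_energy_additivity(self, wt_scheme):
        th = thermo_summary(wt_scheme)
        assert th.dG_UN == pytest.approx(th.dG_UI + th.dG_IN, abs=1e-9)

    def test_two_state_summary(self):
        sch = make_two_state_scheme(279.4, 3.27, 3.40, 0.68)
        th = thermo_summary(sch)
        assert th.dG_UN == pytest.approx(-10.38, abs=0.05)
        assert th.M_UN == pytest.approx(3.95, abs=1e-12)
        assert th.beta_I is None
        assert th.beta_TS2 == pytest.approx(3.27 / 3.95, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        m_ui=st.floats(0.1, 3.0),
        m_iu=st.floats(0.1, 4.0),
        m_in=st.floats(0.01, 2.0),
        m_ni=st.floats(0.01, 2.0),
    )
    def test_beta_ordering_for_positive_m_values(self, m_ui, m_iu, m_in, m_ni):
        sch = make_three_state_scheme(100.0, m_ui, 10.0, m_iu, 50.0, m_in, 1.0, m_ni)
        th = thermo_summary(sch)
        assert 0.0 < th.beta_I <= th.beta_TS2 <= 1.0
        assert th.M_UN == pytest.approx(th.M_UI + m_in + m_ni, rel=1e-12)
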