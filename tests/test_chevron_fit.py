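"""Global chevron fitting: round trips, constraints, identifiability."""

import math

import numpy as np
import pytest

from foldkin import (
    ChevronDataset,
    FitConstraints,
    NoiseModel,
    ThreeStateChevronFitter,
    TwoStateChevronFitter,
    amplitude_model,
    fit_chevron_three_state,
    fit_chevron_two_state,
    generate_chevron,
    make_three_state_scheme,
    normalize_signals,
    two_state_kobs,
)
from foldkin.simulate import NOISELESS

def make_two_state_scheme_for_test():
    from foldkin import make_two_state_scheme

    return make_two_state_scheme(300.0, 3.3, 0.01, 0.9)


TRUE_WT = {
    "k_IU": 1574.0 / 222.2,
    "m_IU": 4.19 - 1.23,
    "k_IN": 253.9,
    "m_IN": 0.75,
    "k_NI": 1.26,
    "m_NI": 0.45,
}


class TestThreeStateFit:
    def test_noise_free_round_trip(self, wt_scheme):
        data = generate_chevron(wt_scheme, noise=NOISELESS)
        res = fit_chevron_three_state(data, n_starts=4, random_state=0)
        assert res.success
        for name, true in TRUE_WT.items():
            assert res.params[name] == pytest.approx(true, rel=1e-6), name

    def test_noisy_recovery_within_three_sigma(self, wt_scheme):
        data = generate_chevron(wt_scheme, noise=NoiseModel(seed=7))
        res = fit_chevron_three_state(data, n_starts=4, random_state=1)
        for name in ("k_IU", "k_IN", "k_NI"):
            sigma_ln = res.sigma[name] / res.params[name]
            z = abs(math.log(res.params[name]) - math.log(TRUE_WT[name])) / sigma_ln
            assert z < 3.0, name

    def test_fixed_parameters_absent_from_covariance(self, wt_scheme):
        data = generate_chevron(wt_scheme, noise=NOISELESS)
        res = fit_chevron_three_state(data, n_starts=2)
        assert res.fixed == {"k_UI": 1574.0, "m_UI": 1.23}
        assert "k_UI" not in res.covariance.index
        assert "m_UI" not in res.covariance.index
        assert "k_UI" not in res.sigma

    def test_covariance_is_symmetric_psd_and_matches_sigma(self, wt_scheme):
        data = generate_chevron(wt_scheme, noise=NoiseModel(seed=3))
        res = fit_chevron_three_state(data, n_starts=2)
        cov = res.covariance.to_numpy()
        assert np.allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)
        # natural-scale rate sigma is k * sigma_ln(k)
        i = res.covariance.index.get_loc("k_IN")
        assert res.sigma["k_IN"] == pytest.approx(
            res.params["k_IN"] * math.sqrt(cov[i, i]), rel=1e-9
        )

    def test_kinetic_M_UN_is_exact_sum_of_m_values(self, wt_scheme):
        data = generate_chevron(wt_scheme, noise=NoiseModel(seed=9))
        res = fit_chevron_three_state(data, n_starts=2)
        p = res.params
        assert res.thermo.M_UN == pytest.approx(
            p["m_UI"] + p["m_IU"] + p["m_IN"] + p["m_NI"], abs=1e-12
        )

    def test_fixing_a_parameter_at_truth_does_not_worsen_the_optimum(self, wt_scheme):
        data = generate_chevron(wt_scheme, noise=NOISELESS)
        free = fit_chevron_three_state(data, n_starts=4)
        fixed = fit_chevron_three_state(
            data,
            constraints=FitConstraints(fixed={"k_UI": 1574.0, "m_UI": 1.23, "k_IN": 253.9}),
            n_starts=4,
        )
        assert fixed.residual_rms["rate_ln"] <= free.residual_rms["rate_ln"] + 1e-8

    def test_total_m_range_constraint_is_respected(self, wt_scheme):
        data = generate_chevron(wt_scheme, noise=NoiseModel(seed=21))
        res = fit_chevron_three_state(
            data, constraints=FitConstraints(M_UN_range=(4.6, 5.2)), n_starts=2
        )
        # soft penalty: the total m-value may overshoot only marginally
        assert 4.6 - 1e-3 <= res.thermo.M_UN <= 5.2 + 1e-3

    def test_rate_only_fit_without_amplitudes(self, wt_scheme):
        full = generate_chevron(wt_scheme, noise=NOISELESS)
        data = ChevronDataset(
            denaturant=full.denaturant, kobs=full.kobs, branch=full.branch
        )
        res = fit_chevron_three_state(data, use_signals=True, n_starts=4)
        assert res.params["k_IN"] == pytest.approx(253.9, rel=1e-4)

    def test_round_trip_over_documented_parameter_ranges(self):
        """Noise-free data from random realistic schemes is refit exactly."""
        rng = np.random.default_rng(17)
        coeffs = {"U": (0.8, 0.025), "I": (1.4, 0.0), "N": (0.3, 0.01)}
        for _ in range(5):
            K_UI = 10.0 ** rng.uniform(1.2, 2.6)
            M_UI = rng.uniform(3.4, 4.5)
            true = {
                "k_IU": 1574.0 / K_UI,
                "m_IU": M_UI - 1.23,
                "k_IN": 10.0 ** rng.uniform(2.0, 2.6),
                "m_IN": rng.uniform(0.3, 1.0),
                "k_NI": 10.0 ** rng.uniform(-0.3, 1.0),
                "m_NI": rng.uniform(0.2, 0.7),
            }
            sch = make_three_state_scheme(
                1574.0, 1.23, true["k_IU"], true["m_IU"], true["k_IN"], true["m_IN"],
                true["k_NI"], true["m_NI"], coeffs,
            )
            data = generate_chevron(sch, noise=NOISELESS)
            res = fit_chevron_three_state(data, n_starts=6, random_state=2)
            for name, val in true.items():
                assert res.params[name] == pytest.approx(val, rel=1e-5), (name, true)


class TestTwoStateFit:
    def test_noise_free_round_trip_and_dG(self, library):
        sch = library["IV7T"].to_scheme()
        data = generate_chevron(sch, noise=NOISELESS)
        res = fit_chevron_two_state(data, n_starts=4)
        assert res.params["k_UN"] == pytest.approx(279.4, rel=1e-6)
        assert res.params["m_UN"] == pytest.approx(3.27, rel=1e-6)
        assert res.params["k_NU"] == pytest.approx(3.40, rel=1e-6)
        assert res.params["m_NU"] == pytest.approx(0.68, rel=1e-6)
        assert res.thermo.dG_UN == pytest.approx(-10.38, abs=0.05)

    def test_single_branch_data_flags_unfolding_parameters(self):
        # a stable protein observed only on the refolding branch: the
        # unfolding rate contributes < 0.5% to every observation
        sch = make_two_state_scheme_for_test()
        rng = np.random.default_rng(2)
        D = np.linspace(0.5, 2.5, 10)
        kobs = np.asarray(two_state_kobs(sch, D)) * np.exp(rng.normal(0.0, 0.03, 10))
        data = ChevronDataset(
            denaturant=D, kobs=kobs, branch=np.array(["refolding"] * 10, dtype=object)
        )
        res = fit_chevron_two_state(data, n_starts=2)
        assert any(name in res.unidentifiable for name in ("k_NU", "m_NU"))


class TestAmplitudeModel:
    def test_identical_baselines_make_initial_equal_final(self):
        coeffs = {"U": (0.5, 0.02), "I": (0.5, 0.02), "N": (0.5, 0.02)}
        sch = make_three_state_scheme(1574, 1.23, 7.08, 2.96, 253.9, 0.75, 1.26, 0.45, coeffs)
        D = np.linspace(0.0, 8.0, 20)
        init, final = amplitude_model(sch, D, "refolding")
        assert np.allclose(init, final, atol=1e-12)

    def test_vanishing_K_UI_gives_unfolded_baseline(self):
        coeffs = {"U": (0.8, 0.02), "I": (1.4, 0.0), "N": (0.3, 0.0)}
        # k_IU >> k_UI so the pre-equilibrium sits entirely on U
        sch = make_three_state_scheme(1e-4, 1.23, 1e4, 2.96, 253.9, 0.75, 1.26, 0.45, coeffs)
        init, _ = amplitude_model(sch, 3.0, "refolding")
        assert float(init) == pytest.approx(0.8 + 0.02 * 3.0, rel=1e-6)

    def test_fluorescent_intermediate_gives_burst_phase_rise(self, wt_scheme):
        """With I brighter than U and N the burst overshoots both endpoints."""
        D = 1.0
        init, final = amplitude_model(wt_scheme, D, "refolding")
        u_baseline = wt_scheme.baseline("U", D)
        assert float(init) > float(u_baseline)
        assert float(init) > float(final)

    def test_unfolding_initial_is_native_baseline(self, wt_scheme):
        D = 6.0
        init, _ = amplitude_model(wt_scheme, D, "unfolding")
        assert float(init) == pytest.approx(float(wt_scheme.baseline("N", D)), rel=1e-12)


class TestNormalizeSignals:
    @pytest.mark.parametrize(
        "raw, expected", [(10.0, 1.0), (2.0, 0.0), (6.0, 0.5)]
    )
    def test_linear_mapping(self, raw, expected):
        assert normalize_signals(raw, blank=2.0, reference=10.0) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_signals(1.0, blank=2.0, reference=2.0)


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = ThreeStateChevronFitter(n_starts=3, random_state=5)
        params = est.get_params()
        assert params["n_starts"] == 3
        clone = TwoStateChevronFitter().set_params(n_starts=3)
        assert clone.get_params()["n_starts"] == 3

    def test_fitted_attributes_and_predict(self, wt_scheme):
        data = generate_chevron(wt_scheme, noise=NOISELESS)
        est = ThreeStateChevronFitter(n_starts=2).fit(data)
        assert hasattr(est, "params_") and hasattr(est, "covariance_")
        D = np.array([1.0, 5.0])
        pred = est.predict(D)
        from foldkin.models import observed_slow_rate

        assert np.allclose(pred, observed_slow_rate(wt_scheme, D), rtol=1e-5)
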