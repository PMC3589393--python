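"""Model-free fitting, AIC selection, Rex override, MC uncertainties."""

import numpy as np
import pytest

from liganddyn import (RelaxationSet, aic, analyze_site, chi_square,
                       fit_model, make_params, relaxation_observables,
                       select_model)
from liganddyn.modelfree import (MODEL_FREE_PARAMETERS, ModelFit,
                                 monte_carlo_uncertainties)

from conftest import ACCEPTED_PARAMS, TAU_M, noiseless_observed


class TestChiSquare:
    def test_exact_match_gives_zero(self, constants):
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants)
        pred = relaxation_observables(
            make_params(2, TAU_M, s2=0.72, tau_e=510e-12), constants)
        assert chi_square(obs, pred) == pytest.approx(0.0, abs=1e-18)

    def test_one_sigma_offset_gives_unity(self, constants):
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants)
        pred = relaxation_observables(
            make_params(2, TAU_M, s2=0.72, tau_e=510e-12), constants)
        shifted = RelaxationSet(
            T1=obs.T1, sigma_T1=obs.sigma_T1, T2=obs.T2, sigma_T2=obs.sigma_T2,
            NOE=obs.NOE + obs.sigma_NOE, sigma_NOE=obs.sigma_NOE,
            field_1H=obs.field_1H)
        assert chi_square(shifted, pred) == pytest.approx(1.0, rel=1e-12)

    def test_time_space_switch(self, constants):
        obs = noiseless_observed(2, dict(s2=0.6, tau_e=100e-12), constants)
        pred = relaxation_observables(
            make_params(2, TAU_M, s2=0.65, tau_e=100e-12), constants)
        assert chi_square(obs, pred, space="time") > 0
        with pytest.raises(ValueError):
            chi_square(obs, pred, space="frequency")


class TestAic:
    @pytest.mark.parametrize("chi2,k,expected", [
        (0.0, 3, 6.0),      # exactly interpolating 3-parameter model
        (0.0, 1, 2.0),
        (11.7, 2, 15.7),    # consistent with the n=1 model-2 entry
        (0.5, 2, 4.5),      # inverted from the accepted n=2 entry
    ])
    def test_definition(self, chi2, k, expected):
        assert aic(chi2, k) == pytest.approx(expected)

    def test_negative_chi2_rejected(self):
        with pytest.raises(ValueError):
            aic(-1.0, 2)


class TestFitModel:
    @pytest.mark.parametrize("label", sorted(ACCEPTED_PARAMS))
    def test_noiseless_round_trip_recovers_all_free_parameters(
            self, label, constants):
        model_id, free = ACCEPTED_PARAMS[label]
        obs = noiseless_observed(model_id, free, constants)
        fit = fit_model(model_id, obs, TAU_M, constants)
        assert fit.converged
        recovered = {"s2": fit.params.Ss2, "sf2": fit.params.Sf2,
                     "ss2": fit.params.Ss2, "tau_e": fit.params.tau_e,
                     "rex": fit.params.R_ex}
        for name, truth in free.items():
            assert recovered[name] == pytest.approx(truth, rel=1e-3), name

    def test_three_parameter_model_interpolates_exactly(self, constants):
        obs = noiseless_observed(5, dict(sf2=0.96, ss2=0.78, tau_e=670e-12),
                                 constants)
        fit = fit_model(5, obs, TAU_M, constants)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.aic == pytest.approx(6.0, abs=1e-8)

    def test_k_matches_model_definition(self, constants):
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants)
        for model_id, expected_k in [(1, 1), (2, 2), (3, 2), (4, 3), (5, 3)]:
            fit = fit_model(model_id, obs, TAU_M, constants)
            assert fit.k == expected_k
            assert fit.aic == pytest.approx(fit.chi2 + 2 * fit.k)

    def test_nested_models_never_fit_worse(self, constants):
        # 1 c 2, 1 c 3, 2 c 4, 2 c 5: the larger model's best chi2
        # cannot exceed the smaller one's
        rng = np.random.default_rng(42)
        for _ in range(5):
            obs = RelaxationSet(
                T1=float(rng.uniform(0.4, 1.2)), sigma_T1=0.01,
                T2=float(rng.uniform(0.05, 0.2)), sigma_T2=0.002,
                NOE=float(rng.uniform(-0.5, 0.9)), sigma_NOE=0.05,
            )
            chi2 = {m: fit_model(m, obs, TAU_M, constants).chi2
                    for m in range(1, 6)}
            assert chi2[2] <= chi2[1] + 1e-6
            assert chi2[3] <= chi2[1] + 1e-6
            assert chi2[4] <= chi2[2] + 1e-6
            assert chi2[5] <= chi2[2] + 1e-6


class TestMonteCarlo:
    def test_sigmas_vanish_with_observable_noise(self, constants):
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants,
                                 rel_sigma=2e-8, sigma_noe=5e-8)
        fit = fit_model(2, obs, TAU_M, constants)
        sig = monte_carlo_uncertainties(fit, obs, constants, n=50, seed=1)
        assert sig["s2"] < 1e-6
        assert sig["tau_e"] < 1e-15

    def test_sigma_s2_matches_reported_scale(self, constants):
        # observable sigmas calibrated so sigma_S2 ~ 0.04, the reported
        # uncertainty scale for the accepted two-glycine fit
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants,
                                 rel_sigma=0.065, sigma_noe=0.05)
        fit = fit_model(2, obs, TAU_M, constants)
        sig = monte_carlo_uncertainties(fit, obs, constants, n=500, seed=2)
        assert 0.02 <= sig["s2"] <= 0.06

    def test_seed_to_seed_stability_at_500_draws(self, constants):
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants,
                                 rel_sigma=0.065, sigma_noe=0.05)
        fit = fit_model(2, obs, TAU_M, constants)
        a = monte_carlo_uncertainties(fit, obs, constants, n=500, seed=10)
        b = monte_carlo_uncertainties(fit, obs, constants, n=500, seed=11)
        assert abs(a["s2"] - b["s2"]) / a["s2"] < 0.15

    def test_reproducible_given_seed(self, constants):
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants)
        fit = fit_model(2, obs, TAU_M, constants)
        a = monte_carlo_uncertainties(fit, obs, constants, n=50, seed=3)
        b = monte_carlo_uncertainties(fit, obs, constants, n=50, seed=3)
        assert a == b

    def test_coverage_of_true_s2_under_noise(self, constants):
        # noisy triples at the reported sigma scale: the recovered S2
        # should sit within 2 reported sigmas of truth in >= 90% of runs
        truth = make_params(2, TAU_M, s2=0.72, tau_e=510e-12)
        pred = relaxation_observables(truth, constants)
        rel = 0.02
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            obs = RelaxationSet(
                T1=pred.T1 * (1 + rng.normal(0, rel)),
                sigma_T1=rel * pred.T1,
                T2=pred.T2 * (1 + rng.normal(0, rel)),
                sigma_T2=rel * pred.T2,
                NOE=pred.NOE + rng.normal(0, 0.05), sigma_NOE=0.05,
            )
            fit = fit_model(2, obs, TAU_M, constants)
            sig = monte_carlo_uncertainties(fit, obs, constants, n=60,
                                            seed=int(rng.integers(2**31)))
            if abs(fit.params.S2 - 0.72) <= 2 * max(sig["s2"], 1e-6):
                hits += 1
        assert hits / n_rep >= 0.90


def _fit(model_id: int, chi2: float, rex: float = 0.0) -> ModelFit:
    """Hand-built ModelFit with a prescribed chi2, for selection tests."""
    from liganddyn.physics import ModelFreeParams
    kwargs = {}
    if model_id in (3, 4):
        kwargs["R_ex"] = rex
    if model_id in (2, 4, 5):
        kwargs["tau_e"] = 1e-10
    params = ModelFreeParams(
        model_id=model_id, tau_m=TAU_M,
        Sf2=1.0 if model_id != 5 else 0.9, Ss2=0.7, **kwargs)
    k = len(MODEL_FREE_PARAMETERS[model_id])
    return ModelFit(params=params, chi2=chi2, k=k, aic=chi2 + 2 * k)


class TestSelectModel:
    def test_minimal_aic_wins(self, constants):
        obs = noiseless_observed(2, dict(s2=0.49, tau_e=90e-12), constants)
        fits = [_fit(2, 11.7), _fit(4, 0.0, rex=2.3)]
        res = select_model(fits, obs)
        assert res.chosen.model_id == 4
        assert not res.rex_override_applied

    def test_t1rho_near_t2_overrides_exchange_model(self, constants):
        obs = noiseless_observed(2, dict(s2=0.49, tau_e=90e-12), constants)
        obs.T1rho = obs.T2 * 1.02
        fits = [_fit(2, 11.7), _fit(4, 0.0, rex=2.3)]
        res = select_model(fits, obs)
        assert res.rex_override_applied
        assert res.chosen.model_id == 2
        assert res.t1rho_t2_ratio == pytest.approx(1.02)

    def test_t1rho_far_from_t2_keeps_exchange_model(self, constants):
        obs = noiseless_observed(2, dict(s2=0.49, tau_e=90e-12), constants)
        obs.T1rho = obs.T2 * 1.25
        res = select_model([_fit(2, 11.7), _fit(4, 0.0, rex=2.3)], obs)
        assert res.chosen.model_id == 4
        assert not res.rex_override_applied

    def test_equal_aic_prefers_fewer_parameters(self, constants):
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants)
        res = select_model([_fit(5, 0.0), _fit(1, 4.0)], obs)
        assert res.chosen.model_id == 1  # both AIC 6.0; k=1 beats k=3

    def test_order_invariance(self, constants):
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants)
        fits = [_fit(1, 9.0), _fit(2, 1.0), _fit(4, 0.1), _fit(5, 0.3)]
        ids = {select_model(list(perm), obs).chosen.model_id
               for perm in ([0, 1, 2, 3], [3, 2, 1, 0], [1, 3, 0, 2])
               for perm in [[fits[j] for j in perm]]}
        assert len(ids) == 1

    def test_selection_pipeline_on_exchange_free_site(self, constants):
        # end-to-end: AIC picks an interpolating 3-parameter model or
        # better; with T1rho ~ T2 no exchange model survives
        obs = noiseless_observed(2, dict(s2=0.72, tau_e=510e-12), constants)
        obs.T1rho = obs.T2
        res = analyze_site(obs, TAU_M, constants, mc_draws=0)
        assert res.chosen.params.model_id in (1, 2, 5)
        assert res.chosen.params.R_ex == 0.0
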