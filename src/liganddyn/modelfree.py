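"""Model-free fitting, AIC model selection, and Monte Carlo uncertainties.

Each site contributes one (T1, T2, NOE) triple.  The five standard
model-free models are fit by deterministic multi-start bounded least
squares in rate space; Akaike's information criterion AIC = chi2 + 2k
(k = number of free parameters) picks the model.  When rotating-frame
data show T1rho ~ T2, any exchange term the AIC favored is overridden
and the best exchange-free model is adopted instead, mirroring how a
spin-lock experiment bounds detectable R_ex from below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .physics import (
    MODEL_FREE_PARAMETERS,
    ModelFreeParams,
    RelaxationPrediction,
    SpinConstants,
    make_params,
    relaxation_observables,
)

#: |T1rho/T2 - 1| below this means the spin lock saw no slow exchange
T1RHO_RATIO_TOLERANCE = 0.10

#: AIC differences below this are treated as ties (simpler model wins)
AIC_TIE_TOLERANCE = 1e-6

#: multi-start grids (order parameters dimensionless, tau_e in ns, Rex 1/s)
_S_STARTS = (0.3, 0.6, 0.9)
_TAU_E_STARTS_NS = (0.01, 0.1, 1.0)
_REX_STARTS = (0.0, 5.0)

REX_UPPER_BOUND = 100.0  # 1/s, far below the spin-lock detectability bound


@dataclass
class RelaxationSet:
    """Observed relaxation data for one site, with uncertainties."""

    T1: float
    sigma_T1: float
    T2: float
    sigma_T2: float
    NOE: float
    sigma_NOE: float
    T1rho: float | None = None
    sigma_T1rho: float | None = None
    field_1H: float = 600.0
    site_id: str = ""

    def __post_init__(self) -> None:
        for name in ("T1", "T2", "NOE", "sigma_T1", "sigma_T2", "sigma_NOE"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (self.T1 > 0 and self.T2 > 0):
            raise ValueError("T1 and T2 must be positive")
        if min(self.sigma_T1, self.sigma_T2, self.sigma_NOE) <= 0:
            raise ValueError("uncertainties must be positive")


@dataclass
class ModelFit:
    """One model's best fit to a RelaxationSet."""

    params: ModelFreeParams
    chi2: float
    k: int
    aic: float
    converged: bool = True
    param_sigmas: dict[str, float] | None = None
    mc_flagged: bool = False

    @property
    def model_id(self) -> int:
        return self.params.model_id


@dataclass
class SelectionResult:
    chosen: ModelFit
    all_fits: list[ModelFit]
    rex_override_applied: bool = False
    t1rho_t2_ratio: float | None = None


def aic(chi2: float, k: int) -> float:
    """Akaike's information criterion, chi2 + 2k."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if k < 1:
        raise ValueError("k must be at least 1")
    return chi2 + 2.0 * k


def _weighted_residuals(
    observed: RelaxationSet, predicted: RelaxationPrediction, space: str
) -> np.ndarray:
    if space == "rate":
        # sigma_R = sigma_T / T^2 by first-order propagation
        r1_o, s_r1 = 1.0 / observed.T1, observed.sigma_T1 / observed.T1**2
        r2_o, s_r2 = 1.0 / observed.T2, observed.sigma_T2 / observed.T2**2
        res = [
            (r1_o - predicted.R1) / s_r1,
            (r2_o - predicted.R2) / s_r2,
            (observed.NOE - predicted.NOE) / observed.sigma_NOE,
        ]
    elif space == "time":
        res = [
            (observed.T1 - predicted.T1) / observed.sigma_T1,
            (observed.T2 - predicted.T2) / observed.sigma_T2,
            (observed.NOE - predicted.NOE) / observed.sigma_NOE,
        ]
    else:
        raise ValueError(f"unknown chi2 space {space!r}")
    return np.array(res)


def chi_square(
    observed: RelaxationSet,
    predicted: RelaxationPrediction,
    space: str = "rate",
) -> float:
    """Sum of squared sigma-weighted residuals over {R1, R2, NOE}.

    Computed in rate space by default (T converted to R = 1/T with
    sigma_R = sigma_T / T^2); ``space="time"`` compares T1/T2 directly.
    """
    return float(np.sum(_weighted_residuals(observed, predicted, space) ** 2))


def _vector_to_params(
    model_id: int, x: np.ndarray, tau_m: float
) -> ModelFreeParams:
    names = MODEL_FREE_PARAMETERS[model_id]
    free: dict[str, float] = {}
    for name, value in zip(names, x):
        if name == "tau_e":
            value = value * 1e-9  # optimizer works in ns
        free[name] = float(value)
    return make_params(model_id, tau_m, **free)


def _start_grid(model_id: int, tau_m_ns: float) -> list[tuple[float, ...]]:
    te = [min(t, tau_m_ns) for t in _TAU_E_STARTS_NS]
    if model_id == 1:
        return [(s,) for s in _S_STARTS]
    if model_id == 2:
        return [(s, t) for s in _S_STARTS for t in te]
    if model_id == 3:
        return [(s, r) for s in _S_STARTS for r in _REX_STARTS]
    if model_id == 4:
        return [(s, t, r) for s in _S_STARTS for t in te for r in _REX_STARTS]
    return [(sf, ss, t) for sf in _S_STARTS for ss in _S_STARTS for t in te]


def _bounds(model_id: int, tau_m_ns: float) -> tuple[list[float], list[float]]:
    lo, hi = [], []
    for name in MODEL_FREE_PARAMETERS[model_id]:
        if name in ("s2", "sf2", "ss2"):
            lo.append(0.0), hi.append(1.0)
        elif name == "tau_e":
            lo.append(0.0), hi.append(tau_m_ns)
        else:  # rex
            lo.append(0.0), hi.append(REX_UPPER_BOUND)
    return lo, hi


def fit_model(
    model_id: int,
    observed: RelaxationSet,
    tau_m: float,
    constants: SpinConstants | None = None,
    space: str = "rate",
) -> ModelFit:
    """Fit one model-free model to an observed triple.

    Deterministic multi-start bounded least squares: order parameters
    start on {0.3, 0.6, 0.9}, tau_e on {10 ps, 100 ps, 1 ns}, R_ex on
    {0, 5}; the lowest final chi2 wins, ties going to the earliest grid
    point.  tau_e is optimized in ns so all parameters are O(1).
    """
    if model_id not in MODEL_FREE_PARAMETERS:
        raise ValueError(f"model_id must be 1..5, got {model_id}")
    if constants is None:
        constants = SpinConstants(field_1H=observed.field_1H)
    tau_m_ns = tau_m * 1e9

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _vector_to_params(model_id, np.clip(x, lo, hi), tau_m)
        return _weighted_residuals(observed, relaxation_observables(p, constants), space)

    lo, hi = _bounds(model_id, tau_m_ns)
    best_x, best_chi2, converged = None, np.inf, False
    for x0 in _start_grid(model_id, tau_m_ns):
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:
            continue
        c2 = float(np.sum(sol.fun**2))
        if np.isfinite(c2) and c2 < best_chi2 - 1e-12:
            best_x, best_chi2 = sol.x, c2
            converged = True
    if best_x is None:
        params = make_params(model_id, tau_m)
        return ModelFit(params=params, chi2=np.inf,
                        k=len(MODEL_FREE_PARAMETERS[model_id]), aic=np.inf,
                        converged=False)
    params = _vector_to_params(model_id, best_x, tau_m)
    k = len(MODEL_FREE_PARAMETERS[model_id])
    return ModelFit(params=params, chi2=best_chi2, k=k,
                    aic=aic(best_chi2, k), converged=converged)


def monte_carlo_uncertainties(
    fit: ModelFit,
    observed: RelaxationSet,
    constants: SpinConstants | None = None,
    n: int = 500,
    seed: int = 0,
    space: str = "rate",
) -> dict[str, float]:
    """Monte Carlo parameter uncertainties for a converged fit.

    Draws ``n`` synthetic (T1, T2, NOE) triples as Gaussian noise about
    the back-calculated observables at the experimental sigmas, refits
    the same model from the fitted solution (warm start), and returns
    the per-parameter standard deviations.  ``fit.param_sigmas`` and
    ``fit.mc_flagged`` (>20% refit failures) are filled in place.
    """
    if not fit.converged:
        raise ValueError("Monte Carlo uncertainties require a converged fit")
    if n < 2:
        raise ValueError("need at least 2 Monte Carlo draws")
    if constants is None:
        constants = SpinConstants(field_1H=observed.field_1H)
    model_id = fit.params.model_id
    tau_m = fit.params.tau_m
    tau_m_ns = tau_m * 1e9
    names = MODEL_FREE_PARAMETERS[model_id]
    pred = relaxation_observables(fit.params, constants)
    x_hat = []
    for name in names:
        value = {"s2": fit.params.Ss2, "sf2": fit.params.Sf2,
                 "ss2": fit.params.Ss2, "tau_e": fit.params.tau_e * 1e9,
                 "rex": fit.params.R_ex}[name]
        x_hat.append(value)

    rng = np.random.default_rng(seed)
    lo, hi = _bounds(model_id, tau_m_ns)
    draws, failures = [], 0
    for _ in range(n):
        synth = replace(
            observed,
            T1=max(pred.T1 + rng.normal(0.0, observed.sigma_T1), 1e-6),
            T2=max(pred.T2 + rng.normal(0.0, observed.sigma_T2), 1e-6),
            NOE=pred.NOE + rng.normal(0.0, observed.sigma_NOE),
        )

        def residuals(x: np.ndarray) -> np.ndarray:
            p = _vector_to_params(model_id, np.clip(x, lo, hi), tau_m)
            return _weighted_residuals(synth, relaxation_observables(p, constants), space)

        try:
            sol = least_squares(residuals, x_hat, bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12,
                                gtol=1e-12, max_nfev=500)
            if not np.all(np.isfinite(sol.x)):
                raise RuntimeError
            draws.append(sol.x)
        except Exception:
            failures += 1
    if not draws:
        fit.mc_flagged = True
        fit.param_sigmas = {name: np.inf for name in names}
        return fit.param_sigmas
    sds = np.std(np.array(draws), axis=0, ddof=1)
    sigmas = {}
    for name, sd in zip(names, sds):
        sigmas[name] = float(sd * 1e-9) if name == "tau_e" else float(sd)
    fit.param_sigmas = sigmas
    fit.mc_flagged = failures > 0.2 * n
    return sigmas


def _argmin_aic(fits: list[ModelFit]) -> ModelFit:
    # Order-invariant: sort by (k, model_id) first so AIC ties resolve to
    # the simpler (then lower-numbered) model.
    best = None
    for f in sorted(fits, key=lambda f: (f.k, f.model_id)):
        if best is None or f.aic < best.aic - AIC_TIE_TOLERANCE:
            best = f
    return best


def select_model(
    all_fits: list[ModelFit], observed: RelaxationSet
) -> SelectionResult:
    """Pick the minimum-AIC model, then apply the T1rho-based Rex check.

    If the AIC winner carries an exchange term but the observed
    T1rho/T2 ratio is within 10% of unity, the spin-lock data contradict
    a slow-exchange contribution and the best exchange-free model is
    adopted instead (flagged in the result).
    """
    fits = [f for f in all_fits if f.converged]
    if len(fits) < 2:
        raise ValueError("need at least two converged fits to select a model")
    chosen = _argmin_aic(fits)
    ratio = None
    override = False
    if observed.T1rho is not None and observed.T2 > 0:
        ratio = observed.T1rho / observed.T2
    if chosen.params.model_id in (3, 4) and ratio is not None:
        if abs(ratio - 1.0) < T1RHO_RATIO_TOLERANCE:
            rex_free = [f for f in fits if f.params.model_id in (1, 2, 5)]
            if rex_free:
                chosen = _argmin_aic(rex_free)
                override = True
    return SelectionResult(chosen=chosen, all_fits=list(all_fits),
                           rex_override_applied=override,
                           t1rho_t2_ratio=ratio)


def analyze_site(
    observed: RelaxationSet,
    tau_m: float,
    constants: SpinConstants | None = None,
    mc_draws: int = 500,
    seed: int = 0,
    space: str = "rate",
) -> SelectionResult:
    """Fit all five models, select one, and attach MC uncertainties."""
    fits = [fit_model(m, observed, tau_m, constants, space) for m in range(1, 6)]
    result = select_model(fits, observed)
    if mc_draws >= 2 and result.chosen.converged:
        monte_carlo_uncertainties(result.chosen, observed, constants,
                                  n=mc_draws, seed=seed, space=space)
    return result
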