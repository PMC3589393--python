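"""Diffusion from pulsed-field-gradient attenuation and the aggregation test.

A stimulated-echo DOSY experiment attenuates each peak by
exp(-D b), with the Stejskal-Tanner factor b = (gamma g delta)^2
(Delta - delta/3).  Curves are fit bi-exponentially to allow for two
slowly exchanging species, collapsing to a single D when the data do
not support two.  Fitted D values across a homologous ligand series are
then compared with the Wilke-Chang correlation D ~ M^-0.6: a log-log
slope steeper (more negative) than -0.6 is the signature of
mass-dependent aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .physics import GAMMA_H


@dataclass(frozen=True)
class GradientGeometry:
    """Gradient timing and strength for a stimulated-echo experiment.

    Defaults are the acquisition used for the ligand series: diffusion
    time Delta = 100 ms, gradient length delta = 2.5 ms, maximum
    gradient 53.5 G/cm (0.535 T/m), 16 fractions linear from 2% to 95%.
    ``tau_g`` optionally applies the bipolar-pair correction
    (Delta - delta/3 - tau_g/2); off by default.
    """

    big_delta: float = 0.100
    little_delta: float = 0.0025
    g_max: float = 0.535
    fractions: tuple[float, ...] = tuple(np.linspace(0.02, 0.95, 16))
    tau_g: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.little_delta < self.big_delta:
            raise ValueError("need 0 < little_delta < big_delta")
        if not self.g_max > 0:
            raise ValueError("g_max must be positive")
        fr = np.asarray(self.fractions, dtype=float)
        if np.any(fr <= 0) or np.any(fr > 1) or np.any(np.diff(fr) <= 0):
            raise ValueError("fractions must be strictly increasing in (0, 1]")


@dataclass
class AttenuationCurve:
    """Peak intensity versus gradient fraction for one resonance."""

    geometry: GradientGeometry
    intensities: np.ndarray
    peak_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.intensities) != len(self.geometry.fractions):
            raise ValueError("intensities must match the gradient schedule")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class DiffusionFit:
    """Bi-exponential diffusion fit, possibly collapsed to one species."""

    components: list[tuple[float, float]]  # (amplitude, D in m^2/s)
    collapsed_D: float | None
    sigma_D: float
    low_confidence: bool = False

    @property
    def n_species(self) -> int:
        return 1 if self.collapsed_D is not None else len(self.components)


@dataclass(frozen=True)
class WilkeChangConstants:
    """Constants of the Wilke-Chang correlation for water at ~298 K.

    D [cm^2/s] = prefactor (x M_solvent)^1/2 T / (eta (M_solute/rho)^0.6)
    with x the solvent association parameter (2.26 for water), eta in cP,
    T in K, rho the solute density in g/cm^3.
    """

    prefactor: float = 7.4e-8
    x: float = 2.26
    M_solvent: float = 18.0
    eta: float = 0.8899
    T: float = 300.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        for name in ("prefactor", "x", "M_solvent", "eta", "T", "rho"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AggregationTestResult:
    slope: float
    sigma_slope: float
    intercept: float
    sigma_intercept: float
    r_squared: float
    theory_slope: float
    theory_intercept: float
    verdict: str  # "monomer" | "aggregation-suspected"


#: relative D separation below which two components count as one species
COLLAPSE_D_RTOL = 1e-3
#: minor-component amplitude fraction below which it is ignored
COLLAPSE_AMPLITUDE_FRACTION = 0.05


def b_factor(fraction, geometry: GradientGeometry, gamma_h: float = GAMMA_H):
    """Stejskal-Tanner b (s/m^2) at a gradient fraction of g_max."""
    g = np.asarray(fraction, dtype=float) * geometry.g_max
    eff = geometry.big_delta - geometry.little_delta / 3.0
    if geometry.tau_g is not None:
        eff -= geometry.tau_g / 2.0
    b = (gamma_h * g * geometry.little_delta) ** 2 * eff
    return float(b) if np.ndim(fraction) == 0 else b


#: bi-exponential split is kept only when it improves on the single
#: species fit at this (strict) partial F-test level; a genuine second
#: species is overwhelmingly significant, while chance splits at this
#: level would otherwise report badly biased weighted D values
SPLIT_ALPHA = 1e-3

#: component D values are confined to this factor around the log-linear
#: initial estimate; a "species" outside it only chases single points
D_BOUND_FACTOR = 20.0

#: relative noise floor used to weight residuals (peak-height noise in
#: these experiments is multiplicative)
NOISE_FLOOR_FRACTION = 0.02


def fit_attenuation(
    curve: AttenuationCurve, gamma_h: float = GAMMA_H
) -> DiffusionFit:
    """Fit I(b) = A1 exp(-D1 b) + A2 exp(-D2 b) with fixed starts.

    Residuals are weighted relative to intensity (multiplicative noise
    model, floored at NOISE_FLOOR_FRACTION of the first point); the
    initial D comes from a log-linear regression and fixed starting
    splits make the fit deterministic.  The two components collapse to
    a single reported D when any of these hold: the bi-exponential does
    not improve on the mono-exponential fit (partial F-test at
    SPLIT_ALPHA -- a second species the data cannot support is noise),
    the minor amplitude is <5%, or the two D values are
    indistinguishable (within 2 sigma_D, with a small relative floor so
    exactly coincident components also collapse).  Curves attenuating
    by less than 50% are flagged low-confidence.
    """
    fr = np.asarray(curve.geometry.fractions)
    if len(fr) < 6:
        raise ValueError("need at least 6 gradient steps")
    b = b_factor(fr, curve.geometry, gamma_h)
    i = curve.intensities
    if i[0] <= 0:
        raise ValueError("first-point intensity must be positive")
    low_confidence = bool(i[-1] > 0.5 * i[0])
    sig = np.maximum(i, NOISE_FLOOR_FRACTION * i[0])

    pos = i > 0
    slope, logi0 = np.polyfit(b[pos], np.log(i[pos]), 1)
    d0 = max(-slope, 1e-13)
    i0 = math.exp(logi0)

    # optimizer units: amplitudes relative to i0, D in 1e-10 m^2/s
    scale = 1e-10
    d0s = d0 / scale
    lo_d, hi_d = d0s / D_BOUND_FACTOR, d0s * D_BOUND_FACTOR
    lsq = dict(method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
               max_nfev=5000)

    def mono_residuals(x):
        a, d = x
        return (i0 * a * np.exp(-d * scale * b) - i) / sig

    mono = least_squares(mono_residuals, (1.0, d0s),
                         bounds=([0.0, lo_d], [10.0, hi_d]), **lsq)
    d_mono = mono.x[1] * scale
    rss_mono = 2.0 * mono.cost
    dof_mono = max(len(i) - 2, 1)
    cov_mono = np.linalg.pinv(mono.jac.T @ mono.jac) \
        * (rss_mono / dof_mono)
    sd_mono = math.sqrt(max(cov_mono[1, 1], 0.0)) * scale

    def residuals(x):
        a1, a2, d1, d2 = x
        model = i0 * (a1 * np.exp(-d1 * scale * b)
                      + a2 * np.exp(-d2 * scale * b))
        return (model - i) / sig

    starts = [
        (0.5, 0.5, min(2.0 * d0s, hi_d), max(0.5 * d0s, lo_d)),
        (0.9, 0.1, d0s, max(0.2 * d0s, lo_d)),
    ]
    lo = [0.0, 0.0, lo_d, lo_d]
    hi = [10.0, 10.0, hi_d, hi_d]
    best, best_cost = None, np.inf
    for x0 in starts:
        sol = least_squares(residuals, x0, bounds=(lo, hi), **lsq)
        if sol.cost < best_cost - 1e-30:
            best, best_cost = sol, sol.cost
    a1, a2, d1s, d2s = best.x
    d1, d2 = d1s * scale, d2s * scale
    amp1, amp2 = a1 * i0, a2 * i0
    rss_bi = 2.0 * best.cost
    dof_bi = max(len(i) - 4, 1)

    # does the second species earn its two extra parameters?
    floor = 1e-20 * float(np.sum((i / sig) ** 2))
    if rss_mono <= floor:
        split_supported = False  # both fits exact; one species suffices
    else:
        f_stat = ((rss_mono - rss_bi) / 2.0) / max(rss_bi / dof_bi, 1e-300)
        split_supported = stats.f.sf(f_stat, 2, dof_bi) < SPLIT_ALPHA

    components = [(float(amp1), float(d1)), (float(amp2), float(d2))]
    if not split_supported:
        return DiffusionFit(components=components,
                            collapsed_D=float(d_mono),
                            sigma_D=float(sd_mono),
                            low_confidence=low_confidence)

    # covariance of the bi-exponential fit; pseudo-inverse if degenerate
    s2 = rss_bi / dof_bi
    cov = np.linalg.pinv(best.jac.T @ best.jac) * s2
    sd1 = math.sqrt(max(cov[2, 2], 0.0)) * scale
    sd2 = math.sqrt(max(cov[3, 3], 0.0)) * scale

    total = amp1 + amp2
    minor_frac = min(amp1, amp2) / total if total > 0 else 0.0
    sigma_d = max(sd1, sd2)
    indistinct = abs(d1 - d2) < max(2.0 * sigma_d,
                                    COLLAPSE_D_RTOL * max(d1, d2))
    if minor_frac < COLLAPSE_AMPLITUDE_FRACTION:
        # stray near-zero-amplitude component: report the major D
        collapsed = d1 if amp1 >= amp2 else d2
        return DiffusionFit(components=components, collapsed_D=float(collapsed),
                            sigma_D=float(min(sd1, sd2)),
                            low_confidence=low_confidence)
    if indistinct:
        collapsed = (amp1 * d1 + amp2 * d2) / total
        return DiffusionFit(components=components, collapsed_D=float(collapsed),
                            sigma_D=float(min(sd1, sd2)),
                            low_confidence=low_confidence)
    return DiffusionFit(components=components, collapsed_D=None,
                        sigma_D=float(sigma_d), low_confidence=low_confidence)


def wilke_chang_diffusion(
    m_solute: float, k: WilkeChangConstants = WilkeChangConstants()
) -> float:
    """Wilke-Chang diffusion coefficient in m^2/s for a solute mass.

    log10 D is linear in log10 M with slope exactly -0.6.
    """
    if not m_solute > 0:
        raise ValueError("M_solute must be positive")
    d_cm2 = (k.prefactor * math.sqrt(k.x * k.M_solvent) * k.T
             / (k.eta * (m_solute / k.rho) ** 0.6))
    return d_cm2 * 1e-4


def theory_intercept(k: WilkeChangConstants = WilkeChangConstants()) -> float:
    """log10 D (m^2/s) of the Wilke-Chang line at log10 M = 0."""
    return math.log10(wilke_chang_diffusion(1.0, k))


#: absolute tolerance floors for the monomer verdict (noiseless data has
#: zero standard errors, where a pure 3-sigma band would be empty)
SLOPE_ATOL = 0.02
INTERCEPT_ATOL = 0.06


def aggregation_test(
    d_values,
    m_values,
    k: WilkeChangConstants = WilkeChangConstants(),
    n_sigma: float = 3.0,
) -> AggregationTestResult:
    """OLS of log10 D on log10 M against the Wilke-Chang expectation.

    Verdict "monomer" when slope and intercept agree with theory within
    n_sigma standard errors (plus small absolute floors); otherwise
    "aggregation-suspected" -- a more negative slope than -0.6 is what a
    mass-dependent multimerization produces.
    """
    d = np.asarray(d_values, dtype=float)
    m = np.asarray(m_values, dtype=float)
    if len(d) < 3 or len(d) != len(m):
        raise ValueError("need at least 3 matched (D, M) pairs")
    if np.any(d <= 0) or np.any(m <= 0):
        raise ValueError("D and M must be positive")
    fit = stats.linregress(np.log10(m), np.log10(d))
    t_int = theory_intercept(k)
    slope_ok = abs(fit.slope - (-0.6)) <= n_sigma * fit.stderr + SLOPE_ATOL
    int_ok = (abs(fit.intercept - t_int)
              <= n_sigma * fit.intercept_stderr + INTERCEPT_ATOL)
    verdict = "monomer" if (slope_ok and int_ok) else "aggregation-suspected"
    return AggregationTestResult(
        slope=float(fit.slope), sigma_slope=float(fit.stderr),
        intercept=float(fit.intercept),
        sigma_intercept=float(fit.intercept_stderr),
        r_squared=float(fit.rvalue**2), theory_slope=-0.6,
        theory_intercept=t_int, verdict=verdict,
    )
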