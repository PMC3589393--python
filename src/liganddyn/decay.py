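"""Exponential decay fitting for T1 / T2 / T1rho and NOE ratio reduction.

Peak intensities from HSQC spectra recorded at a schedule of relaxation
delays are fit to a two-parameter exponential I(t) = I0 exp(-t/T) by
weighted non-linear least squares.  The steady-state NOE is reduced from
a saturated/reference intensity pair with a correction for incomplete
longitudinal recovery during the recycle delay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

#: delay schedules (s) used for the free and protein-bound ligand series
DELAY_PRESETS: dict[str, tuple[float, ...]] = {
    "free-T1": (0.05, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 10.0),
    "free-T2": (0.016, 0.096, 0.256, 0.512, 0.736, 0.992, 1.504, 2.000,
                2.992, 5.008),
    "bound-T1": (0.0109, 0.0543, 0.1086, 0.2173, 0.3802, 0.5432, 0.7605,
                 0.9978, 1.3037, 1.6296),
    "bound-T2": (0.016, 0.032, 0.048, 0.064, 0.096, 0.128, 0.160, 0.192,
                 0.224, 0.256),
}
DELAY_PRESETS["bound-T1rho"] = DELAY_PRESETS["bound-T2"]

#: best-fit decay times beyond this bound are treated as non-decaying
T_UPPER_BOUND = 1.0e6

#: duplicate-intensity deviations above this fraction raise a QC flag
DUPLICATE_QC_THRESHOLD = 0.10


@dataclass
class DecaySeries:
    """One peak-intensity decay: delays (s), intensities, optional sigma.

    ``duplicates`` holds repeat measurements as (delay, intensity) pairs;
    each delay must also appear in the main schedule.  Points are stored
    sorted by delay, so fits do not depend on input order.
    """

    delays: np.ndarray
    intensities: np.ndarray
    sigma: np.ndarray | None = None
    duplicates: list[tuple[float, float]] = field(default_factory=list)
    site_id: str = ""
    experiment: str = ""

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.ndim != 1 or self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must be equal-length 1-D")
        if len(self.delays) < 3:
            raise ValueError("need at least 3 points to fit a decay")
        if not np.all(self.delays > 0):
            raise ValueError("delays must be strictly positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        order = np.argsort(self.delays, kind="stable")
        self.delays = self.delays[order]
        self.intensities = self.intensities[order]
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)[order]
            if not np.all(self.sigma > 0):
                raise ValueError("sigma values must be positive")
        if len(np.unique(self.delays)) != len(self.delays):
            raise ValueError("duplicate delays belong in `duplicates`")
        for t, _ in self.duplicates:
            if not np.any(np.isclose(self.delays, t)):
                raise ValueError(f"duplicate delay {t} not in the schedule")


@dataclass(frozen=True)
class ExpFit:
    """Result of a two-parameter exponential fit I(t) = I0 exp(-t/T)."""

    I0: float
    T: float
    sigma_I0: float
    sigma_T: float
    rss: float
    success: bool = True

    @property
    def rate(self) -> float:
        return 1.0 / self.T


def _initial_guess(t: np.ndarray, i: np.ndarray) -> tuple[float, float]:
    # I0 = max intensity; T = delay where intensity first drops below
    # I0/e, linearly interpolated.  Fixed rule, so the fit is deterministic.
    i0 = float(np.max(i))
    target = i0 / math.e
    below = np.nonzero(i < target)[0]
    if len(below) == 0 or below[0] == 0:
        t_guess = float(t[-1]) if len(below) == 0 else float(t[0])
    else:
        k = below[0]
        frac = (i[k - 1] - target) / (i[k - 1] - i[k])
        t_guess = float(t[k - 1] + frac * (t[k] - t[k - 1]))
    return i0, max(t_guess, 1e-6)


def duplicate_consistency(series: DecaySeries) -> float | None:
    """Max fractional deviation |dI| / mean(I) over duplicate pairs.

    Returns None (with a warning) when the series has no duplicates.
    Values above DUPLICATE_QC_THRESHOLD (10%) indicate the measurement
    noise exceeds what the acquisition protocol tolerates.
    """
    if not series.duplicates:
        warnings.warn("no duplicate delays recorded; consistency undefined")
        return None
    worst = 0.0
    for t, i_dup in series.duplicates:
        k = int(np.argmin(np.abs(series.delays - t)))
        i_main = series.intensities[k]
        mean = 0.5 * (i_main + i_dup)
        if mean == 0:
            continue
        worst = max(worst, abs(i_main - i_dup) / abs(mean))
    return worst


def duplicate_sigma(series: DecaySeries) -> float | None:
    """RMS point uncertainty implied by the duplicate pairs."""
    if not series.duplicates:
        return None
    sq = []
    for t, i_dup in series.duplicates:
        k = int(np.argmin(np.abs(series.delays - t)))
        sq.append(0.5 * (series.intensities[k] - i_dup) ** 2)
    rms = math.sqrt(float(np.mean(sq)))
    return rms if rms > 0 else None


def fit_exponential_decay(series: DecaySeries) -> ExpFit:
    """Weighted least-squares fit of I(t) = I0 exp(-t/T).

    Weights: explicit per-point sigma when given (uncertainties are then
    absolute); otherwise uniform weighting with the scale taken from the
    duplicate-pair RMS when available (covariance then rescaled by the
    residual variance, the usual convention for unknown noise).

    A best-fit T running into the 1e6 s bound is reported with
    ``success=False`` (non-decaying data).
    """
    t, i = series.delays, series.intensities
    if np.ptp(i) == 0:
        raise ValueError("intensities are all equal; nothing to fit")
    sigma = series.sigma
    absolute = sigma is not None
    if sigma is None:
        s = duplicate_sigma(series)
        sigma = np.full_like(i, s if s is not None else 1.0)

    p0 = _initial_guess(t, i)

    def model(tt, i0, tau):
        return i0 * np.exp(-tt / tau)

    try:
        popt, pcov = curve_fit(
            model, t, i, p0=p0, sigma=sigma, absolute_sigma=absolute,
            bounds=((0.0, 1e-12), (np.inf, T_UPPER_BOUND)), maxfev=10000,
            xtol=1e-13, ftol=1e-13, gtol=1e-13,
        )
    except RuntimeError:
        return ExpFit(I0=p0[0], T=p0[1], sigma_I0=np.inf, sigma_T=np.inf,
                      rss=np.inf, success=False)
    i0_hat, t_hat = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = (i - model(t, *popt)) / sigma
    rss = float(np.sum(resid**2))
    ok = t_hat < 0.999 * T_UPPER_BOUND
    return ExpFit(I0=i0_hat, T=t_hat, sigma_I0=float(perr[0]),
                  sigma_T=float(perr[1]), rss=rss, success=ok)


def noe_from_ratio(
    i_sat: float, i_ref: float, t1: float, recycle_delay: float
) -> float:
    """Steady-state NOE from a saturated/reference intensity pair.

    NOE = (I_sat / I_ref) * (1 - exp(-d/T1)) where d is the recycle
    delay.  The multiplicative factor accounts for incomplete
    longitudinal recovery during d and tends to 1 as d/T1 -> infinity,
    so the NOE reduces to the bare ratio at long recycle delays.
    """
    if i_ref == 0:
        raise ValueError("reference intensity must be non-zero")
    if not t1 > 0:
        raise ValueError("T1 must be positive")
    if not recycle_delay > 0:
        raise ValueError("recycle delay must be positive")
    f_corr = 1.0 - math.exp(-recycle_delay / t1)
    return (i_sat / i_ref) * f_corr
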