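"""Synthetic-data generators standing in for the spectrometer.

Every input the analysis consumes can be generated here with the
statistical structure the downstream fits assume: mono-exponential
HSQC intensity decays with multiplicative replicate noise, stimulated-
echo attenuation curves for monomer/aggregate mixtures, and EX2-style
global deuterium uptake with back-exchange.  All randomness flows
through a mandatory seed, so two runs with the same configuration are
identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import decay as decay_mod
from .decay import DELAY_PRESETS, DecaySeries, fit_exponential_decay, noe_from_ratio
from .dosy import AttenuationCurve, GradientGeometry, b_factor, wilke_chang_diffusion
from .hdx import HdxRecord, PERDEUTERATION_FRACTION
from .masses import DELTA_MASS_D_H, average_mass, deprotonated_mz
from .modelfree import RelaxationSet
from .physics import ModelFreeParams, SpinConstants, relaxation_observables

#: total ligand concentration in the diffusion experiments (mol/L)
LIGAND_CONCENTRATION = 0.5e-3

#: average mass of the undeuterated protein standard (bovine carbonic
#: anhydrase II, ~29 kDa); synthetic anchor, only mass differences matter
BCA_REFERENCE_MASS = 29089.0
#: exchangeable backbone amides assumed for the protein (residues minus
#: N-terminus and prolines); synthetic default
BCA_N_AMIDES = 240


@dataclass(frozen=True)
class LigandSpec:
    """One member of the benzenesulfonamide-oligoglycine ligand series."""

    name: str
    formula: str
    n_subunits: int
    molecular_weight: float  # neutral, average, g/mol

    @property
    def mz_deprotonated(self) -> float:
        return deprotonated_mz(self.formula)


@dataclass
class SimulationConfig:
    """Shared knobs for the generators; the seed is mandatory."""

    seed: int
    noise_fraction: float = 0.02
    delay_preset_T1: str = "bound-T1"
    delay_preset_T2: str = "bound-T2"

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _glycine_formula(n: int) -> str:
    # benzenesulfonamide core C7H7NO4S plus n glycine residues (C2H3NO),
    # the first carrying the 15N label
    return f"C{7 + 2 * n}H{7 + 3 * n}N{n}[15N]O{n + 4}S"


def ligand_catalog() -> list[LigandSpec]:
    """The six ligands: SA-OH plus SA-Gly1..SA-Gly5 (15N at Gly 1)."""
    specs = [LigandSpec("SA-OH", "C7H7NO4S", 0,
                        round(average_mass("C7H7NO4S"), 2))]
    for n in range(1, 6):
        f = _glycine_formula(n)
        specs.append(LigandSpec(f"SA-Gly{n}", f, n, round(average_mass(f), 2)))
    return specs


# ---------------------------------------------------------------------------
# relaxation


@dataclass
class RelaxationExperiment:
    """Synthetic raw data for one site: decays plus NOE intensity pairs."""

    t1_series: DecaySeries
    t2_series: DecaySeries
    t1rho_series: DecaySeries
    noe_pairs: list[tuple[float, float]]  # (I_sat, I_ref) replicates
    recycle_delay: float
    field_1H: float
    site_id: str


def simulate_relaxation_dataset(
    p: ModelFreeParams,
    constants: SpinConstants,
    cfg: SimulationConfig,
    i0: float = 1000.0,
    recycle_delay: float = 3.0,
    rex_suppression: float = 1.0,
    site_id: str = "",
) -> RelaxationExperiment:
    """Emit decay series and NOE pairs back-calculated from the model.

    T1rho decays at R2 - rex_suppression * R_ex: by default the spin
    lock fully suppresses slow exchange, so T1rho ~ T2 exactly when
    R_ex = 0 and exceeds it otherwise.  Duplicate intensities are
    recorded at three delays of each schedule.  Noise is multiplicative
    Gaussian at cfg.noise_fraction.
    """
    if not 0.0 <= rex_suppression <= 1.0:
        raise ValueError("rex_suppression must lie in [0, 1]")
    rng = cfg.rng()
    pred = relaxation_observables(p, constants)
    times = {
        "T1": (cfg.delay_preset_T1, 1.0 / pred.R1),
        "T2": (cfg.delay_preset_T2, 1.0 / pred.R2),
        "T1rho": (cfg.delay_preset_T2,
                  1.0 / (pred.R2 - rex_suppression * p.R_ex)),
    }
    series: dict[str, DecaySeries] = {}
    for name, (preset, t_true) in times.items():
        delays = np.array(DELAY_PRESETS[preset])
        clean = i0 * np.exp(-delays / t_true)
        noisy = clean * (1.0 + rng.normal(0.0, cfg.noise_fraction, clean.shape))
        dup_idx = [1, len(delays) // 2, len(delays) - 2]
        dups = [
            (float(delays[j]),
             float(clean[j] * (1.0 + rng.normal(0.0, cfg.noise_fraction))))
            for j in dup_idx
        ]
        sigma = (cfg.noise_fraction * clean if cfg.noise_fraction > 0 else None)
        series[name] = DecaySeries(delays, noisy, sigma=sigma, duplicates=dups,
                                   site_id=site_id, experiment=name)
    f_corr = 1.0 - math.exp(-recycle_delay * pred.R1)
    pairs = []
    for _ in range(2):
        i_ref = i0 * (1.0 + rng.normal(0.0, cfg.noise_fraction))
        i_sat = (i0 * pred.NOE / f_corr) \
            * (1.0 + rng.normal(0.0, cfg.noise_fraction))
        pairs.append((float(i_sat), float(i_ref)))
    return RelaxationExperiment(
        t1_series=series["T1"], t2_series=series["T2"],
        t1rho_series=series["T1rho"], noe_pairs=pairs,
        recycle_delay=recycle_delay, field_1H=constants.field_1H,
        site_id=site_id,
    )


def measure_relaxation(exp: RelaxationExperiment) -> RelaxationSet:
    """Reduce a synthetic experiment to an observed RelaxationSet.

    Decays are fit per `decay.fit_exponential_decay`; the NOE comes from
    each saturated/reference pair corrected with the fitted T1, with the
    replicate half-range as its uncertainty.  Sigma floors keep the set
    valid for noiseless input.
    """
    fits = {name: fit_exponential_decay(getattr(exp, attr))
            for name, attr in (("T1", "t1_series"), ("T2", "t2_series"),
                               ("T1rho", "t1rho_series"))}
    for name, f in fits.items():
        if not f.success:
            raise RuntimeError(f"{name} decay fit failed")
    noes = [noe_from_ratio(i_sat, i_ref, fits["T1"].T, exp.recycle_delay)
            for i_sat, i_ref in exp.noe_pairs]
    noe = float(np.mean(noes))
    sigma_noe = max(0.5 * abs(noes[0] - noes[-1]), 1e-6) \
        if len(noes) > 1 else 0.05

    def sig(f):
        return max(f.sigma_T, 1e-6 * f.T)

    return RelaxationSet(
        T1=fits["T1"].T, sigma_T1=sig(fits["T1"]),
        T2=fits["T2"].T, sigma_T2=sig(fits["T2"]),
        NOE=noe, sigma_NOE=sigma_noe,
        T1rho=fits["T1rho"].T, sigma_T1rho=sig(fits["T1rho"]),
        field_1H=exp.field_1H, site_id=exp.site_id,
    )


# ---------------------------------------------------------------------------
# diffusion


def simulate_dosy(
    species: list[tuple[float, float]],
    geometry: GradientGeometry,
    cfg: SimulationConfig,
    exchange: str = "fast",
    i0: float = 1000.0,
    peak_id: str = "",
) -> AttenuationCurve:
    """Attenuation curve for a mixture of (population, D) species.

    Fast exchange on the NMR time scale averages to a mono-exponential
    at the population-weighted D; slow exchange sums the component
    attenuations.  Populations must sum to 1.
    """
    pops = np.array([s[0] for s in species], dtype=float)
    ds = np.array([s[1] for s in species], dtype=float)
    if abs(pops.sum() - 1.0) > 1e-6:
        raise ValueError("species populations must sum to 1")
    if np.any(ds <= 0):
        raise ValueError("diffusion coefficients must be positive")
    b = b_factor(np.asarray(geometry.fractions), geometry)
    if exchange == "fast":
        clean = i0 * np.exp(-float(pops @ ds) * b)
    elif exchange == "slow":
        clean = i0 * (pops[:, None] * np.exp(-np.outer(ds, b))).sum(axis=0)
    else:
        raise ValueError(f"unknown exchange mode {exchange!r}")
    rng = cfg.rng()
    noisy = clean * (1.0 + rng.normal(0.0, cfg.noise_fraction, clean.shape))
    return AttenuationCurve(geometry=geometry,
                            intensities=np.clip(noisy, 0.0, None),
                            peak_id=peak_id)


def dimer_fraction(c_total: float, kd: float) -> float:
    """Fraction of molecules in the dimer for 2 M <-> M2 at equilibrium.

    Kd = [M]^2 / [M2]; closed form from the quadratic in free monomer.
    """
    if c_total <= 0 or kd <= 0:
        raise ValueError("concentrations must be positive")
    m_free = (-kd + math.sqrt(kd * kd + 8.0 * kd * c_total)) / 4.0
    return 1.0 - m_free / c_total


def dimerizing_diffusion(
    m_solute: float, kd: float, c_total: float = LIGAND_CONCENTRATION
) -> float:
    """Population-weighted D under fast monomer-dimer exchange.

    The dimer diffuses as a particle of twice the mass (D ~ M^-0.6).
    """
    f_dim = dimer_fraction(c_total, kd)
    d_mono = wilke_chang_diffusion(m_solute)
    d_dim = wilke_chang_diffusion(2.0 * m_solute)
    return (1.0 - f_dim) * d_mono + f_dim * d_dim


# ---------------------------------------------------------------------------
# hydrogen/deuterium exchange


def bimodal_rate_profile(
    n_amides: int = BCA_N_AMIDES,
    uptake_short: float = 75.0,
    uptake_long: float = 96.0,
    t_short: float = 3.0,
    t_long: float = 120.0,
    k_fast: float = 2.0,
) -> np.ndarray:
    """Per-amide exchange rates (1/min) hitting two uptake anchors.

    A fast surface shell exchanges at ``k_fast`` and a slow core at a
    rate solved (with the shell size) so that expected uptake equals
    ``uptake_short`` at ``t_short`` and ``uptake_long`` at ``t_long``.
    Solved at call time rather than hard-coded.
    """
    if not 0 < uptake_short < uptake_long < n_amides:
        raise ValueError("need 0 < uptake_short < uptake_long < n_amides")
    f1 = 1.0 - math.exp(-k_fast * t_short)
    f2 = 1.0 - math.exp(-k_fast * t_long)

    def n_fast_for(k_slow: float) -> float:
        g1 = 1.0 - math.exp(-k_slow * t_short)
        return (uptake_short - n_amides * g1) / (f1 - g1)

    def mismatch(k_slow: float) -> float:
        g2 = 1.0 - math.exp(-k_slow * t_long)
        nf = n_fast_for(k_slow)
        return nf * f2 + (n_amides - nf) * g2 - uptake_long

    k_slow = brentq(mismatch, 1e-8, k_fast / 2.0, xtol=1e-14)
    n_fast = int(round(n_fast_for(k_slow)))
    rates = np.full(n_amides, k_slow)
    rates[:n_fast] = k_fast
    return rates


def expected_uptake(rates: np.ndarray, t: float) -> float:
    """EX2 expected deuterons at exposure time t (min): sum 1 - e^-kt."""
    return float(np.sum(1.0 - np.exp(-np.asarray(rates) * t)))


def simulate_hdx(
    n_amides: int,
    rates: np.ndarray,
    times,
    back_ex: float,
    cfg: SimulationConfig,
    condition: str = "apo",
    reference_mass: float = BCA_REFERENCE_MASS,
    n_replicates: int = 5,
    replicate_sd: float = 1.5,
) -> list[HdxRecord]:
    """Replicate observed masses for one condition at each exposure time.

    observed = reference + U(t) * (m2H - m1H) * (1 - back_ex) + noise,
    with U(t) the EX2 expected uptake; >= 5 replicates per condition.
    A perdeuterated control consistent with ``back_ex`` is attached.
    """
    rates = np.asarray(rates, dtype=float)
    if len(rates) != n_amides:
        raise ValueError("rates must have one entry per amide")
    if not 0.0 <= back_ex < 1.0:
        raise ValueError("back_ex must lie in [0, 1)")
    if n_replicates < 5:
        raise ValueError("protocol requires at least five replicates")
    rng = cfg.rng()
    theory = (reference_mass
              + PERDEUTERATION_FRACTION * n_amides * DELTA_MASS_D_H)
    perdeut_obs = theory - back_ex * (theory - reference_mass)
    records = []
    for t in np.atleast_1d(times):
        u = expected_uptake(rates, float(t))
        mean_mass = reference_mass + u * DELTA_MASS_D_H * (1.0 - back_ex)
        masses = mean_mass + rng.normal(0.0, replicate_sd, n_replicates)
        records.append(HdxRecord(
            condition=condition, time_in_D2O=float(t),
            replicate_masses=masses, reference_mass_H=reference_mass,
            perdeuterated_mass_obs=perdeut_obs,
        ))
    return records


def ligand_series_hdx_profiles(
    n_amides: int = BCA_N_AMIDES,
    n_protected: int = 8,
    core_stabilization: float = 0.6,
    chain_destabilization: float = 1.15,
) -> dict[str, np.ndarray]:
    """Per-condition rate profiles emulating the ligand series.

    Any bound ligand buries ``n_protected`` fast-shell amides, which
    then exchange at the slow-core rate (visible as fewer deuterons at
    short times).  The benzenesulfonamide moiety itself stabilizes the
    slow core (rates scaled by ``core_stabilization``), while each
    glycine subunit destabilizes it by ``chain_destabilization`` --
    visible as a chain-length trend at long times.  These modulations
    are illustrative of the trend under study, not fitted to data.
    """
    base = bimodal_rate_profile(n_amides)
    k_fast = base.max()
    k_slow = base.min()
    profiles = {"apo": base}
    for name, n in [("SA-OH", 0)] + [(f"SA-Gly{k}", k) for k in range(1, 6)]:
        rates = base.copy()
        fast_idx = np.nonzero(rates == k_fast)[0]
        rates[fast_idx[-n_protected:]] = k_slow
        slow = rates == k_slow
        rates[slow] *= core_stabilization * chain_destabilization**n
        profiles[name] = rates
    return profiles
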