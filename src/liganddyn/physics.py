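"""Forward model: extended model-free dynamics to predicted 15N relaxation.

The amide 15N of a ligand rigidly attached to a slowly tumbling protein
relaxes through the 1H-15N dipolar interaction and the 15N chemical-shift
anisotropy (CSA).  Internal motion of the N-H bond vector is described by
the extended model-free parameterization: a generalized order parameter
S2 = Sf2 * Ss2 factored into fast (Sf2) and slow (Ss2) contributions, an
effective internal correlation time tau_e for the slow internal motion
(the fast internal correlation time is taken to zero), and an exchange
broadening term R_ex added to the transverse rate.  The overall tumbling
time tau_m is treated as known and isotropic.

All frequencies are angular (rad/s); times are seconds; rates are 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

# CODATA-style defaults; overridable per SpinConstants instance.
MU0_OVER_4PI = 1.0e-7          # T m / A
HBAR = 1.054571817e-34         # J s
GAMMA_H = 2.6752218744e8       # rad/s/T, 1H
GAMMA_N = -2.7126e7            # rad/s/T, 15N (negative)
R_NH = 1.02e-10                # m, amide N-H bond length
CSA_N = -160.0                 # ppm, 15N chemical-shift anisotropy

#: number of free parameters per model-free model
MODEL_FREE_PARAMETERS: dict[int, tuple[str, ...]] = {
    1: ("s2",),
    2: ("s2", "tau_e"),
    3: ("s2", "rex"),
    4: ("s2", "tau_e", "rex"),
    5: ("sf2", "ss2", "tau_e"),
}


@dataclass(frozen=True)
class SpinConstants:
    """Spin-pair constants needed to map J(omega) to relaxation rates.

    field_1H is the proton Larmor frequency of the spectrometer in MHz
    (600 for the instrument used for the bound-ligand experiments).
    """

    field_1H: float = 600.0
    gamma_H: float = GAMMA_H
    gamma_N: float = GAMMA_N
    r_NH: float = R_NH
    delta_sigma_N: float = CSA_N

    def __post_init__(self) -> None:
        if not self.field_1H >= 0:
            raise ValueError(f"field_1H must be non-negative, got {self.field_1H}")
        if not self.gamma_H > 0:
            raise ValueError("gamma_H must be positive")
        if not self.gamma_N < 0:
            raise ValueError("gamma_N must be negative (15N)")
        if not self.r_NH > 0:
            raise ValueError("r_NH must be positive")


def larmor_frequencies(constants: SpinConstants) -> tuple[float, float]:
    """Angular Larmor frequencies (omega_H, omega_N) in rad/s.

    omega_N carries the sign of gamma_N (negative), so the combination
    frequency omega_H - omega_N exceeds omega_H.
    """
    if constants.field_1H < 0:
        raise ValueError("field_1H must be non-negative")
    omega_h = 2.0 * math.pi * constants.field_1H * 1.0e6
    omega_n = omega_h * (constants.gamma_N / constants.gamma_H)
    return omega_h, omega_n


@dataclass(frozen=True)
class ModelFreeParams:
    """Extended model-free parameter set for one N-H bond vector.

    S2 is always the product Sf2 * Ss2 (exposed as a property).  The five
    standard models constrain subsets of the parameters:

    ========  ======================  ====
    model     free parameters         k
    ========  ======================  ====
    1         S2                      1
    2         S2, tau_e               2
    3         S2, R_ex                2
    4         S2, tau_e, R_ex         3
    5         Sf2, Ss2, tau_e         3
    ========  ======================  ====

    Models 1-4 have Sf2 = 1 (so S2 = Ss2); models 1 and 3 additionally
    fix tau_e = 0; R_ex = 0 except in models 3 and 4.
    """

    model_id: int
    tau_m: float
    Sf2: float = 1.0
    Ss2: float = 1.0
    tau_e: float = 0.0
    R_ex: float = 0.0

    @property
    def S2(self) -> float:
        return self.Sf2 * self.Ss2

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_FREE_PARAMETERS:
            raise ValueError(f"model_id must be 1..5, got {self.model_id}")
        for name in ("Sf2", "Ss2", "tau_e", "R_ex", "tau_m"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if not 0.0 <= self.Sf2 <= 1.0 or not 0.0 <= self.Ss2 <= 1.0:
            raise ValueError("order parameters must lie in [0, 1]")
        if self.tau_e < 0:
            raise ValueError("tau_e must be >= 0")
        if self.R_ex < 0:
            raise ValueError("R_ex must be >= 0")
        if not self.tau_m > 0:
            raise ValueError("tau_m must be > 0")
        self._check_model_constraints()

    def _check_model_constraints(self) -> None:
        m = self.model_id
        if m in (1, 2, 3, 4) and self.Sf2 != 1.0:
            raise ValueError(f"model {m} requires Sf2 = 1")
        if m in (1, 3) and self.tau_e != 0.0:
            raise ValueError(f"model {m} requires tau_e = 0")
        if m in (1, 2, 5) and self.R_ex != 0.0:
            raise ValueError(f"model {m} requires R_ex = 0")

    def with_free(self, **free: float) -> "ModelFreeParams":
        """Return a copy with the given free parameters replaced.

        Keys are the lower-case names in MODEL_FREE_PARAMETERS (s2 maps
        onto Ss2 for models 1-4).
        """
        allowed = MODEL_FREE_PARAMETERS[self.model_id]
        updates: dict[str, float] = {}
        for name, value in free.items():
            if name not in allowed:
                raise ValueError(
                    f"parameter {name!r} is not free in model {self.model_id}"
                )
            key = {"s2": "Ss2", "sf2": "Sf2", "ss2": "Ss2",
                   "tau_e": "tau_e", "rex": "R_ex"}[name]
            updates[key] = value
        return replace(self, **updates)


def make_params(model_id: int, tau_m: float, **free: float) -> ModelFreeParams:
    """Build a ModelFreeParams from the free parameters of a model.

    ``make_params(2, 11.5e-9, s2=0.72, tau_e=510e-12)`` fills the
    constrained parameters (Sf2 = 1, R_ex = 0) automatically.
    """
    base = ModelFreeParams(model_id=model_id, tau_m=tau_m)
    return base.with_free(**free)


def spectral_density(omega, p: ModelFreeParams):
    """Extended model-free spectral density J(omega) in s/rad.

    J(w) = (2/5) [ S2 tau_m / (1 + (w tau_m)^2)
                   + (Sf2 - S2) tau' / (1 + (w tau')^2) ],
    with 1/tau' = 1/tau_m + 1/tau_e and the fast internal correlation
    time taken to zero.  When tau_e = 0 the second Lorentzian vanishes.
    J is even in omega; negative inputs are evaluated at |omega|.
    """
    w = np.abs(np.asarray(omega, dtype=float))
    if not np.all(np.isfinite(w)):
        raise ValueError("omega must be finite")
    s2 = p.S2
    j = s2 * p.tau_m / (1.0 + (w * p.tau_m) ** 2)
    if p.tau_e > 0.0:
        tau_p = p.tau_m * p.tau_e / (p.tau_m + p.tau_e)
        j = j + (p.Sf2 - s2) * tau_p / (1.0 + (w * tau_p) ** 2)
    j = 0.4 * j
    return float(j) if np.isscalar(omega) or np.ndim(omega) == 0 else j


@dataclass(frozen=True)
class RelaxationPrediction:
    """Predicted relaxation observables for one site."""

    R1: float
    R2: float
    NOE: float

    @property
    def T1(self) -> float:
        return 1.0 / self.R1

    @property
    def T2(self) -> float:
        return 1.0 / self.R2

    def __post_init__(self) -> None:
        if not self.R1 > 0 or not self.R2 > 0:
            raise ValueError("relaxation rates must be positive")


def dipolar_constant(c: SpinConstants) -> float:
    """Dipolar coupling constant d = (mu0/4pi) hbar gH gN / r^3 (rad/s).

    Negative for 15N; only d^2 enters the rate expressions.
    """
    return MU0_OVER_4PI * HBAR * c.gamma_H * c.gamma_N / c.r_NH**3


def relaxation_observables(
    p: ModelFreeParams, c: SpinConstants
) -> RelaxationPrediction:
    """Predict (R1, R2, NOE) from model-free parameters at a stated field.

    Standard 15N dipolar + CSA expressions:

    R1  = (d^2/4) [J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + c^2 J(wN)
    R2  = (d^2/8) [4 J(0) + J(wH-wN) + 3 J(wN) + 6 J(wH) + 6 J(wH+wN)]
          + (c^2/6) [4 J(0) + 3 J(wN)] + R_ex
    NOE = 1 + (gH/gN) (d^2/4) (1/R1) [6 J(wH+wN) - J(wH-wN)]

    with d the dipolar constant and c = wN * delta_sigma * 1e-6 / sqrt(3).
    """
    wh, wn = larmor_frequencies(c)
    d2 = dipolar_constant(c) ** 2
    csa = wn * c.delta_sigma_N * 1.0e-6 / math.sqrt(3.0)
    c2 = csa * csa

    j0 = spectral_density(0.0, p)
    jwn = spectral_density(wn, p)
    jwh = spectral_density(wh, p)
    jdiff = spectral_density(wh - wn, p)
    jsum = spectral_density(wh + wn, p)

    r1 = (d2 / 4.0) * (jdiff + 3.0 * jwn + 6.0 * jsum) + c2 * jwn
    r2 = (
        (d2 / 8.0) * (4.0 * j0 + jdiff + 3.0 * jwn + 6.0 * jwh + 6.0 * jsum)
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jwn)
        + p.R_ex
    )
    noe = 1.0 + (c.gamma_H / c.gamma_N) * (d2 / 4.0) * (6.0 * jsum - jdiff) / r1
    return RelaxationPrediction(R1=r1, R2=r2, NOE=noe)
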