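"""Run configuration: defaults for every stage, YAML-overridable."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .dosy import GradientGeometry, WilkeChangConstants
from .physics import SpinConstants


@dataclass
class RunConfig:
    """Everything the pipeline needs that is not data.

    Defaults are the stated experimental conditions: 600 MHz field,
    tau_m = 11.5 ns, 3 s recycle delay, the published gradient geometry,
    water Wilke-Chang constants, 90% perdeuteration assumption and 35%
    back-exchange, seed 0.
    """

    field_1H: float = 600.0
    gamma_H: float = SpinConstants().gamma_H
    gamma_N: float = SpinConstants().gamma_N
    r_NH: float = SpinConstants().r_NH
    delta_sigma_N: float = SpinConstants().delta_sigma_N
    tau_m_ns: float = 11.5
    recycle_delay_s: float = 3.0
    chi2_space: str = "rate"
    mc_draws: int = 500

    dosy_big_delta_s: float = 0.100
    dosy_little_delta_s: float = 0.0025
    dosy_g_max_T_per_m: float = 0.535

    wc_prefactor: float = 7.4e-8
    wc_x: float = 2.26
    wc_M_solvent: float = 18.0
    wc_eta_cP: float = 0.8899
    wc_T_K: float = 300.0
    wc_rho: float = 1.0

    hdx_back_exchange: float = 0.35
    hdx_n_amides: int = 240
    hdx_perdeuteration: float = 0.90

    seed: int = 0
    output_dir: str = "results"

    def spin_constants(self) -> SpinConstants:
        return SpinConstants(field_1H=self.field_1H, gamma_H=self.gamma_H,
                             gamma_N=self.gamma_N, r_NH=self.r_NH,
                             delta_sigma_N=self.delta_sigma_N)

    @property
    def tau_m(self) -> float:
        return self.tau_m_ns * 1e-9

    def gradient_geometry(self, fractions=None) -> GradientGeometry:
        kwargs = dict(big_delta=self.dosy_big_delta_s,
                      little_delta=self.dosy_little_delta_s,
                      g_max=self.dosy_g_max_T_per_m)
        if fractions is not None:
            kwargs["fractions"] = tuple(fractions)
        return GradientGeometry(**kwargs)

    def wilke_chang(self) -> WilkeChangConstants:
        return WilkeChangConstants(prefactor=self.wc_prefactor, x=self.wc_x,
                                   M_solvent=self.wc_M_solvent,
                                   eta=self.wc_eta_cP, T=self.wc_T_K,
                                   rho=self.wc_rho)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
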