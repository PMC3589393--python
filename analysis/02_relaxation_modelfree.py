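"""Relaxation pipeline: synthetic decays -> T1/T2/NOE -> model selection.

For each ligand in the series the accepted extended model-free
parameter set is used to back-calculate relaxation observables at
600 MHz (tau_m = 11.5 ns), synthetic HSQC decay series with 2%
multiplicative noise are generated, reduced to (T1, T2, T1rho, NOE),
and all five model-free models are refit with AIC selection and Monte
Carlo uncertainties.  The one-glycine ligand is generated with an
exchange term whose spin-lock signature is absent (T1rho ~ T2), so the
selection stage demonstrates the exchange override: the AIC may prefer
a model with Rex, but the rotating-frame data veto it.

Writes results/modelfree_table.csv (a Table-1-style summary).
"""

from pathlib import Path

import pandas as pd

from liganddyn import SpinConstants, analyze_site, make_params
from liganddyn.simulate import (SimulationConfig, measure_relaxation,
                                simulate_relaxation_dataset)

OUT = Path(__file__).resolve().parents[1] / "results"
TAU_M = 11.5e-9
SEED = 2013

#: accepted per-ligand generating parameters (model, free params)
GENERATING = {
    "SA-Gly1": dict(model=4, s2=0.35, tau_e=123e-12, rex=2.3),
    "SA-Gly2": dict(model=2, s2=0.72, tau_e=510e-12),
    "SA-Gly3": dict(model=5, sf2=0.92, ss2=0.79, tau_e=490e-12),
    "SA-Gly4": dict(model=5, sf2=0.95, ss2=0.76, tau_e=750e-12),
    "SA-Gly5": dict(model=5, sf2=0.96, ss2=0.78, tau_e=670e-12),
}


def main() -> None:
    constants = SpinConstants(field_1H=600.0)
    rows = []
    for j, (name, g) in enumerate(GENERATING.items()):
        free = {k: v for k, v in g.items() if k != "model"}
        params = make_params(g["model"], TAU_M, **free)
        # the exchange term in the SA-Gly1 generator is an apparent one:
        # the spin lock does not relieve it (suppression 0 => T1rho ~ T2)
        suppression = 0.0 if name == "SA-Gly1" else 1.0
        cfg = SimulationConfig(seed=SEED + j, noise_fraction=0.02)
        exp = simulate_relaxation_dataset(params, constants, cfg,
                                          rex_suppression=suppression,
                                          site_id=name)
        observed = measure_relaxation(exp)
        result = analyze_site(observed, TAU_M, constants,
                              mc_draws=500, seed=SEED + j)
        p = result.chosen.params
        sig = result.chosen.param_sigmas or {}
        rows.append({
            "ligand": name,
            "true_model": g["model"],
            "chosen_model": p.model_id,
            "S2": round(p.S2, 2),
            "sigma_S2": round(sig.get("s2", sig.get("ss2", float("nan"))), 2),
            "Sf2": round(p.Sf2, 2),
            "Ss2": round(p.Ss2, 2),
            "tau_e_ps": int(round(p.tau_e * 1e12)),
            "Rex_per_s": round(p.R_ex, 1),
            "AIC": round(result.chosen.aic, 1),
            "T1rho_T2_ratio": round(result.t1rho_t2_ratio, 3),
            "rex_override": result.rex_override_applied,
        })
        print(f"{name}: chose model {p.model_id} "
              f"(S2 = {p.S2:.2f}, AIC = {result.chosen.aic:.1f}, "
              f"override = {result.rex_override_applied})")
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "modelfree_table.csv", index=False)
    print("\n" + frame.to_string(index=False))
    print("\nThe order parameter jumps from ~0.4 at one glycine to a "
          "plateau of 0.7-0.8 at two or more, i.e. the first subunit is "
          "rigidly bound whenever at least one distal subunit exists.")


if __name__ == "__main__":
    main()
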