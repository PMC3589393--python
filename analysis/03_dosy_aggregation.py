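"""Diffusion analysis: attenuation fits and the aggregation test.

Synthetic stimulated-echo curves are generated for the five SA-Gly
ligands under two scenarios -- pure monomers diffusing per the
Wilke-Chang correlation, and a fast-exchange monomer/dimer equilibrium
whose dimer fraction grows with chain length -- each with 2%
multiplicative noise.  Fitted D values are regressed on molecular
weight in log-log space: monomers give slope -0.6 at the theoretical
intercept, the dimerizing series a visibly steeper slope.

Writes results/dosy_aggregation.json.
"""

import json
from pathlib import Path

from liganddyn import GradientGeometry, aggregation_test, fit_attenuation
from liganddyn.simulate import (SimulationConfig, dimerizing_diffusion,
                                ligand_catalog, simulate_dosy,
                                wilke_chang_diffusion)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 415


def run_scenario(name: str, d_of_mass, seed: int) -> dict:
    geometry = GradientGeometry()
    ligands = [s for s in ligand_catalog() if s.n_subunits > 0]
    fitted, masses = [], []
    for j, spec in enumerate(ligands):
        cfg = SimulationConfig(seed=seed + j, noise_fraction=0.02)
        curve = simulate_dosy([(1.0, d_of_mass(spec))], geometry, cfg,
                              peak_id=spec.name)
        fit = fit_attenuation(curve)
        if fit.collapsed_D is not None:
            d = fit.collapsed_D
        else:  # amplitude-weighted single value, as a DOSY trace reports
            total = sum(a for a, _ in fit.components)
            d = sum(a * dd for a, dd in fit.components) / total
        fitted.append(d)
        masses.append(spec.molecular_weight)
    res = aggregation_test(fitted, masses)
    print(f"{name}: slope {res.slope:.3f} +/- {res.sigma_slope:.3f}, "
          f"intercept {res.intercept:.2f}, R^2 {res.r_squared:.4f} "
          f"-> {res.verdict}")
    return {
        "D_m2_per_s": dict(zip([s.name for s in ligands], fitted)),
        "slope": res.slope, "sigma_slope": res.sigma_slope,
        "intercept": res.intercept, "sigma_intercept": res.sigma_intercept,
        "r_squared": res.r_squared, "theory_slope": res.theory_slope,
        "theory_intercept": res.theory_intercept, "verdict": res.verdict,
    }


def main() -> None:
    payload = {
        "monomer": run_scenario(
            "monomer", lambda s: wilke_chang_diffusion(s.molecular_weight),
            SEED),
        # Kd tightening tenfold per subunit drives the dimer fraction from
        # ~9% (n = 1) to ~94% (n = 5) at 0.5 mM total ligand
        "dimerizing": run_scenario(
            "dimerizing",
            lambda s: dimerizing_diffusion(s.molecular_weight,
                                           kd=0.1 * 0.1**s.n_subunits),
            SEED + 100),
    }
    OUT.mkdir(exist_ok=True)
    with open(OUT / "dosy_aggregation.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print("\nA monomeric series tracks the Wilke-Chang line (slope -0.6); "
          "mass-dependent dimerization steepens the slope, which is what "
          "the aggregation test flags.")


if __name__ == "__main__":
    main()
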