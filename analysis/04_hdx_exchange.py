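"""Global H/D-exchange analysis of the synthetic ligand series.

EX2 uptake records are generated for the protein alone, with the
benzenesulfonamide control (SA-OH), and with each SA-Gly ligand, at
3 min and 120 min in D2O (five replicates each, 35% back-exchange).
The pipeline converts replicate masses to deuteron counts, corrects
for back-exchange, and runs the pairwise significance tests.  The apo
protein exchanges ~75 hydrogens at 3 min and ~96 at 120 min; bound
ligands protect the fast shell, while longer glycine chains
progressively destabilize the slow core.

Writes results/hdx_summary.csv and results/hdx_pairwise_p.csv.
"""

from pathlib import Path

from liganddyn.hdx import pairwise_pvalues, summarize_conditions
from liganddyn.simulate import (BCA_N_AMIDES, SimulationConfig,
                                ligand_series_hdx_profiles, simulate_hdx)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 829
BACK_EXCHANGE = 0.35


def main() -> None:
    profiles = ligand_series_hdx_profiles(BCA_N_AMIDES)
    records = []
    for j, (condition, rates) in enumerate(sorted(profiles.items())):
        cfg = SimulationConfig(seed=SEED + j)
        records.extend(simulate_hdx(BCA_N_AMIDES, rates, [3.0, 120.0],
                                    BACK_EXCHANGE, cfg, condition=condition))
    summary = summarize_conditions(records, n_amides=BCA_N_AMIDES)
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "hdx_summary.csv", index=False,
                   float_format="%.4f")
    print(summary.to_string(index=False))
    pair = pairwise_pvalues(records, 120.0)
    pair.to_csv(OUT / "hdx_pairwise_p.csv", float_format="%.4f")
    print("\npairwise p-values at 120 min:")
    print(pair.to_string(float_format=lambda v: f"{v:.3f}"))
    print("\nCorrected apo counts sit near 75 (3 min) and 96 (120 min); "
          "ligand-bound conditions exchange fewer hydrogens than apo, with "
          "counts creeping back up with glycine chain length.")


if __name__ == "__main__":
    main()
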