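# liganddyn

Quantitative analyses of ligand and protein mobility in complexes of
bovine carbonic anhydrase II (BCA) with benzenesulfonamide ligands
carrying oligoglycine chains (SA-Gly_n, n = 1-5, 15N-labeled at the first
glycine), rebuilt as a tested Python pipeline over synthetic data.  It is
aimed at biophysicists who want the number-crunching side of such a study
-- relaxation fitting, model selection, diffusion regression, exchange
counting -- as reusable, verifiable code.

Three analyses, each a module plus a driver script:

1. **15N relaxation -> extended model-free dynamics.**  HSQC peak-decay
   series give T1, T2, T1rho; the steady-state NOE comes from
   saturated/reference ratios.  The triple (T1, T2, NOE) is fit to the
   five standard model-free models built on

       J(w) = (2/5)[S2 tau_m/(1+(w tau_m)^2) + (Sf2-S2) tau'/(1+(w tau')^2)],
       S2 = Sf2 * Ss2,   1/tau' = 1/tau_m + 1/tau_e,

   with tau_m fixed at 11.5 ns and the field at 600 MHz.  Model choice is
   by AIC = chi2 + 2k; a rotating-frame check (T1rho ~ T2) vetoes spurious
   exchange (Rex) terms; uncertainties come from 500 Monte Carlo draws.
2. **DOSY diffusion -> aggregation test.**  Stimulated-echo attenuation
   curves are fit (bi-exponential with a significance-gated collapse to
   one species) and the fitted D values regressed against molecular
   weight.  The Wilke-Chang correlation predicts slope -0.6 and intercept
   -7.80 (log10 D in m^2/s) for monomers; steeper slopes flag
   mass-dependent aggregation.
3. **HDX-MS -> deuteron counts.**  Intact-protein mass shifts in D2O
   divided by m(2H)-m(1H) count exchanged hydrogens; a perdeuterated
   control calibrates the 35% back-exchange correction; pooled-variance
   t-tests compare conditions.  A formula engine with explicit isotope
   labels ("C9H9N[15N]O5S") supplies the ligand ion masses.

A synthetic-data module (`liganddyn.simulate`) generates every input the
pipeline consumes -- the ligand catalog, decay series, attenuation curves,
EX2 uptake records -- so the whole artifact runs and is tested offline.

## Worked example

Fit the accepted model for the two-glycine ligand from its own noiseless
forward calculation, end to end through the CLI:

```sh
liganddyn simulate relax --model 2 --s2 0.72 --tau-e-ps 510 --noise 0 \
    --out decays.csv
liganddyn relax-fit decays.csv --out fits.csv
```

`fits.csv` contains the fitted relaxation times (values in seconds):

    site_id,experiment,value,...
    model2,T1,0.7950351697254439,...
    model2,T1rho,0.08171806981030352,...
    model2,T2,0.08171806981030352,...
    model2,NOE,0.09526669129453656,...

i.e. T1 = 0.795 s, T2 = 81.7 ms (T1rho identical -- no slow exchange), and
a weak positive NOE of 0.095, the slow-tumbling signature of a small
ligand rigidly carried by a 29 kDa protein.  Feeding the triple to the
model-free stage (`liganddyn modelfree relax.csv --out report.json`)
returns

    "model": 2, "S2": 0.72, "tau_e_ps": 510, "Rex_per_s": 0.0, "aic": 4.0

recovering the generating order parameter S2 = 0.72 (the first glycine
subunit is tightly held in the active site) and internal correlation time
510 ps exactly; AIC = chi2 + 2k = 4.0 for this exactly-fitting
two-parameter model.  The analysis drivers run the same machinery across
the whole ligand series:

```sh
python analysis/01_ligand_masses.py       # catalog + (M-H)- masses
python analysis/02_relaxation_modelfree.py  # Table-style model-free summary
python analysis/03_dosy_aggregation.py    # monomer vs dimerizing scenarios
python analysis/04_hdx_exchange.py        # deuteron counts + t-tests
```

writing their tables under `results/`.  For instance the monomer DOSY
scenario prints

    monomer: slope -0.599 +/- 0.007, intercept -7.80, R^2 0.9995 -> monomer

and the mass table gives the deprotonated-ion monoisotopic masses
258.0208, 315.0423, 372.0637, 429.0852, 486.1067 Da for SA-Gly1..5.

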