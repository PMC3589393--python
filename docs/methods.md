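# Methods

This package reimplements, as a tested pipeline over synthetic data, the
three quantitative analyses used to dissect ligand and protein mobility in
complexes of bovine carbonic anhydrase II (BCA) with para-substituted
benzenesulfonamide ligands carrying oligoglycine chains (SA-Gly_n, n = 1-5,
15N-labeled at the first glycine): 15N spin relaxation interpreted through
the extended model-free formalism with AIC model selection; translational
diffusion against the Wilke-Chang correlation as an aggregation test; and
global hydrogen/deuterium-exchange mass spectrometry as a protein-mobility
probe.

## Relaxation forward model (`physics`)

The amide 15N relaxes through the 1H-15N dipolar coupling and the 15N CSA.
With the extended model-free spectral density

    J(w) = (2/5) [ S2 tau_m / (1 + (w tau_m)^2)
                 + (Sf2 - S2) tau' / (1 + (w tau')^2) ],
    1/tau' = 1/tau_m + 1/tau_e,   S2 = Sf2 * Ss2,

the observables are the standard combinations

    R1  = (d^2/4)[J(wH-wN) + 3J(wN) + 6J(wH+wN)] + c^2 J(wN)
    R2  = (d^2/8)[4J(0) + J(wH-wN) + 3J(wN) + 6J(wH) + 6J(wH+wN)]
          + (c^2/6)[4J(0) + 3J(wN)] + Rex
    NOE = 1 + (gH/gN)(d^2/4)(1/R1)[6J(wH+wN) - J(wH-wN)]

with d = (mu0/4pi) hbar gH gN / r^3 and c = wN * dsigma / sqrt(3).  The
fast internal correlation time is taken to zero, the convention of the
model-free software lineage this mirrors; models 1-4 are then exact special
cases of the two-Lorentzian form (model 5), which a test verifies bitwise.
J is even; combination frequencies use the signed (negative) 15N Larmor
frequency, so wH - wN > wH.

Constants (all overridable): gH = 2.6752218744e8, gN = -2.7126e7 rad/s/T,
r_NH = 1.02 A, CSA = -160 ppm, field 600 MHz, tau_m = 11.5 ns.  The CSA and
bond length a given legacy analysis used are rarely recoverable; the round
trips the pipeline is validated on (simulate with these constants, refit
with the same constants) are insensitive to the exact choice.

## Decay fitting (`decay`)

Peak intensities at the shipped delay schedules (separate presets for free
and protein-bound ligands) are fit to I(t) = I0 exp(-t/T) by bounded
weighted least squares.  The initial guess is fixed (I0 = max intensity;
T = interpolated 1/e crossing), making the fit deterministic; points are
canonically sorted so permuting the input cannot change the result.  When
per-point sigmas are given the covariance is absolute and a 1000-seed test
checks 1-sigma coverage lands in 60-76%; otherwise weighting is uniform
with the scale set from duplicate-pair RMS when duplicates exist.  A
best-fit T at the 1e6 s bound is flagged as non-decaying.  Duplicate QC:
max |dI|/mean over duplicate pairs, flagged above 10%.

The steady-state NOE is the saturated/reference intensity ratio times
(1 - exp(-d/T1)) with d the 3 s recycle delay; the factor tends to 1 at
long recycle delay, so the NOE reduces to the bare ratio there.  The exact
historical form of this recovery correction is not recoverable from the
sources that describe it; this multiplicative convention is a documented
approximation.

## Model-free fitting and selection (`modelfree`)

chi2 is computed over {R1, R2, NOE} in rate space (sigma_R = sigma_T/T^2);
a `space="time"` switch compares T1/T2 directly, since which space a given
legacy analysis used is generally unstated.  Each of the five models is
minimized by multi-start bounded least squares (order parameters start on
{0.3, 0.6, 0.9}, tau_e on {10 ps, 100 ps, 1 ns}, Rex on {0, 5}/s; ties to
the earliest grid point), with box constraints S in [0,1], tau_e in
[0, tau_m], Rex in [0, 100]/s.  tau_e is optimized in ns so the optimizer
sees O(1) parameters.  AIC = chi2 + 2k; the minimum wins, AIC ties within
1e-6 going to the model with fewer parameters.  A model with three free
parameters interpolates a three-observable triple exactly, so its AIC is
2k = 6.0 by construction -- a value the tests pin down.

Rotating-frame veto: T1rho equals T2 unless exchange slower than the
spin-lock field contributes (the spin lock bounds detectable Rex from
below, here by orders of magnitude more than the fitted ~2/s).  If the AIC
picks a model with Rex while |T1rho/T2 - 1| < 0.10, the best Rex-free model
is adopted instead and flagged.  Conversely a ratio well above 1 is
positive evidence for suppressed exchange and the Rex model stands; both
directions are exercised by the generator.

Parameter uncertainties come from Monte Carlo: n = 500 Gaussian draws about
the back-calculated observables at the experimental sigmas, refit from the
solution (warm start), standard deviation per parameter; >20% refit
failures flags the result.  Seeded and reproducible.

## Diffusion and the aggregation test (`dosy`)

Stejskal-Tanner factor b = (gamma g delta)^2 (Delta - delta/3), with the
published geometry as default (Delta = 100 ms, delta = 2.5 ms, g_max =
53.5 G/cm, 16 fractions linear 2-95%); an optional tau_g field applies the
bipolar-pair correction.  Attenuation curves are fit bi-exponentially to
allow a second slowly exchanging species.  Numerical choices that matter:

* residuals are weighted for multiplicative noise (sigma_i proportional to
  intensity, floored at 2% of the first point);
* component D values are confined within a factor 20 of the log-linear
  initial estimate -- a "species" outside that range can only chase single
  noisy points;
* the split is kept only when a partial F-test (alpha = 1e-3) says the two
  extra parameters are earned; a genuine mixture (e.g. 4:1 D ratio) passes
  this overwhelmingly, while on truly mono-exponential data a chance split
  would report a badly biased weighted D;
* an accepted split still collapses to one value when the minor amplitude
  is below 5% (the major D is reported) or the two Ds are within 2 sigma_D
  of each other (amplitude-weighted D), with a 1e-3 relative floor so
  exactly coincident components collapse at zero noise.

Wilke-Chang: D[cm^2/s] = 7.4e-8 (x M_solvent)^1/2 T / (eta (M/rho)^0.6),
x = 2.26 and M_solvent = 18.0 for water, eta = 0.8899 cP at 298 K, T =
300 K, rho = 1 g/cm^3; log10 D is linear in log10 M with slope exactly
-0.6 and intercept -7.80 in m^2/s units, which the tests verify.  (The
printed viscosity figure "8.899 centipoise" is read as 0.8899 cP, the
physical value for water; only that reading reproduces the -7.80
intercept.)  The aggregation test is OLS of log10 D on log10 M; verdict
"monomer" requires slope and intercept consistent with theory within 3
standard errors plus small absolute floors (0.02 / 0.06) -- the floors
exist because noiseless input has zero standard errors and would otherwise
never pass its own theory.  A steeper-than-theory slope is the signature of
mass-dependent multimerization.

## HDX mass analysis (`masses`, `hdx`)

The formula engine parses Hill-style strings with bracketed isotope labels
("C9H9N[15N]O5S"), summing most-abundant-isotope masses (NIST table) with
explicit isotopes overriding, plus one electron mass per negative charge.
It reproduces the five published (M-H)- values of the ligand series at
4 d.p. against an independent summation oracle.

Deuteron count = (observed - reference mass)/(m2H - m1H) with the 1.006277
Da monoisotopic difference; because only mass differences enter, the
average-vs-monoisotopic convention for the ~29 kDa protein cancels.
Back-exchange is estimated from a perdeuterated control against a theory
mass assuming 90% of amides exchanged; the correction divides counts by
(1 - back-exchange), 35% being the stated value for this system.  The
number of exchangeable amides defaults to 240 (residues minus N-terminus
and prolines; a FASTA-based counter is provided since the exact value used
originally is unpublished).  Condition comparisons use two-sided
pooled-variance t-tests at alpha = 0.05 with no multiplicity correction,
matching the original analysis; figure-style stars mark significance vs
the apo protein (*) and vs the benzenesulfonamide control (**).  Raw and
corrected counts are always reported, since whether published count plots
are corrected is typically unstated.

## Synthetic data (`simulate`)

The generators emit exactly what the analyses consume, at the stated study
conditions: mono-exponential decays on the published delay schedules with
2% multiplicative noise (duplicate deviations then sit well under the 10%
QC bound) and duplicates at three delays; NOE saturated/reference pairs in
duplicate; T1rho decays at R2 minus a configurable fraction of Rex
(default 1: the spin lock fully suppresses slow exchange); stimulated-echo
curves for fast- or slow-exchange mixtures on the published gradient
schedule; and EX2 uptake, U(t) = sum_i (1 - exp(-k_i t)), with replicate
masses at >= 5 per condition and 1.5 Da replicate noise (SEMs of ~0.7 Da,
the scale of published error bars).

The bimodal HDX rate profile is solved at call time (brentq), not
hard-coded: a fast shell at k_fast = 2/min and a slow core whose size and
rate hit the two uptake anchors ~75 deuterons at 3 min and ~96 at 120 min.
The ligand-series profiles are illustrative of the mechanism under study:
binding buries 8 shell amides (fewer deuterons at short times), the
benzenesulfonamide core stabilizes the slow core (rates x 0.6), and each
glycine destabilizes it (x 1.15 per subunit), producing the short-time
protection and the long-time chain-length trend.  The monomer/dimer
diffusion scenario treats the dimer as a particle of twice the mass
(D ~ M^-0.6) under fast exchange, with the dimer fraction in closed form
from Kd and the 0.5 mM total concentration.

What the generators do *not* emulate: raw FIDs, phasing or peak picking;
isotope envelopes (only average masses with Gaussian replicate noise);
EX1 behavior or correlated exchange; gradient nonlinearity or convection.
Passing tests therefore validate the estimators against their own
statistical assumptions, not against spectrometer artifacts.

## Problem sizes

Defaults keep the full suite and the acceptance script in the minutes
range on one core: 500 Monte Carlo draws per chosen model (the stated
count), 1000 realizations for the decay-coverage property, 10^4 trials for
the t-test calibration, 200 seeds for the DOSY slope distribution.  The
analysis drivers under `analysis/` use one site per ligand and five HDX
replicates per condition, mirroring the study's scale.

## Known limitations

Only isotropic overall tumbling with fixed tau_m is supported (no diffusion
tensor, no tau_m optimization); model selection is AIC-only (no F-tests or
BIC); the DOSY module fits peak-height attenuation, not full 2D
inverse-Laplace processing; HDX is global (intact protein), with no
peptide-level resolution.  Because measured per-ligand diffusion
coefficients and raw replicate masses were never published as numbers, the
experimental regression (-0.54 +/- 0.02 slope, -7.83 intercept) can only
be emulated qualitatively through the generators, and fixtures standing in
for such data are synthetic by construction.
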