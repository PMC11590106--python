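# Methods

## Equilibrium model

The assay mixes a fluorescently labeled mannose oligosaccharide (total
[M]0), the lectin receptor ConA (total [C]0, the tetramer counted as a
single binding entity — the binding constants are defined on that
basis, so no per-monomer site statistics are applied), and glucose
(total [G]0).  Both sugars bind the same site with dissociation
constants K_M and K_G (molar).  Substituting the mass-action
expressions for the two complexes into the receptor balance gives a
monic cubic in the free receptor concentration C:

    C^3 + (K_M + K_G + M0 + G0 − C0) C^2
        + (K_M K_G + K_G (M0 − C0) + K_M (G0 − C0)) C
        − K_M K_G C0 = 0.

The combined mass-balance function
f(C) = C + C·M0/(K_M+C) + C·G0/(K_G+C) − C0 is strictly increasing on
C ≥ 0 with f(0) = −C0 ≤ 0 and f(C0) ≥ 0, so exactly one root lies in
[0, C0]; that is the physical solution.  The solver enumerates the
companion-matrix roots, clamps roots within 1e−12·C0 of a boundary onto
it, requires exactly one candidate after tolerance deduplication, and
then polishes with up to three Newton steps on f itself.  Polishing on
f rather than on the polynomial matters: f′ ≥ 1 everywhere, so the
update is stable even when the cubic coefficients span many decades and
the companion roots carry cancellation error (e.g. K_M ≪ C0, or
millimolar glucose against nanomolar receptor).  Free and bound species
are recovered from the exact ratios M0·K_M/(K_M+C) and M0·C/(K_M+C)
(never by subtracting near-equal totals, which loses ~8 digits when one
species dominates).  Every solved state is checked against all three
mass balances and both dissociation identities at relative tolerance
1e−9 (absolute floor 1e−18 M); violations raise rather than return.

Glucose is never assumed in excess — the full cubic is solved even
though at μM assay / mM glucose the depletion of glucose is negligible;
the exact solve costs the same.

## Units

All internal computation is molar.  Glucose crosses the API boundary in
mg/dL (the clinical convention) and is converted with MW 180.156 g/mol:
molar = mg/dL × 0.01 / MW, so 400 mg/dL = 22.203 mM.  The target window
0–400 mg/dL spans hypo- to severe hyperglycemia.

## Assay-design objective

ΔF(M0, C0) = free-ligand fraction at the high glucose endpoint minus at
the low endpoint.  ΔF → 0 at both C0 extremes (no receptor: nothing
bound at either endpoint; excess receptor: ligand stays bound at both)
and is single-peaked in between for this model, which the code enforces
as a unimodality guard (fluctuations below 1e−9 ignored); a violation
indicates solver failure, not a feature of the chemistry.

Grids default to logarithmic spacing at 60 points per decade (the maps
span decades).  The 40%-threshold band is extracted by linear
interpolation in (log10 C0, ΔF) between the bracketing grid points on
each flank of the maximum.  The maximum itself is flat — for the three
ligands studied the objective varies by <0.002 across the plateau — so
`optimal_protein_conc` reports, besides the argmax (ties broken toward
smaller C0), every grid point within 0.005 ΔF of the maximum.  Point
estimates of the optimum from different grids should be compared as
bands, not as single values.

## Titration fitting

Anisotropy vs log10 protein concentration is fit with the
four-parameter Boltzmann sigmoid
r(x) = r_max + (r_min − r_max)/(1 + exp((x − x0)/dx)) by unweighted
least squares (no replicate variances are assumed available).
Initialization: asymptotes from the 5th/95th percentiles of r, midpoint
from interpolation to the half-rise, width a quarter of the titrated
log-range — robust for monotone sigmoids.  A log10 abscissa is the
package convention; the Boltzmann family is conventional for semilog
anisotropy titrations.

K_d extraction has two modes.  "naive" reads K_d = 10^x0, the midpoint
concentration.  "depletion" subtracts half the ligand total:
K_d = 10^x0 − L0/2.  At the bench conditions modeled here
(L0 = 0.06 μM against K_d ≈ 0.054 μM) the ligand consumes a
non-negligible share of the protein, so the naive midpoint
overestimates K_d by roughly L0/2 (~50%); both modes are exposed so the
bias is visible rather than hidden.  The default is naive, matching the
common semilog-plot procedure.  Constants are reported to three
significant figures; K_a = 1/K_d exactly.

The closed-form two-component isotherm
CM = (b − sqrt(b² − 4 P0 L0))/2, b = P0 + L0 + K_d serves as the
forward model for synthetic titrations and agrees with the full
competitive solver at G0 = 0 to 1e−10 relative.

## Glucose calibration and scoring

The response r(g) is fit with a monotone four-parameter log-logistic
r(g) = r_inf + (r_0 − r_inf)/(1 + (g/g_50)^h), chosen over splines or
polynomials because it matches the mechanistic curve shape and inverts
in closed form — prediction must be exact, not iterative.  Inversion
clamps readings outside the open (r_inf, r_0) interval to 1e−9 of the
span inside it and flags them (a reading above the zero-glucose
asymptote predicts ≈0 glucose, below the saturating asymptote a very
large value).

Accuracy metrics over reference/prediction pairs restricted to 50–400
mg/dL (configurable; relative error explodes at very low glucose, and
the range filter is the only guard — no winsorization):

- MARD = 100 · mean(|pred − actual| / actual)  [percent]
- RMSE = sqrt(mean((pred − actual)²))  [mg/dL]
- SEC  = sqrt(SSres / (n − p)), p = 4 calibration parameters [mg/dL],
  omitted with a flag when n ≤ p.

SEC conventions differ across the glucose-sensing literature; both SEC
and RMSE are reported so comparisons can state which is used.

## Synthetic data

The generator emulates steady-state spectrofluorometer output.
Anisotropy of a mixed population is the population-fraction-weighted
average r = r_free + (r_bound − r_free)·f_bound, i.e. equal quantum
yield and lifetime in the free and bound states; intensity-weighted
mixing, photobleaching, inner-filter and scattering effects are not
modeled, so passing round-trip tests demonstrates correctness of the
analysis chain under these assumptions, not robustness to every real
instrument artifact.  Defaults r_free = 0.05, r_bound = 0.25 (typical
of a small dye free vs protein-bound), additive Gaussian anisotropy
noise sd 0.003 — a fixture choice for a bench instrument, not a claim
about any particular one.  Optional multiplicative noise on the raw
polarized intensities propagates through the anisotropy formula
instead.  One integer seed drives a single pseudorandom stream per
generator call; identical inputs and seed give byte-identical tables.

Raw intensity pairs are generated by inverting the anisotropy formula
at a configured total intensity T = I_VV + 2·G·I_VH:
I_VV = T(1+2r)/3, G·I_VH = T(1−r)/3.  Inversion accepts r in (−0.5, 1];
r = 1 is the fully polarized degenerate reading I_VH = 0.

The instrument factor is computed as G = I_VH/I_VV from a reference
reading, and can equally be supplied as a calibrated constant (the
horizontal-excitation convention differs between instruments).

## Problem sizes and numerical choices

Acceptance-level computations use 80 grid points per decade for the
threshold bands (results change by <1% beyond ~30/decade), 1000 random
systems for the solver/bisection cross-check at 1e−8 relative
agreement, 50 noisy replicates for K_d-recovery statistics, and 25
replicate calibrate/predict cycles per noise level for the MARD-vs-
noise monotonicity check (averaging across seeds keeps a Monte Carlo
comparison of nearby noise levels stable).  All of this runs in seconds
on one CPU.

## Known limitations

- Single-site competitive binding only: no cooperativity between the
  tetramer's sites, no kinetics, no temperature/pH dependence of the
  constants (bench buffer values; interstitial-fluid constants would
  differ).
- The calibration family is a phenomenological fit, not the mechanistic
  curve; its adequacy is checked only by residuals on the mechanistic
  shape (residual RMS < 1e−3 anisotropy units, noiseless).
- MARD/SEC from synthetic data characterize the analysis chain, not any
  physical instrument's accuracy.
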