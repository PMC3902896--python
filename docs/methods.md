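# Methods

## Binding models and unit conventions

Both saturation models are written in dissociation form. The Langmuir model
Ȳ = x/(K_app + x) treats the response element as binding a single ligand
and resolves an *apparent* constant; the two-monomer assembly model
Ȳ = x²/(K_tot + x²) resolves the *total* macroscopic constant for loading
two receptor monomers onto a palindrome, whatever microscopic path (two
monomers stepwise, or a pre-formed dimer) assembles them. The dimer model is
two-state — empty vs doubly bound; singly-ligated palindrome intermediates
are not carried as a separate macrostate, which is exactly what makes K_tot
a macroscopic product constant. Its midpoint is x = √K_tot with Hill slope
2, so a 100× change in K_tot shifts the transition 10× in concentration.

All internal quantities are molar (K_app, k_dim, concentrations) or molar
squared (K_tot). The bundled panel stores printed units (nM, fM²), and
"fM²" is interpreted as 1e-15 M², not (1e-15 M)². Only that reading is
internally consistent: √(0.800e-15 M²) = 28 nM, matching the ~32 nM
Langmuir midpoint measured for the same palindrome, whereas the literal
reading gives 0.9 fM, seven orders of magnitude off. The prose convention
"affinity" refers to the association sense; stored values are dissociation
constants (K_assoc = 1/K_d).

The solution dimerization 2M ⇌ M₂ with dissociation constant k_dim gives
free monomer as the positive root of r_total = x + 2x²/k_dim. The root is
evaluated as x = 2r/(1 + √(1 + 8r/k_dim)), which is subtraction-free and
keeps mass conservation accurate to better than 1e-10 relative across
1 pM–1 mM even when dimerization is negligible; the naive quadratic formula
loses ~8 digits in that regime.

## Isotherm fitting

A single constant is fit globally to all replicates pooled, by unweighted
least squares on Ȳ (no weighting scheme is assumed for footprint data).
The parameter is optimized on a log10 scale: SSR is scanned on a dense
log-spaced grid (8 points per decade, one decade beyond the data range on
each side; doubled exponents for K_tot, which lives on the squared scale),
then the best three grid points are refined with a bounded scalar optimizer
(xatol 1e-12 in log10). This multi-start scheme is deterministic and
recovers noise-free generating constants to better than 1e-6 relative.

Fit quality is reported as SD = √(SSR/(N − p)) with p = 1; the N − p
convention is documented here because "SD" of a fit is otherwise ambiguous.
Saturation values outside [−0.2, 1.2] are rejected as outliers before
fitting, with a logged warning. Flat data (range of Ȳ < 1e-3) is flagged
non-identifiable (`converged=False`).

Confidence intervals use case-resampling bootstrap (percentile intervals,
default 1000 draws, seeded) over the pooled points, since the error model
behind published "± SD" values on binding constants is generally unstated.
At the panel noise level (additive SD 0.087, two replicates of 12 points),
95% intervals cover the generating constant at close to nominal rate in the
test suite's coverage study.

## Dose–response model

FA(D) = e + d·Ȳ(f·D; K_tot): the in-vitro isotherm is treated as a
transition curve rescaled into cellular units — d rescales the amplitude
(absorbing the action of all other factors), e shifts the baseline, and f
converts expression-vector dose (ng) into receptor concentration (M),
assumed strictly proportional (expression saturation is out of scope). The
published description fixes the roles of d, e, f but not the exact algebra;
here d is the amplitude, so the plateau is e + d. Under the alternate
reading where the "maximal" parameter is the plateau itself, map
d = d_max − e.

(d, e, f) are strictly global — no per-curve nuisance parameters — and are
fit by pooled unweighted least squares with every curve's K_tot fixed
(per-point 1/SEM weighting is available behind a flag, default off).
Multi-start over log-spaced f (1e-12–1e-6 M/ng, 2 per decade) with a
trust-region reflective optimizer, d ≥ 0 and e > 0 bounded. The model is
invariant under rescaling doses by c and f by 1/c; the fit recovers this
equivalence class exactly on noise-free data.

## Affinity–function diagnostics

Cross-sections interpolate each curve linearly in dose within its grid and
never extrapolate. Regression is ordinary least squares of activity on
affinity, both optionally log10-transformed (base 10 chosen as the
conventional display scale); significance is the F-test of the slope,
P = SF(R²(n−2)/(1−R²); 1, n−2) — the probability that the observed R²
arises from two uncorrelated variables. On the bundled panel this gives
R² = 0.73 (P = 0.014) on log–log scale vs 0.44 on linear scale against
K_app; the rounded printed inputs leave the linear value ~0.01 below the
published 0.45 rounding. Against log K_tot the panel gives R² = 0.75,
within 0.02 of the log K_app value, reflecting the near-affine relation
between the two log-affinities.

A note on convexity: at a mid-sensitivity dose the simulated family's
cross-section decays convexly in K_tot — exactly, since
∂²FA/∂K_tot² > 0 — and the test suite asserts convexity via
divided-difference slopes on the K_tot axis. Against the *measured* K_app
column raw second differences need not all be positive, because the
empirical K_app spacing is uneven and only approximately log-affine in
K_tot; monotone decay is asserted there.

Perturbation simulations apply a uniform change to every HRE:
`affinity_fold_reduction` multiplies each dissociation-scale K_tot by the
factor; `max_activity_fold_reduction` divides the plateau e + d by the
factor keeping the baseline (negative resulting amplitude is an error).
Reports draw n = 3 noisy replicates per condition and test
perturbed-vs-wild-type with Welch's unequal-variance t-test (the asterisk
thresholds 0.05 / 0.005 follow the display convention). Two degenerate
zero-variance samples with equal means are reported as P = 1 (scipy returns
NaN); this only arises in noise-free simulations.

## Occupancy simulator

Receptor assembly at a promoter of 1–12 ordered sites (half-sites and
palindromes) is computed by exact enumeration of the configurational
partition function. Assumptions:

- **Trace DNA**: the promoter does not deplete the receptor pool; each
  species' free monomer x and dimer [M₂] = x²/k_dim come from the solution
  equilibrium alone, given its total concentration.
- **Binding pathways**: monomers bind half-sites (weight x/k_half); only
  pre-formed dimers bind palindromes (weight [M₂]/k_pal). A species with no
  detectable dimerization (k_dim = None) has no dimer pool and cannot
  occupy palindromes. Where only a lower limit on k_dim was measurable, the
  record carries `k_dim_is_lower_limit=True` and the limit value is used as
  the constant — the weakest dimerization consistent with the data.
  Monomer occupancy of palindromes (singly-ligated species) is excluded.
- **Cooperativity**: one factor of k_c per nearest-neighbor pair of sites
  occupied by the *same* species, regardless of the two site types (so a
  monomer on a half-site couples to a dimer on an adjacent palindrome with
  the full k_c); heterotypic adjacent pairs get none.
- **Competition setup**: sweeps assign all species the same total at each
  grid point; per-species totals are accepted for asymmetric scenarios.
  The x-axis of a sweep is *total* receptor concentration, with solution
  dimerization resolved internally.

"Fully ligated" is homotypic (every site occupied by one species); mixed
full states are aggregated separately. Enumeration is validated against
hand-derived closed-form partition functions for all one-, two- and
three-site architectures, against independence factorization at k_c = 1,
and against normalization, permutation-symmetry and monotonicity
invariants, all at 1e-10.

With three archetypes sharing k_half = 1 µM and k_pal = 10 nM but differing
in (k_dim, k_c) — weak dimerizer (10 µM, 200), intermediate (1 µM, 50),
strong (16 nM, 1) — the simulator reproduces the architecture-selectivity
logic: weak dimerizers dominate half-sites (their monomer pool is not
drained into dimers), strong dimerizers dominate isolated palindromes, and
multi-site promoters select the intermediate (two palindromes) or the
cooperative weak dimerizer (two half-sites) over windows of concentration.

## Synthetic data

Generators are deterministic under a fixed seed (numpy `default_rng`) and
emit the declared replicate count.

- **Isotherms**: Ȳ from the dimer model plus additive Gaussian noise,
  default SD 0.087 — the residual scatter of the reference global fit —
  with two replicates of 12 log-spaced points over 1 nM–3 µM, spanning
  every panel midpoint (28–748 nM). Values are clipped to the fitting
  validity window [−0.2, 1.2]; clipping is logged.
- **Dose–response families**: FA = 1 + (f_max − 1)·Ȳ(f·D) with f_max = 5
  and f = 1 nM/ng on 10 log-spaced doses, 3–1500 ng.
- **Error perturbation**: Gaussian replicates in additive, relative, or
  per-HRE mode; the per-HRE relative SD is √3·SEM/FA from the panel
  (n = 3), a documented stand-in for the original error-injection
  procedure, which is described only by reference. Re-analyzing such
  families at the 100 ng cross-section gives log–log R² with median ~0.8
  across seeds (enveloped in [0.6, 0.95] by the test suite) — individual
  realizations vary widely, which is itself one of the framework's points.

The generators emulate the *statistical* structure of footprint titrations
and transfection assays (sigmoidal shape, replicate noise); they do not
model densitometry artifacts, expression saturation at high vector dose,
chromatin or promoter-context effects. Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to those unmodeled effects.

## Study sizes and numerical choices

Simulation studies use 100 seeds for the model-comparison and K_tot
recovery studies, 50 seeds for (d, e, f) recovery and 200 for the
cross-section R² envelope — sizes at which the medians are stable to well
inside the asserted tolerances. Optimizer tolerances are 1e-12 (log10
scalar refinement) and 1e-14 (xtol/ftol/gtol, least_squares); ties in the
multi-start pick the lowest SSR. Degenerate inputs (flat curves, zero
totals, empty grids) are either flagged non-identifiable or rejected with
typed errors, as documented per function.

## Limitations

- Kinetics (on/off rates, timescale separation), ionic-strength and
  temperature dependence of constants are out of scope.
- The dose-to-concentration map is strictly linear; real expression
  saturates at high vector dose.
- Site affinities in the occupancy simulator come in two classes
  (half-site, palindrome); sequence-dependent variation within a class is
  not modeled, and k_dim/k_c are consumed as inputs, not fit.
- Bootstrap intervals reflect resampling of the observed design points;
  they do not propagate systematic densitometry error.
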