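# Methods

## Models

MPOD spatial profiles are modelled as functions of retinal eccentricity in
degrees of visual angle (no micrometre conversion anywhere in the model
layer; axial morphometry stays in µm). Two families are implemented:

* `M_EG(x) = A1·e^(−p1·x) + A2·e^(−p2·(x−x2)²)` — the legacy two-component
  form, expressed in base *e*; `meg_to_base10` divides the amplitudes by
  ln 10 for comparison with base-10 parameterisations.
* `M_3G(x) = Σᵢ Nᵢ·e^(−qᵢ·(x−gᵢ)²)` — three Gaussian components with roles
  (central peak / intermediate / tail) enforced by fitting bounds, not by
  the parameter type.

The tail spread `q3` may be slightly negative: fitted cohorts show small
negative values (the third component then grows towards a distant centre
`g3`, approximating a flat, slowly varying background over the 0–5° analysis
window). Evaluation, differentiation and integration all admit this case;
integration falls back from the error-function closed form to adaptive
quadrature (absolute tolerance 1e-9) for any non-decaying term.

Derivatives are closed-form. For a Gaussian term `N·e^(−q·u²)` with
`u = x − g`: order 1 is `−2qNu·e^(−qu²)`, order 2 `N·e^(−qu²)(4q²u²−2q)`;
orders 3–4 are implemented for internal root refinement. Exponential terms
differentiate as `(−p1)^k·A1·e^(−p1·x)`. All derivatives are verified
against central finite differences in the test suite.

## Critical points dd1–dd6

The second derivative is scanned on a 1e-3° grid over the analysis domain
(default 0–5°, matching the fitted data range; observed dd6 values near 2°
are comfortably interior). Zeros are bracketed by sign changes of the second
derivative and extrema by sign changes of the third; each bracket is refined
by 50 bisection steps (interval ≈ 1e-18°, far below the 1e-6° contract).
Events closer together than 2e-3° are treated as a degenerate double root
and reported once, the extremum outranking tangency zeros.

Labels are assigned by *chained* selection: dd1 is the first zero, dd2 the
first maximum beyond dd1, dd3 the first zero beyond dd2, dd4 the first
minimum beyond dd3, dd5 the first zero beyond dd4, dd6 the first maximum
beyond the last assigned point. This realises the canonical
zero/max/zero/min/zero/max sequence of a fully featured profile, makes
dd1 < … < dd6 hold by construction whenever all six exist, and treats the
curvature minimum adjacent to 0° (boundary or interior — it always precedes
dd3) as the unreported first minimum, so dd4 is the *second* minimum. An
absent intermediate point does not block later ones: a profile can have a
dd6 without a dd5 when the curvature rises from its eccentric minimum to a
maximum without crossing zero — consistent with cohorts in which dd6 is
present in every eye while dd5 is not. Absence is a value (None), never an
error.

## Derived parameters

* `A0 = M(0)`; `A_ecc = M(dd4)` when dd4 exists.
* `AUC02`, `AUC5`: integrals over 0–0.2° and 0–5° (closed form + quadrature
  as above; additive over adjacent intervals to 1e-9).
* `HHr`: the half-height level `A0/2` is ambiguous on non-monotonic
  profiles, where a shoulder can hover near it. The default convention is
  the *last sustained down-crossing*: the largest eccentricity at which the
  curve falls through `A0/2` and stays below it through the domain end.
  A `first` crossing convention is selectable. `HHr` is absent when the
  curve never settles below half height.
* Shape classification: a profile is an `eccentric_peak` when it rises above
  a preceding trough by more than `RISE_TOL = 1e-3` a.u.; `shoulder` when it
  is monotone to within that tolerance but has a dd4; otherwise
  `central_peak_monotonic`. The prominence tolerance exists because
  parameters quoted to three decimals can produce spurious sub-millidensity
  gradient reversals near the centre (the grand-mean parameterisation shows
  a 4e-4 a.u. rise over 0.012° — two orders below instrument noise); a
  strict derivative-sign rule would misclassify such profiles as
  eccentric-peaked. The same tolerance defines the `monotonic` flag.

Recomputing the derived parameters from grand-mean primaries printed to
three decimals reproduces the printed eccentricities (dd1–dd6, HHr) to about
±0.01° but the amplitude/area quantities only to ~2–3%: the rounding
sensitivity concentrates in the `N3·e^(−q3(x−g3)²)` tail term, where
`q3 = −0.020` multiplies `(x−10)² = 100` at the origin, so a 0.0005 rounding
of q3 moves `A0` by ~5%·0.29·... ≈ 1–2%. Tests therefore assert positions at
±0.02° and amplitudes/areas at 3%, and these tolerances are documented as
rounding-limited, not as model error.

## Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective) with analytic Jacobians. Default box bounds:
`Nᵢ ∈ [0, 2]`, `q1 ∈ [2, 180]`, `q2 ∈ [0.1, 10]`, `q3 ∈ [−0.1, 0.1]`,
`g1 ∈ [−0.1, 0.1]`, `g2 ∈ [0, 1.5]`, `g3 ∈ [−2, 10]` (M3G);
`Aᵢ ∈ [0, 2]`, `p1, p2 ∈ [0.1, 20]`, `x2 ∈ [0, 2]` (MEG). The M3G limits
reproduce the clamps visible in fitted-cohort extreme values (q1 max exactly
180, g1 at ±0.1, g3 spanning −2 to 10) and are what separates the component
roles; all are user-overridable.

Multi-start replaces manual parameter steering: one deterministic heuristic
start (central value → N1; location of the residual maximum after a
central-Gaussian guess → g2; small negative q3) plus Latin-hypercube draws
inside the box (default `n_starts = 8`, seeded). The lowest-SSE start wins;
ties break to the lowest start index, so identical profile + config + seed
always returns the identical fit. The loss is unweighted least squares;
per-point SD weighting is available (`weighted=True`) but off by default,
since instrument exports do not document a weighting. Optimiser tolerances
default to 1e-12, tight enough that noise-free model-family data are
recovered to ≤1e-4 in every parameter.

SSE is reported in raw a.u.²; the CLI also emits ×10³ values for
readability. `transfer_evaluation` fits each family on each window and
scores each fit on every window at least as wide, producing the 2°→2°,
2°→5° and 5°→5° comparison rows.

## Profile extraction from maps

Maps are 2D MPOD rasters with a sub-pixel foveolar centre (0-based row/col)
and a degrees-per-pixel scale. For each requested radius the map is sampled
at `n_angles` (default 360) equally spaced angles by bilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1 — chosen for determinism and
testability, as instrument interpolation is unpublished); the
circumferential mean and SD become the profile point. Default radii run from
0.02° to 6.0° in 0.02° steps, oversampling the narrowest fitted feature
(central spreads up to 180 deg⁻² ⇒ half-width ≈ 0.06°). Radius 0 degenerates
to the interpolated centre value with SD 0. A circle leaving the image is an
error naming the radius.

## Synthetic data

The generator emulates the statistical structure a fitted cohort implies:

* Parameters: independent normals at the published cohort means/SDs,
  truncated to the fitting box by rejection (cap 10⁴ proposals). Truncation
  visibly shifts some marginals (q1 mean ≈ 52 rather than 32; N3 and g3
  similarly) — the tests assert sample moments against exact
  truncated-normal oracles. No inter-parameter covariance is imposed because
  none is published; end-to-end results must not read the independence as
  biology.
* Profiles: model evaluation plus i.i.d. Gaussian noise, default
  `noise_sd = 0.01` a.u. (about 1.5% of a typical central amplitude, the
  scale of scatter visible in machine-generated profile plots).
* Maps: radially symmetric renderings with optional pixel noise.
* Morphometry: FAZ equivalent radius (0.91 ± 0.19°), foveal bowl height
  (123 ± 22 µm) and foveal pit radius (3.96 ± 0.44°) are drawn *conditionally
  on each eye's realised dd6* so that the standardised regression
  `dd6 = 0.605·FAZer + 0.426·bwlht + 0.190·Pr` holds with population
  R² = 0.81 (defaults; all controllable). An equicorrelation among the
  predictors is solved from `b'Sb = R²` (ρ ≈ 0.25 at the defaults —
  plausible, as foveal pit and FAZ metrics correlate), and predictors are
  drawn from their exact conditional Gaussian given dd6. At `target_R2 = 1`
  dd6 becomes an exact linear combination of the standardised predictors.
  The remaining morphometry variables are independent draws at their
  published moments, except the two redundant FAZ diameters, which are
  generated at correlation 0.98 with FAZer so that factor analysis sees the
  expected single dominant FAZ factor.
* Eyes whose sampled parameters lack a dd6 (≈4% at the default
  distributions) enter the link at the cohort-average dd6 (z = 0) rather
  than being resampled, keeping the parameter marginals exactly truncated
  normal. Real cohorts show dd6 in every eye; this is a generator
  simplification, not a claim about data.

## Cohort statistics

Factor analysis is principal components on the correlation matrix of
complete cases; loadings are eigenvector·√eigenvalue, factors retained by
the Kaiser rule (eigenvalue > 1) unless a count is given, significance at
|loading| > 0.7. No rotation is applied by default (none is standard for
this workflow); varimax is available. Factor signs are fixed so each
factor's largest-magnitude loading is positive. The full loading matrix
reproduces the correlation matrix to 1e-10.

Regressions run on z-scores (sample SD, n−1). Multiple regression reports
standardised betas and R², flagging R² < 0.5 as below the conventional
usefulness bar. Forward stepwise selection adds the candidate with the
largest F-to-enter while its p-value is below `alpha_enter = 0.05` (entry
criterion chosen as the conventional default), recording entry order and
per-step R² increments, which sum to the final R² exactly. Rows missing any
used variable are dropped listwise per analysis, so each analysis has its
own complete-case n. Rank-deficient designs and constant variables raise
named errors.

## Problem sizes

Validation uses sizes the full pipeline supports comfortably: 50 noisy
profiles for parameter recovery, one 48-eye cohort (the published cohort
size) for model comparison, 200 48-eye cohorts for the regression workflow,
10⁴ eyes for generator moment checks, 512² px maps for pipeline closure, and
1000 random parameter draws for critical-point ordering.

## Limitations

* Exact published SSE tables for real eyes cannot be reproduced from
  synthetic cohorts; only orderings and magnitude relations are asserted.
* The generator's parameter independence and Gaussian noise are idealised;
  passing recovery tests demonstrates the pipeline's correctness on data of
  the assumed structure, not robustness to instrument artefacts, fixation
  error or spatially correlated noise.
* Dual-wavelength image formation, foveolar-centre detection and absolute
  volume calibration (machine-specific "sumV" units) are out of scope;
  volumes are relative quantities.
* No 2D (e.g. Zernike) surface models and no Bayesian or mixed-effects
  fitting.
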