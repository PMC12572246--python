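# mpod — modelling the macular pigment optical density profile

The macular pigment — the xanthophyll carotenoids lutein, zeaxanthin and
meso-zeaxanthin concentrated at the centre of the human retina — is mapped in
vivo as macular pigment optical density (MPOD) against retinal eccentricity,
producing a *spatial density profile*. Profiles vary between eyes: some
decline monotonically from a central peak, some carry an eccentric
"shoulder", some a true eccentric (ring-like) peak. Clinically useful,
comparable descriptions of these shapes require an analytic model.

This package implements such a model and everything needed to use and
validate it without patient data. It targets researchers working with
dual-wavelength autofluorescence MPOD maps and OCT/OCTA foveal morphometry.

## Models

Two analytic forms of MPOD vs eccentricity `x` (degrees of visual angle):

* the legacy exponential + Gaussian model

  `M_EG(x) = A1·exp(−p1·x) + A2·exp(−p2·(x − x2)²)`

* a three-Gaussian-component model

  `M_3G(x) = Σᵢ Nᵢ·exp(−qᵢ·(x − gᵢ)²)`,  i = 1, 2, 3

  where component 1 carries the central peak, component 2 any intermediate
  shoulder or eccentric peak, and component 3 the peripheral tail-off
  (component roles enforced by fitting bounds).

Because both forms are smooth, the fitted curve can be interrogated through
its derivatives: the zeros and extrema of the second derivative define up to
six critical points `dd1 … dd6` that delimit the central-peak, intermediate
and tail zones. `dd4` (the second curvature minimum) locates any shoulder or
eccentric peak; `dd6` (the second curvature maximum) is a well-defined outer
boundary of the pigment distribution. Scalar metrics follow: the central
amplitude `A0 = M(0)`, the eccentric amplitude `A_ecc = M(dd4)`, areas under
the curve to 0.2° and 5°, and the half-height radius `HHr`.

## What the package provides

* `mpod.models` — both model families, closed-form derivatives, base-10
  amplitude conversion for the legacy model.
* `mpod.profiles` — radial-profile CSV I/O, resampling, and extraction of
  profiles from 2D MPOD maps by circular-path averaging.
* `mpod.fitting` — bounded multi-start nonlinear least squares over
  configurable eccentricity windows (0–2°, 0–5°), SSE model comparison and
  cross-window transfer evaluation.
* `mpod.features` — critical points `dd1…dd6`, derived parameters, profile
  shape classification (monotonic / shoulder / eccentric peak).
* `mpod.simulate` — synthetic profiles, maps and cohorts, including a
  controllable linear link between `dd6` and foveal morphometry (FAZ
  equivalent radius, foveal bowl height, foveal pit radius).
* `mpod.stats` — principal-components factor analysis with the |loading|>0.7
  significance rule, multiple regression and forward stepwise regression on
  standardised variables.
* a CLI: `mpod extract | fit | derive | simulate | cohort-stats`.

## Worked example

```python
from mpod import (GRAND_MEAN_M3G, ModelCurve, ModelKind, FitConfig,
                  fit_model, derive_all, render_profile)

# interrogate the three-Gaussian model at the published grand-mean parameters
curve = ModelCurve(ModelKind.M3G, GRAND_MEAN_M3G)
feats = derive_all(curve, domain=(0.0, 5.0))
print("profile class :", feats.profile_class.value)
print("A0  = %.3f a.u.   HHr = %.3f deg" % (feats.derived.A0, feats.derived.HHr))
print("dd4 = %.3f deg    dd6 = %.3f deg" % (feats.critical.dd4, feats.critical.dd6))
print("AUC 0-0.2 = %.3f   AUC 0-5 = %.3f a.u.*deg"
      % (feats.derived.AUC02, feats.derived.AUC5))

# simulate a noisy instrument export of the same eye and refit it
noisy = render_profile(GRAND_MEAN_M3G, noise_sd=0.01, seed=42)
fit = fit_model(noisy, "m3g", FitConfig(seed=0))
print("refit on noisy profile: sse = %.4g, g2 = %.3f deg"
      % (fit.sse, fit.curve.params.g2))
```

Output:

```
profile class : shoulder
A0  = 0.633 a.u.   HHr = 1.176 deg
dd4 = 0.687 deg    dd6 = 1.498 deg
AUC 0-0.2 = 0.122   AUC 0-5 = 1.021 a.u.*deg
refit on noisy profile: sse = 0.02175, g2 = 0.577 deg
```

The grand-mean profile declines monotonically but carries a curvature
relaxation at 0.687° — a shoulder. Its pigment extends (by the `dd6`
criterion) to about 1.5° of eccentricity, and half the central density is
reached at 1.18°. The refit of a noisy rendering returns the shoulder
component centre `g2` within a few hundredths of a degree of the generator
truth, with an SSE at the noise floor (250 in-window points × 0.01² ≈ 0.025).

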