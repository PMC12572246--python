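"""Synthetic MPOD profiles, maps and cohorts.

Stands in for an unreleased 48-eye dataset: model parameters are drawn from
independent normals (with the cohort means and standard deviations of the
fitted population) truncated to the fitting box, profiles are the model plus
i.i.d. Gaussian measurement noise, and per-eye foveal morphometry is drawn
from the published summary distributions with the outer-boundary eccentricity
dd6 linearly linked to FAZ equivalent radius, foveal bowl height and foveal
pit radius at a controllable population R-squared.

The link is imposed on standardised variables.  Writing ``y`` for the
standardised dd6 and ``x`` for the three standardised predictors, the target
regression ``y = b'x + e`` with coefficients ``b = (0.605, 0.426, 0.190)``
fixes ``Cov(x, y) = S b`` once a predictor correlation matrix ``S`` is
chosen; an equicorrelation ``rho`` is solved so that the population
R-squared ``b' S b`` equals the requested value, and the predictors are then
drawn from their exact conditional Gaussian distribution given each eye's
realised dd6.  At ``target_R2 = 1`` the link degenerates to dd6 being an
exact linear combination of the standardised predictors.

Parameters are sampled independently because no inter-parameter covariance
structure is published for the fitted population; end-to-end tests must not
read biological meaning into that independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortSpecError
from .features import critical_points
from .fitting import DEFAULT_M3G_BOUNDS
from .models import M3GParams, ModelCurve, ModelKind, eval_model
from .profiles import MPODMap, RadialProfile, default_radii

__all__ = [
    "CohortSpec",
    "MorphometryRecord",
    "MPODSummary",
    "PARAM_MEANS",
    "PARAM_SDS",
    "MORPH_MEANS",
    "MORPH_SDS",
    "sample_cohort",
    "cohort_frame",
    "render_profile",
    "render_map",
    "mpod_summary",
]

#: Cohort mean / sd of the fitted three-Gaussian parameters (48 eyes, 0-5 deg).
PARAM_MEANS: dict[str, float] = {
    "N1": 0.224, "N2": 0.296, "N3": 0.097,
    "q1": 32.092, "q2": 1.938, "q3": -0.009,
    "g1": -0.027, "g2": 0.547, "g3": 5.345,
}
PARAM_SDS: dict[str, float] = {
    "N1": 0.102, "N2": 0.125, "N3": 0.092,
    "q1": 43.978, "q2": 0.792, "q3": 0.032,
    "g1": 0.067, "g2": 0.265, "g3": 5.243,
}

#: Cohort mean / sd of the foveal morphometry variables.  Linear measures are
#: degrees of visual angle; axial measures (AvCRT, fov_th, bwlht) micrometres.
MORPH_MEANS: dict[str, float] = {
    "FAZf": 2.27, "FAZm": 2.03, "FAZer": 0.91,
    "AvCRT": 274.0, "fov_th": 231.0, "bwlht": 123.0,
    "Fr": 0.81, "Pr": 3.96, "fov_ang": 168.0,
}
MORPH_SDS: dict[str, float] = {
    "FAZf": 0.41, "FAZm": 0.39, "FAZer": 0.19,
    "AvCRT": 14.0, "fov_th": 14.0, "bwlht": 22.0,
    "Fr": 0.16, "Pr": 0.44, "fov_ang": 3.0,
}

#: Correlation imposed between FAZer and the two redundant FAZ diameters.
_FAZ_RHO = 0.98

_REJECTION_CAP = 10_000


@dataclass(frozen=True)
class MorphometryRecord:
    """Per-eye foveal morphometry (degrees of visual angle unless noted)."""

    FAZf: float      # FAZ maximum Feret diameter
    FAZm: float      # FAZ mean diameter
    FAZer: float     # FAZ equivalent radius
    AvCRT: float     # average central retinal thickness (um)
    fov_th: float    # central foveal thickness (um)
    bwlht: float     # foveal bowl height (um)
    Fr: float        # foveolar radius
    Pr: float        # foveal pit radius
    fov_ang: float   # foveal pit angle (degrees of angle)

    def __post_init__(self):
        vals = [getattr(self, f.name) for f in fields(self)]
        if min(vals) <= 0:
            raise ValueError("morphometry values must be positive")
        if self.FAZer > self.FAZf:
            raise ValueError("FAZ equivalent radius cannot exceed Feret diameter")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class MPODSummary:
    """Instrument-style MPOD summaries of one profile.

    ODrad values are MPOD at fixed eccentricities (a.u.); sumV values are
    relative pigment volumes, the rotational integral 2*pi*int_0^r M(s) s ds
    (instrument absolute volume calibration is machine-specific and not
    emulated); Peak is the profile maximum.
    """

    ODrad02: float
    ODrad1: float
    ODrad2: float
    ODrad3: float
    sumV02: float
    sumV1: float
    sumV2: float
    sumV3: float
    Peak: float

    def __post_init__(self):
        v = [self.sumV02, self.sumV1, self.sumV2, self.sumV3]
        if any(b < a for a, b in zip(v, v[1:])):
            raise ValueError("sumV must be non-decreasing in radius")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _default_param_means():
    return dict(PARAM_MEANS)


def _default_param_sds():
    return dict(PARAM_SDS)


def _default_bounds():
    return dict(DEFAULT_M3G_BOUNDS)


def _default_morph_means():
    return dict(MORPH_MEANS)


def _default_morph_sds():
    return dict(MORPH_SDS)


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    dd6_link is (beta_FAZer, beta_bwlht, beta_Pr, target_R2) on standardised
    variables.
    """

    n_eyes: int = 48
    param_means: dict = field(default_factory=_default_param_means)
    param_sds: dict = field(default_factory=_default_param_sds)
    bounds: dict = field(default_factory=_default_bounds)
    noise_sd: float = 0.01
    morph_means: dict = field(default_factory=_default_morph_means)
    morph_sds: dict = field(default_factory=_default_morph_sds)
    dd6_link: tuple[float, float, float, float] = (0.605, 0.426, 0.190, 0.81)
    seed: int = 0

    def __post_init__(self):
        if self.n_eyes < 1:
            raise CohortSpecError("n_eyes must be >= 1")
        if self.noise_sd < 0:
            raise CohortSpecError("noise_sd must be non-negative")
        if any(s < 0 for s in self.param_sds.values()):
            raise CohortSpecError("parameter sds must be non-negative")
        r2 = self.dd6_link[3]
        if not 0.0 < r2 <= 1.0:
            raise CohortSpecError("target R2 must lie in (0, 1]")
        for name, mu in self.param_means.items():
            lo, hi = self.bounds[name]
            sd = self.param_sds[name]
            if sd == 0:
                if not lo <= mu <= hi:
                    raise CohortSpecError(
                        f"{name}: degenerate mean {mu} outside bounds ({lo}, {hi})")
                continue
            mass = stats.norm.cdf((hi - mu) / sd) - stats.norm.cdf((lo - mu) / sd)
            if mass < 1e-6:
                raise CohortSpecError(
                    f"{name}: truncation to ({lo}, {hi}) leaves no mass around "
                    f"mean {mu} (sd {sd})")


def _truncated_normal(rng, mu, sd, lo, hi, n):
    """Rejection sampling of N(mu, sd) truncated to [lo, hi]."""
    if sd == 0:
        return np.full(n, mu)
    out = np.empty(n)
    filled = 0
    for _ in range(_REJECTION_CAP):
        draw = rng.normal(mu, sd, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled:filled + keep.size] = keep
        filled += keep.size
        if filled == n:
            return out
    raise CohortSpecError(
        f"rejection sampling exhausted for mu={mu}, sd={sd}, bounds=({lo},{hi})")


def _link_geometry(beta: np.ndarray, r2: float):
    """Equicorrelation and conditional moments for the dd6-morphometry link."""
    cross = beta[0] * beta[1] + beta[0] * beta[2] + beta[1] * beta[2]
    rho = (r2 - float(beta @ beta)) / (2.0 * cross)
    S = np.full((3, 3), rho)
    np.fill_diagonal(S, 1.0)
    if np.linalg.eigvalsh(S)[0] < -1e-12:
        raise CohortSpecError(
            f"dd6 link infeasible: implied predictor correlation {rho:.3f}")
    c = S @ beta                       # Cov(x, y), Var(y) = 1
    cond_cov = S - np.outer(c, c)
    w, v = np.linalg.eigh(cond_cov)
    if w[0] < -1e-10:
        raise CohortSpecError("dd6 link infeasible: conditional covariance "
                              "not positive semidefinite")
    L = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return c, L


def _draw_params(rng, spec: CohortSpec) -> M3GParams:
    vals = {name: float(_truncated_normal(
        rng, spec.param_means[name], spec.param_sds[name],
        *spec.bounds[name], 1)[0]) for name in PARAM_MEANS}
    return M3GParams(**vals)


def sample_cohort(spec: CohortSpec | None = None
                  ) -> list[tuple[M3GParams, MorphometryRecord]]:
    """Draw a synthetic cohort of model parameters and linked morphometry.

    Deterministic for a given ``spec.seed``.  Eyes whose realised parameter
    set lacks a dd6 critical point (rare under the default distributions)
    enter the link at the cohort-average dd6.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)

    params = [_draw_params(rng, spec) for _ in range(spec.n_eyes)]
    dd6 = np.array([
        critical_points(ModelCurve(ModelKind.M3G, p)).dd6 or np.nan
        for p in params])

    ok = np.isfinite(dd6)
    mu = float(np.mean(dd6[ok])) if ok.any() else 0.0
    sd = float(np.std(dd6[ok], ddof=1)) if ok.sum() > 1 else 1.0
    z = np.where(ok, (dd6 - mu) / (sd if sd > 0 else 1.0), 0.0)

    beta = np.asarray(spec.dd6_link[:3], dtype=float)
    c, L = _link_geometry(beta, float(spec.dd6_link[3]))
    noise = rng.standard_normal((spec.n_eyes, 3))
    xz = z[:, None] * c[None, :] + noise @ L.T   # standardised FAZer, bwlht, Pr

    mm, ms = spec.morph_means, spec.morph_sds
    records = []
    for i in range(spec.n_eyes):
        faz_er = mm["FAZer"] + ms["FAZer"] * xz[i, 0]
        bwlht = mm["bwlht"] + ms["bwlht"] * xz[i, 1]
        pr = mm["Pr"] + ms["Pr"] * xz[i, 2]
        z_er = (faz_er - mm["FAZer"]) / ms["FAZer"]
        for _ in range(_REJECTION_CAP):
            mix = _FAZ_RHO * z_er + np.sqrt(1 - _FAZ_RHO**2) * rng.standard_normal(2)
            faz_f = mm["FAZf"] + ms["FAZf"] * mix[0]
            faz_m = mm["FAZm"] + ms["FAZm"] * mix[1]
            others = {k: rng.normal(mm[k], ms[k])
                      for k in ("AvCRT", "fov_th", "Fr", "fov_ang")}
            vals = {"FAZf": faz_f, "FAZm": faz_m, "FAZer": faz_er,
                    "bwlht": bwlht, "Pr": pr, **others}
            if min(vals.values()) > 0 and faz_er <= faz_f:
                records.append(MorphometryRecord(**vals))
                break
        else:  # pragma: no cover - means/sds make this unreachable
            raise CohortSpecError("could not draw a valid morphometry record")
    return list(zip(params, records))


def cohort_frame(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Cohort as a table: eye_id, morphometry, generator-truth parameters."""
    cohort = sample_cohort(spec)
    rows = []
    for i, (p, m) in enumerate(cohort):
        row = {"eye_id": f"eye_{i:03d}"}
        row.update(m.to_dict())
        row.update({f"true_{k}": v for k, v in p.to_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


def render_profile(params: M3GParams, grid=None, noise_sd: float = 0.01,
                   seed: int | None = None) -> RadialProfile:
    """Model evaluation on ``grid`` plus i.i.d. Gaussian measurement noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    grid = default_radii() if grid is None else np.asarray(grid, dtype=float)
    curve = ModelCurve(ModelKind.M3G, params)
    y = eval_model(curve, grid)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, grid.size)
    return RadialProfile(grid, y, np.full(grid.size, float(noise_sd)))


def render_map(params: M3GParams, size_px: tuple[int, int] = (512, 512),
               scale: float = 0.02, center: tuple[float, float] | None = None,
               noise_sd: float = 0.0, seed: int | None = None) -> MPODMap:
    """Radially symmetric 2D rendering of a model, plus optional pixel noise."""
    nr, nc = size_px
    if center is None:
        center = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    r0, c0 = center
    if not (0 <= r0 <= nr - 1 and 0 <= c0 <= nc - 1):
        raise ValueError(f"center {center} outside image of shape {size_px}")
    rows = np.arange(nr)[:, None] - r0
    cols = np.arange(nc)[None, :] - c0
    dist = scale * np.hypot(rows, cols)
    curve = ModelCurve(ModelKind.M3G, params)
    pixels = eval_model(curve, dist.ravel()).reshape(nr, nc)
    if noise_sd > 0:
        pixels = pixels + np.random.default_rng(seed).normal(0, noise_sd, pixels.shape)
    return MPODMap(pixels, center, scale)


def mpod_summary(params: M3GParams) -> MPODSummary:
    """Instrument-style point and relative-volume summaries of a model."""
    curve = ModelCurve(ModelKind.M3G, params)
    od = eval_model(curve, [0.2, 1.0, 2.0, 3.0])
    grid = np.arange(0.0, 3.0 + 5e-4, 1e-3)
    y = eval_model(curve, grid)
    integrand = 2.0 * np.pi * grid * y
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (integrand[1:] + integrand[:-1]) * np.diff(grid))])
    sumv = np.interp([0.2, 1.0, 2.0, 3.0], grid, cum)
    peak_grid = np.arange(0.0, 6.0, 1e-3)
    peak = float(np.max(eval_model(curve, peak_grid)))
    return MPODSummary(*od, *sumv, peak)
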