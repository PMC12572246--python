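"""Analytic models of the macular pigment optical density (MPOD) spatial profile.

Two model families are provided, both functions of retinal eccentricity ``x``
expressed in degrees of visual angle:

* ``MEG`` — the legacy two-component model, a declining exponential plus a
  Gaussian::

      M_EG(x) = A1 * exp(-p1 * x) + A2 * exp(-p2 * (x - x2)**2)

  The exponential carries the central peak and peripheral tail-off; the
  Gaussian carries any eccentric shoulder or eccentric peak.

* ``M3G`` — a sum of three Gaussian components::

      M_3G(x) = sum_i  N_i * exp(-q_i * (x - g_i)**2),   i = 1..3

  Component roles (enforced by fitting bounds, not by the parameter type):
  component 1 is the central peak, component 2 any intermediate shoulder or
  eccentric peak, component 3 the peripheral tail-off.  The tail spread
  ``q3`` may be slightly negative — a fitted-tail artefact in which the third
  component grows away from its (distant) centre ``g3`` — and every
  evaluation and integration routine in this package handles that case.

Both families are analytically differentiable to any order; closed-form
derivatives up to order four are implemented here and are the basis of the
critical-point analysis in :mod:`mpod.features`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum

import numpy as np

from .errors import InvalidModelError

__all__ = [
    "MEGParams",
    "M3GParams",
    "ModelKind",
    "ModelCurve",
    "eval_model",
    "model_derivative",
    "meg_to_base10",
    "meg_from_base10",
    "GRAND_MEAN_M3G",
    "LN10",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class MEGParams:
    """Parameters of the exponential-plus-Gaussian model.

    A1 : exponential amplitude (MPOD a.u.), >= 0
    p1 : exponential decay constant (deg^-1), > 0
    A2 : Gaussian amplitude (a.u.), >= 0
    p2 : Gaussian spread (deg^-2), > 0
    x2 : Gaussian peak eccentricity (deg), >= 0
    """

    A1: float
    p1: float
    A2: float
    p2: float
    x2: float

    def __post_init__(self):
        vals = [self.A1, self.p1, self.A2, self.p2, self.x2]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidModelError(f"non-finite MEG parameter: {self}")
        if self.A1 < 0 or self.A2 < 0:
            raise InvalidModelError("MEG amplitudes must be non-negative")
        if self.p1 <= 0 or self.p2 <= 0:
            raise InvalidModelError("MEG decay/spread constants must be positive")
        if self.x2 < 0:
            raise InvalidModelError("MEG Gaussian centre x2 must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.A1, self.p1, self.A2, self.p2, self.x2], dtype=float)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "MEGParams":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})

    @classmethod
    def from_array(cls, a) -> "MEGParams":
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class M3GParams:
    """Parameters of the three-Gaussian model.

    N1..N3 : component amplitudes (a.u.), >= 0
    q1..q3 : component spreads (deg^-2); q1, q2 > 0, q3 unrestricted in sign
    g1..g3 : component centre eccentricities (deg)
    """

    N1: float
    N2: float
    N3: float
    q1: float
    q2: float
    q3: float
    g1: float
    g2: float
    g3: float

    def __post_init__(self):
        vals = [getattr(self, f.name) for f in fields(self)]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidModelError(f"non-finite M3G parameter: {self}")
        if min(self.N1, self.N2, self.N3) < 0:
            raise InvalidModelError("M3G amplitudes must be non-negative")
        if self.q1 <= 0 or self.q2 <= 0:
            raise InvalidModelError("M3G spreads q1 and q2 must be positive")

    @property
    def N(self) -> np.ndarray:
        return np.array([self.N1, self.N2, self.N3], dtype=float)

    @property
    def q(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.q3], dtype=float)

    @property
    def g(self) -> np.ndarray:
        return np.array([self.g1, self.g2, self.g3], dtype=float)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.N1, self.N2, self.N3, self.q1, self.q2, self.q3,
             self.g1, self.g2, self.g3], dtype=float)

    def component(self, i: int) -> "M3GParams":
        """Copy of the parameters with all amplitudes but component ``i`` zeroed."""
        amps = [0.0, 0.0, 0.0]
        amps[i] = [self.N1, self.N2, self.N3][i]
        return M3GParams(*amps, self.q1, self.q2, self.q3, self.g1, self.g2, self.g3)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "M3GParams":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})

    @classmethod
    def from_array(cls, a) -> "M3GParams":
        return cls(*(float(v) for v in a))


class ModelKind(str, Enum):
    MEG = "meg"
    M3G = "m3g"


_PARAM_TYPE = {ModelKind.MEG: MEGParams, ModelKind.M3G: M3GParams}


@dataclass(frozen=True)
class ModelCurve:
    """A model family tag together with a matching parameter set."""

    kind: ModelKind
    params: MEGParams | M3GParams

    def __post_init__(self):
        kind = ModelKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not isinstance(self.params, _PARAM_TYPE[kind]):
            raise InvalidModelError(
                f"model kind {kind.value!r} does not match parameter type "
                f"{type(self.params).__name__}")

    def __call__(self, x):
        return eval_model(self, x)

    def to_dict(self) -> dict:
        return {"kind": self.kind.value, "params": self.params.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelCurve":
        kind = ModelKind(d["kind"])
        return cls(kind, _PARAM_TYPE[kind].from_dict(d["params"]))


#: M3G parameterisation fitted to a 48-eye cohort grand-mean profile
#: (printed to three decimals); the standard worked example throughout.
GRAND_MEAN_M3G = M3GParams(
    N1=0.200, N2=0.250, N3=0.039,
    q1=14.515, q2=1.700, q3=-0.020,
    g1=-0.017, g2=0.562, g3=10.000,
)


def _as_x(x) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("eccentricities must be finite")
    return x


def _gauss_terms(N, q, g, x, order: int) -> np.ndarray:
    """Derivative of order 0..4 of ``sum_i N_i exp(-q_i (x-g_i)^2)``."""
    u = x[:, None] - np.asarray(g)[None, :]
    q = np.asarray(q)[None, :]
    N = np.asarray(N)[None, :]
    e = N * np.exp(-q * u * u)
    if order == 0:
        t = e
    elif order == 1:
        t = -2.0 * q * u * e
    elif order == 2:
        t = (4.0 * q**2 * u**2 - 2.0 * q) * e
    elif order == 3:
        t = (12.0 * q**2 * u - 8.0 * q**3 * u**3) * e
    elif order == 4:
        t = (12.0 * q**2 - 48.0 * q**3 * u**2 + 16.0 * q**4 * u**4) * e
    else:  # pragma: no cover - internal guard
        raise ValueError(f"unsupported derivative order {order}")
    return t.sum(axis=1)


def _eval_deriv(curve: ModelCurve, x: np.ndarray, order: int) -> np.ndarray:
    p = curve.params
    if curve.kind is ModelKind.M3G:
        return _gauss_terms(p.N, p.q, p.g, x, order)
    # MEG: exponential derivative (-p1)^k A1 e^{-p1 x}, plus a Gaussian term
    expo = (-p.p1) ** order * p.A1 * np.exp(-p.p1 * x)
    gaus = _gauss_terms([p.A2], [p.p2], [p.x2], x, order)
    return expo + gaus


def eval_model(curve: ModelCurve, x) -> np.ndarray:
    """Evaluate an MPOD model at eccentricities ``x`` (degrees).

    Vectorised over ``x``; a scalar is treated as a length-1 array.  The
    returned values are MPOD in the same arbitrary optical-density units as
    the model amplitudes.
    """
    if not isinstance(curve, ModelCurve):
        raise InvalidModelError("eval_model expects a ModelCurve")
    return _eval_deriv(curve, _as_x(x), 0)


def model_derivative(curve: ModelCurve, x, order: int = 1) -> np.ndarray:
    """Closed-form derivative of the model with respect to eccentricity.

    Only orders 1 and 2 are part of the public contract (gradient and
    curvature of the MPOD profile); higher orders are used internally for
    critical-point refinement.
    """
    if order not in (1, 2):
        raise ValueError("model_derivative supports order 1 or 2")
    return _eval_deriv(curve, _as_x(x), order)


def meg_to_base10(params: MEGParams) -> MEGParams:
    """Convert base-e MEG amplitudes to the original base-10 convention.

    Divides ``A1`` and ``A2`` by ln(10); decay/spread/centre parameters are
    unchanged (the exponents carry the base change in the amplitudes only
    when the decay constants are reinterpreted as base-10 exponents).
    """
    return MEGParams(params.A1 / LN10, params.p1, params.A2 / LN10,
                     params.p2, params.x2)


def meg_from_base10(params: MEGParams) -> MEGParams:
    """Inverse of :func:`meg_to_base10`."""
    return MEGParams(params.A1 * LN10, params.p1, params.A2 * LN10,
                     params.p2, params.x2)
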