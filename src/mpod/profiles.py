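"""Radial MPOD profiles: file I/O, resampling and extraction from 2D maps.

A radial profile is MPOD (arbitrary optical-density units) sampled against
eccentricity (degrees of visual angle) from the foveolar centre, optionally
with a per-eccentricity standard deviation, as exported by dual-wavelength
autofluorescence instruments.  Profiles are stored as plain CSV.

2D MPOD maps are grayscale rasters with a known sub-pixel foveolar centre
and a degrees-per-pixel scale; profiles are extracted from them by averaging
the map along circular paths of increasing radius (circumferential mean and
standard deviation), the same construction the instruments use for their
machine-generated profile plots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ExtrapolationError, OutOfBoundsError, ProfileParseError

__all__ = [
    "RadialProfile",
    "MPODMap",
    "read_profile",
    "write_profile",
    "read_map",
    "write_map",
    "extract_radial_profile",
    "resample_profile",
    "default_radii",
]


@dataclass
class RadialProfile:
    """MPOD versus eccentricity for one eye.

    ecc : strictly increasing eccentricities (deg), ecc[0] >= 0
    mpod : MPOD values (a.u.), finite
    sd : optional per-point standard deviation (a.u.)
    eye_id : free-text label
    """

    ecc: np.ndarray
    mpod: np.ndarray
    sd: np.ndarray | None = None
    eye_id: str = ""

    def __post_init__(self):
        self.ecc = np.asarray(self.ecc, dtype=float)
        self.mpod = np.asarray(self.mpod, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.ecc.ndim != 1 or self.mpod.shape != self.ecc.shape:
            raise ValueError("ecc and mpod must be 1-D arrays of equal length")
        if self.sd is not None and self.sd.shape != self.ecc.shape:
            raise ValueError("sd must match ecc in length")
        if self.ecc.size:
            if self.ecc[0] < 0:
                raise ValueError("eccentricities must be non-negative")
            if np.any(np.diff(self.ecc) <= 0):
                raise ValueError("eccentricities must be strictly increasing")
        if not np.all(np.isfinite(self.mpod)):
            raise ValueError("MPOD values must be finite")

    def __len__(self) -> int:
        return self.ecc.size

    def window(self, lo: float, hi: float) -> "RadialProfile":
        """Sub-profile with lo <= ecc <= hi."""
        m = (self.ecc >= lo) & (self.ecc <= hi)
        sd = self.sd[m] if self.sd is not None else None
        return RadialProfile(self.ecc[m], self.mpod[m], sd, self.eye_id)


@dataclass
class MPODMap:
    """2D MPOD raster with geometry.

    pixels : 2D array of MPOD values (a.u.)
    center : (row, col) sub-pixel foveolar centre, 0-based
    scale : degrees of visual angle per pixel, > 0
    """

    pixels: np.ndarray
    center: tuple[float, float]
    scale: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.scale <= 0:
            raise ValueError("scale must be positive (degrees per pixel)")
        r, c = self.center
        nr, nc = self.pixels.shape
        if not (0 <= r <= nr - 1 and 0 <= c <= nc - 1):
            raise OutOfBoundsError(f"center {self.center} outside image {self.pixels.shape}")


def default_radii(rmin: float = 0.02, rmax: float = 6.0, step: float = 0.02) -> np.ndarray:
    """Default extraction radii: 0.02 deg steps out to 6 deg.

    The step oversamples the narrowest fitted profile feature (central
    component spreads up to ~180 deg^-2 correspond to a half-width of
    ~0.06 deg).
    """
    n = int(round((rmax - rmin) / step))
    return rmin + step * np.arange(n + 1)


def read_profile(path, dialect: dict | None = None) -> RadialProfile:
    """Read a radial profile from delimited text.

    ``dialect`` keys (all optional): ``sep`` (default ','), ``header``
    (default ``"auto"``: use a header row if the first cell is non-numeric),
    ``columns`` (names or indices of ecc/mpod/sd columns).

    Rows are sorted by eccentricity and duplicate eccentricities averaged.
    """
    dialect = dialect or {}
    sep = dialect.get("sep", ",")
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:
        raise ProfileParseError(f"cannot read {path}: {e}") from e
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ProfileParseError(f"{path}: empty file")

    header = dialect.get("header", "auto")
    if header == "auto":
        first = lines[0].split(sep)[0].strip()
        try:
            float(first)
            header = False
        except ValueError:
            header = True

    start = 1 if header else 0
    rows = []
    for i, ln in enumerate(lines[start:], start=start + 1):
        cells = [c.strip() for c in ln.split(sep)]
        if len(cells) < 2:
            raise ProfileParseError(f"{path}: row {i}: expected >= 2 columns")
        try:
            vals = [float(c) for c in cells if c != ""]
        except ValueError:
            raise ProfileParseError(f"{path}: row {i}: non-numeric cell") from None
        rows.append(vals)

    ncol = min(len(r) for r in rows)
    df = pd.DataFrame([r[:ncol] for r in rows])
    has_sd = ncol >= 3
    df.columns = ["ecc", "mpod", "sd"][:ncol] if ncol <= 3 else (
        ["ecc", "mpod", "sd"] + [f"extra{i}" for i in range(ncol - 3)])
    grouped = df.groupby("ecc", as_index=False).mean().sort_values("ecc")
    sd = grouped["sd"].to_numpy() if has_sd else None
    return RadialProfile(grouped["ecc"].to_numpy(), grouped["mpod"].to_numpy(),
                         sd, eye_id=path.stem)


def write_profile(profile: RadialProfile, path) -> None:
    """Write a profile as CSV (columns ecc_deg, mpod[, sd]; 9 significant digits)."""
    path = Path(path)
    cols = {"ecc_deg": profile.ecc, "mpod": profile.mpod}
    if profile.sd is not None:
        cols["sd"] = profile.sd
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.9g")


def write_map(mp: MPODMap, path) -> None:
    """Write a map as float32 TIFF plus a JSON sidecar with geometry."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, mp.pixels.astype(np.float32))
    sidecar = {"center": [float(mp.center[0]), float(mp.center[1])],
               "scale": float(mp.scale)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_map(path, center=None, scale=None) -> MPODMap:
    """Read a grayscale TIFF/PNG map; geometry from arguments or sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    pixels = np.asarray(iio.imread(path), dtype=float)
    if pixels.ndim == 3:
        pixels = pixels.mean(axis=2)
    if center is None or scale is None:
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        center = center or tuple(sidecar["center"])
        scale = scale or float(sidecar["scale"])
    return MPODMap(pixels, tuple(center), scale)


def extract_radial_profile(mp: MPODMap, radii, n_angles: int = 360) -> RadialProfile:
    """Circular-path averaging of a 2D MPOD map.

    For each radius (degrees) the map is sampled at ``n_angles`` equally
    spaced angles by bilinear interpolation; the circumferential mean becomes
    the profile value and the circumferential standard deviation the ``sd``
    field.  Radius 0 degenerates to the (interpolated) centre value with
    sd 0.
    """
    radii = np.sort(np.atleast_1d(np.asarray(radii, dtype=float)))
    if np.any(radii < 0):
        raise ValueError("radii must be non-negative")
    if n_angles < 8:
        raise ValueError("n_angles must be >= 8")
    nr, nc = mp.pixels.shape
    r0, c0 = mp.center
    theta = 2.0 * np.pi * np.arange(n_angles) / n_angles

    mean = np.empty_like(radii)
    sd = np.empty_like(radii)
    for k, rad in enumerate(radii):
        rp = rad / mp.scale
        rows = r0 + rp * np.sin(theta)
        cols = c0 + rp * np.cos(theta)
        if (rows.min() < 0 or rows.max() > nr - 1
                or cols.min() < 0 or cols.max() > nc - 1):
            raise OutOfBoundsError(
                f"circle of radius {rad:g} deg exits the image bounds")
        if rad == 0.0:
            v = ndimage.map_coordinates(mp.pixels, [[r0], [c0]], order=1)
            mean[k], sd[k] = float(v[0]), 0.0
            continue
        vals = ndimage.map_coordinates(mp.pixels, [rows, cols], order=1)
        mean[k] = vals.mean(dtype=np.float64)
        sd[k] = vals.std(dtype=np.float64)
    return RadialProfile(radii, mean, sd)


def resample_profile(profile: RadialProfile, grid) -> RadialProfile:
    """Linear interpolation of a profile onto ``grid`` (no extrapolation)."""
    grid = np.sort(np.atleast_1d(np.asarray(grid, dtype=float)))
    if grid.size and (grid[0] < profile.ecc[0] or grid[-1] > profile.ecc[-1]):
        raise ExtrapolationError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] extends beyond measured range "
            f"[{profile.ecc[0]:g}, {profile.ecc[-1]:g}]")
    mpod = np.interp(grid, profile.ecc, profile.mpod)
    sd = None
    if profile.sd is not None:
        sd = np.interp(grid, profile.ecc, profile.sd)
    return RadialProfile(grid, mpod, sd, profile.eye_id)
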