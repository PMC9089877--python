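"""Commissioning QA analytics: local gamma index and profile dosimetry.

The gamma index combines dose difference and distance-to-agreement: for a
reference point r with dose D(r), gamma(r) is the minimum over evaluated
points e of sqrt[(|e-r|/DTA)^2 + ((De-Dr)/(dd*Dr))^2] with *local*
normalization (the dose criterion scales with the local reference dose).
Points below a threshold fraction of the reference maximum are excluded.
Profile dosimetry extracts R90 (distal 90% depth), level widths (95/50/5%)
and 20-80% penumbrae with linear crossing interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "QAError", "DoseProfile", "DoseMap", "GammaParams", "ProfileMetrics",
    "gamma_1d", "gamma_2d", "pass_rate", "profile_metrics",
    "point_dose_difference",
]


class QAError(ValueError):
    pass


@dataclass(eq=False)
class DoseProfile:
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.values = np.asarray(self.values, float)
        if self.positions.size != self.values.size:
            raise QAError("positions/values length mismatch")
        if self.positions.size < 2:
            raise QAError("profile needs >= 2 points")
        if np.any(np.diff(self.positions) <= 0):
            raise QAError("positions must strictly increase")


@dataclass(eq=False)
class DoseMap:
    """2-D dose on a rectilinear grid; values shape (nx, ny)."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.x.size, self.y.size):
            raise QAError("values must be (nx, ny)")


@dataclass(frozen=True)
class GammaParams:
    """Gamma criterion: DTA (mm), dose difference (%), low-dose threshold
    (% of the reference maximum); normalization is local."""

    dta_mm: float = 2.0
    dose_diff_pct: float = 2.0
    threshold_pct: float = 10.0
    search_factor: float = 3.0   # search radius in units of DTA
    upsample: int = 10           # evaluated-profile refinement factor

    def __post_init__(self):
        if min(self.dta_mm, self.dose_diff_pct, self.threshold_pct) <= 0:
            raise QAError("gamma parameters must be positive")


def _upsample_profile(profile: DoseProfile, factor: int):
    """Linear refinement that keeps original nodes (so refinements nest)."""
    p, v = profile.positions, profile.values
    if factor <= 1:
        return p, v
    segs = [np.linspace(p[i], p[i + 1], factor + 1)[:-1]
            for i in range(p.size - 1)]
    fine = np.concatenate(segs + [p[-1:]])
    return fine, np.interp(fine, p, v)


def gamma_1d(reference: DoseProfile, evaluated: DoseProfile,
             params: GammaParams = GammaParams()) -> np.ndarray:
    """Per-reference-point local gamma; NaN where below threshold."""
    lo = max(reference.positions[0], evaluated.positions[0])
    hi = min(reference.positions[-1], evaluated.positions[-1])
    if lo >= hi:
        raise QAError("profiles do not overlap spatially")
    pe, ve = _upsample_profile(evaluated, params.upsample)
    thr = params.threshold_pct / 100.0 * float(np.max(reference.values))
    radius = params.search_factor * params.dta_mm
    out = np.full(reference.positions.size, np.nan)
    for i, (r, dr) in enumerate(zip(reference.positions, reference.values)):
        if dr < thr:
            continue
        near = np.abs(pe - r) <= radius
        if not np.any(near):
            near = np.array([np.argmin(np.abs(pe - r))])
        dist2 = ((pe[near] - r) / params.dta_mm) ** 2
        diff2 = ((ve[near] - dr) /
                 (params.dose_diff_pct / 100.0 * dr)) ** 2
        out[i] = math.sqrt(float(np.min(dist2 + diff2)))
    return out


def gamma_2d(reference: DoseMap, evaluated: DoseMap,
             params: GammaParams = GammaParams(3.0, 3.0),
             upsample_2d: int = 4) -> np.ndarray:
    """2-D local gamma map; NaN below threshold.

    The evaluated map is refined ``upsample_2d``-fold per axis by bilinear
    interpolation before the disc search (radius ``search_factor`` x DTA).
    """
    if reference.values.shape != evaluated.values.shape and (
            reference.x.size != evaluated.x.size):
        pass  # shapes may legitimately differ; geometry carries alignment
    fx = _refine_axis(evaluated.x, upsample_2d)
    fy = _refine_axis(evaluated.y, upsample_2d)
    interp = RegularGridInterpolator((evaluated.x, evaluated.y),
                                     evaluated.values)
    gx, gy = np.meshgrid(fx, fy, indexing="ij")
    fine = interp(np.stack([gx.ravel(), gy.ravel()], axis=1)).reshape(
        fx.size, fy.size)
    thr = params.threshold_pct / 100.0 * float(np.max(reference.values))
    radius = params.search_factor * params.dta_mm
    out = np.full(reference.values.shape, np.nan)
    inv_dta2 = 1.0 / params.dta_mm ** 2
    for i, rx in enumerate(reference.x):
        jx0 = int(np.searchsorted(fx, rx - radius))
        jx1 = int(np.searchsorted(fx, rx + radius, side="right"))
        dx2 = (fx[jx0:jx1] - rx) ** 2
        for j, ry in enumerate(reference.y):
            dr = reference.values[i, j]
            if dr < thr:
                continue
            jy0 = int(np.searchsorted(fy, ry - radius))
            jy1 = int(np.searchsorted(fy, ry + radius, side="right"))
            if jx0 >= jx1 or jy0 >= jy1:
                continue
            dy2 = (fy[jy0:jy1] - ry) ** 2
            dist2 = (dx2[:, None] + dy2[None, :]) * inv_dta2
            diff2 = ((fine[jx0:jx1, jy0:jy1] - dr)
                     / (params.dose_diff_pct / 100.0 * dr)) ** 2
            out[i, j] = math.sqrt(float(np.min(dist2 + diff2)))
    return out


def _refine_axis(axis: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1:
        return axis
    segs = [np.linspace(axis[i], axis[i + 1], factor + 1)[:-1]
            for i in range(axis.size - 1)]
    return np.concatenate(segs + [axis[-1:]])


def pass_rate(gamma_values, criterion: float = 1.0) -> float:
    """Percent of analyzed (non-NaN) points with gamma <= criterion."""
    g = np.asarray(gamma_values, float).ravel()
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise QAError("no analyzed points above threshold")
    return 100.0 * float(np.mean(g <= criterion))


@dataclass(frozen=True)
class ProfileMetrics:
    r90: float | None
    width_95: float | None
    width_50: float | None
    width_5: float | None
    penumbra_left: float | None
    penumbra_right: float | None


def _crossings(positions, values, level):
    """All linearly interpolated crossings of ``level``, ascending."""
    v = values - level
    out = []
    for i in range(v.size - 1):
        a, b = v[i], v[i + 1]
        if a == 0.0:
            out.append(positions[i])
        if (a < 0 < b) or (a > 0 > b):
            out.append(positions[i]
                       + a / (a - b) * (positions[i + 1] - positions[i]))
    if v[-1] == 0.0:
        out.append(positions[-1])
    return out


def profile_metrics(profile: DoseProfile, kind: str = "lateral"
                    ) -> ProfileMetrics:
    """R90, 95/50/5% widths and per-edge 20-80% penumbrae.

    Levels are relative to the profile maximum.  Depth profiles take the
    distal (falling-edge) 90% crossing as R90; lateral widths span the
    outermost crossings of each level.  A level that is never crossed
    yields None rather than a fabricated number.
    """
    if kind not in ("depth", "lateral"):
        raise QAError(f"unknown profile kind {kind!r}")
    p, v = profile.positions, profile.values
    vmax = float(np.max(v))
    if vmax <= 0:
        raise QAError("profile maximum must be positive")
    imax = int(np.argmax(v))

    def width(level_frac):
        c = _crossings(p, v, level_frac * vmax)
        if len(c) < 2:
            return None
        return float(c[-1] - c[0])

    def distal(level_frac):
        c = [x for x in _crossings(p, v, level_frac * vmax) if x >= p[imax]]
        return float(c[-1]) if c else None

    def edge_penumbra(side):
        if side == "left":
            c20 = [x for x in _crossings(p, v, 0.2 * vmax) if x <= p[imax]]
            c80 = [x for x in _crossings(p, v, 0.8 * vmax) if x <= p[imax]]
            if not c20 or not c80:
                return None
            return float(abs(c80[0] - c20[0]))
        c20 = [x for x in _crossings(p, v, 0.2 * vmax) if x >= p[imax]]
        c80 = [x for x in _crossings(p, v, 0.8 * vmax) if x >= p[imax]]
        if not c20 or not c80:
            return None
        return float(abs(c20[-1] - c80[-1]))

    return ProfileMetrics(
        r90=distal(0.9),
        width_95=width(0.95), width_50=width(0.5), width_5=width(0.05),
        penumbra_left=edge_penumbra("left"),
        penumbra_right=edge_penumbra("right"))


def point_dose_difference(reference: DoseProfile, evaluated: DoseProfile,
                          position: float) -> float:
    """Local dose difference (%) at an interpolated position."""
    for prof in (reference, evaluated):
        if not prof.positions[0] <= position <= prof.positions[-1]:
            raise QAError(f"position {position} outside profile")
    r = float(np.interp(position, reference.positions, reference.values))
    e = float(np.interp(position, evaluated.positions, evaluated.values))
    if r == 0.0:
        raise QAError("reference dose is zero at the requested position")
    return 100.0 * (e - r) / r
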