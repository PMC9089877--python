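"""Pencil-beam dose engine for scanned carbon-ion beams.

Coordinate convention: the beam axis is z, the isocenter plane is z = 0 and
+z points toward the source; the beam travels in -z.  x and y are the
transverse scanning axes.  A voxel phantom stores stopping power relative
to water (RSP); the engine converts geometric depth to water-equivalent
depth by ray tracing, evaluates the three integral-depth-dose components on
that effective depth, and spreads each laterally with a normalized 2-D
Gaussian.  Component 1 (the primary carbon beam) is split once, at a plane
700 mm upstream of the isocenter, into N x N deflected sub-beams so that
lateral heterogeneity off the spot axis is sampled; components 2 and 3 (the
fragment halo) see density information only along the spot's central axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .beam_data import (BeamDataLibrary, PencilBeamKernel,
                        fragment_ratio_at_depth, idd_at_depth)

__all__ = [
    "DoseEngineError", "VoxelPhantom", "Spot", "SubBeam", "DoseGrid",
    "ControlPoint", "TransitDeposit", "MUCalibration",
    "water_box", "build_slab_phantom", "heterogeneous_slab_phantom",
    "effective_depth", "lateral_gaussian", "sigma_at_depth", "split_beam",
    "compute_dose", "compute_field_dose_water", "dose_components",
    "transit_dose", "sequence_control_points", "mu_calibration",
    "mu_for_reference_dose", "depth_dose_profile",
]

SPLIT_PLANE_MM = 700.0
_SIGMA_REACH = 4.5  # lateral evaluation window in units of sigma


class DoseEngineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# geometry

@dataclass(eq=False)
class VoxelPhantom:
    """RSP-per-voxel grid; ``values`` has shape (nx, ny, nz).

    ``origin`` is the coordinate of the center of voxel (0, 0, 0); axes are
    sorted ascending.  The beam enters through the +z face.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise DoseEngineError("phantom values must be 3-D (nx, ny, nz)")
        if min(self.spacing) <= 0:
            raise DoseEngineError("voxel spacing must be positive")
        if np.any(self.values < 0):
            raise DoseEngineError("RSP must be non-negative")

    @property
    def shape(self):
        return self.values.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    @property
    def z_top_face(self) -> float:
        """z of the upstream (entry) face of the grid."""
        zc = self.axis_centers(2)
        return zc[-1] + self.spacing[2] / 2.0

    def is_uniform(self) -> bool:
        v = self.values
        return bool(np.all(v == v.flat[0]))


def water_box(lateral_mm: float = 160.0, depth_mm: float = 160.0,
              spacing: float = 2.0, surface_z: float = 0.0,
              rsp: float = 1.0) -> VoxelPhantom:
    """Uniform phantom with its entry surface at ``surface_z``.

    Lateral extent is centered on the beam axis; depth extends downstream
    (toward -z) from the surface.
    """
    n_lat = int(round(lateral_mm / spacing))
    n_z = int(round(depth_mm / spacing))
    # keep the beam axis (x = y = 0) on a voxel center
    x0 = -(n_lat // 2) * spacing
    z0 = surface_z - depth_mm + spacing / 2.0
    return VoxelPhantom(values=np.full((n_lat, n_lat, n_z), rsp),
                        spacing=(spacing,) * 3,
                        origin=(x0, x0, z0))


def build_slab_phantom(regions, bounds, spacing: float = 2.0,
                       default_rsp: float = 0.0) -> VoxelPhantom:
    """Voxelize box regions ``(x0, x1, y0, y1, z0, z1, rsp)``.

    Voxel membership is decided by voxel-center containment; a voxel whose
    center falls inside two regions is an error (overlap).
    """
    (xlo, xhi), (ylo, yhi), (zlo, zhi) = bounds
    nx = int(round((xhi - xlo) / spacing))
    ny = int(round((yhi - ylo) / spacing))
    nz = int(round((zhi - zlo) / spacing))
    origin = (xlo + spacing / 2, ylo + spacing / 2, zlo + spacing / 2)
    xc = origin[0] + spacing * np.arange(nx)
    yc = origin[1] + spacing * np.arange(ny)
    zc = origin[2] + spacing * np.arange(nz)
    values = np.full((nx, ny, nz), default_rsp)
    covered = np.zeros((nx, ny, nz), dtype=int)
    for (x0, x1, y0, y1, z0, z1, rsp) in regions:
        if x1 <= x0 or y1 <= y0 or z1 <= z0:
            raise DoseEngineError("region extents must be positive")
        mx = (xc >= x0) & (xc < x1)
        my = (yc >= y0) & (yc < y1)
        mz = (zc >= z0) & (zc < z1)
        sel = np.ix_(np.nonzero(mx)[0], np.nonzero(my)[0], np.nonzero(mz)[0])
        covered[sel] += 1
        values[sel] = rsp
    if np.any(covered > 1):
        raise DoseEngineError("overlapping regions in slab phantom spec")
    return VoxelPhantom(values=values, spacing=(spacing,) * 3, origin=origin)


# RSP of the heterogeneity-phantom materials (acrylic / lung- /
# bone-equivalent) and its layout: a 150x150x20 mm slab holding two
# 30x30x20 mm columns, a 40 mm air gap, then water.
ACRYLIC_RSP = 1.16
LUNG_RSP = 0.11
BONE_RSP = 1.37
AIR_RSP = 0.001


def heterogeneous_slab_phantom(spacing: float = 2.0,
                               water_depth: float = 160.0) -> VoxelPhantom:
    """Three-column slab phantom: lung column at x = -30 mm, bone column at
    x = +30 mm, acrylic elsewhere; slab at z in [40, 60] mm, 40 mm air gap,
    water surface at z = 0 (isocenter plane)."""
    xlo, xhi = -80.0, 80.0
    zlo, zhi = -water_depth, 60.0
    nx = int(round((xhi - xlo) / spacing))
    nz = int(round((zhi - zlo) / spacing))
    origin = (xlo + spacing / 2, xlo + spacing / 2, zlo + spacing / 2)
    xc = origin[0] + spacing * np.arange(nx)
    zc = origin[2] + spacing * np.arange(nz)
    values = np.zeros((nx, nx, nz))
    in_water = zc < 0.0
    in_gap = (zc >= 0.0) & (zc < 40.0)
    in_slab = (zc >= 40.0) & (zc < 60.0)
    values[:, :, in_water] = 1.0
    values[:, :, in_gap] = AIR_RSP
    in_plate_x = np.abs(xc) < 75.0
    lung_x = (xc >= -45.0) & (xc < -15.0)
    bone_x = (xc >= 15.0) & (xc < 45.0)
    col_y = np.abs(xc) < 15.0
    slab = np.full((nx, nx), AIR_RSP)
    slab[np.ix_(in_plate_x, in_plate_x)] = ACRYLIC_RSP
    slab[np.ix_(lung_x, col_y)] = LUNG_RSP
    slab[np.ix_(bone_x, col_y)] = BONE_RSP
    values[:, :, in_slab] = slab[:, :, None]
    return VoxelPhantom(values=values, spacing=(spacing,) * 3, origin=origin)


# ---------------------------------------------------------------------------
# plan entities

@dataclass(frozen=True)
class Spot:
    """One scanning spot: position at the isocenter plane, nominal energy
    index into the beam library, weight in MU, and an optional range-shifter
    water-equivalent offset."""

    x: float
    y: float
    energy_index: int
    w: float
    rs_weq: float = 0.0

    def __post_init__(self):
        if self.w < 0:
            raise DoseEngineError("spot MU must be non-negative")


@dataclass(frozen=True)
class SubBeam:
    parent: Spot
    weight: float
    x0: float          # lateral offset at the split plane, x
    y0: float
    slope_x: float     # deflection, mm lateral per mm traveled toward -z
    slope_y: float
    cov_x: tuple       # (S_xx, S_xt, S_tt) at the split plane
    cov_y: tuple

    def center_at(self, z):
        t = SPLIT_PLANE_MM - np.asarray(z, float)
        return (self.parent.x + self.x0 + self.slope_x * t,
                self.parent.y + self.y0 + self.slope_y * t)

    def optics_var_at(self, z, axis: str):
        s = self.cov_x if axis == "x" else self.cov_y
        t = SPLIT_PLANE_MM - np.asarray(z, float)
        return s[0] + 2.0 * t * s[1] + t * t * s[2]


@dataclass(eq=False)
class DoseGrid:
    """Dose scored on the phantom geometry (Gy per voxel).

    When component tracking is on, ``carbon`` and ``fragment`` partition the
    physical dose exactly, and ``alpha_num``/``beta_num`` hold the
    dose-weighted LQM accumulators used by the radiobiology chain.
    """

    spacing: tuple
    origin: tuple
    physical: np.ndarray
    carbon: np.ndarray | None = None
    fragment: np.ndarray | None = None
    alpha_num: np.ndarray | None = None
    beta_num: np.ndarray | None = None

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.physical.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass(frozen=True)
class ControlPoint:
    index: int
    first_spot: int
    last_spot: int
    current: float      # MU/s
    reason: str
    period: float       # s


@dataclass(frozen=True)
class TransitDeposit:
    x: float
    y: float
    mu: float


# ---------------------------------------------------------------------------
# ray tracing

def effective_depth(phantom: VoxelPhantom, entry, direction, point) -> float:
    """Water-equivalent path length from ``entry`` to ``point`` (mm).

    Line integral of RSP with nearest-voxel sampling at quarter-voxel
    steps; space outside the grid contributes nothing.
    """
    d = np.asarray(direction, float)
    norm = float(np.linalg.norm(d))
    if norm == 0.0:
        raise DoseEngineError("direction must be a non-zero vector")
    d = d / norm
    entry = np.asarray(entry, float)
    point = np.asarray(point, float)
    dist = float(np.dot(point - entry, d))
    if dist <= 0:
        return 0.0
    step = min(phantom.spacing) / 4.0
    n = max(1, int(math.ceil(dist / step)))
    step = dist / n
    s = (np.arange(n) + 0.5) * step
    pts = entry[None, :] + s[:, None] * d[None, :]
    idx = []
    inside = np.ones(n, dtype=bool)
    for ax in range(3):
        i = np.round((pts[:, ax] - phantom.origin[ax])
                     / phantom.spacing[ax]).astype(int)
        inside &= (i >= 0) & (i < phantom.shape[ax])
        idx.append(np.clip(i, 0, phantom.shape[ax] - 1))
    rsp = phantom.values[idx[0], idx[1], idx[2]]
    return float(np.sum(rsp[inside]) * step)


def _wepl_profile(phantom: VoxelPhantom, x_split: float, y_split: float,
                  slope_x: float, slope_y: float) -> np.ndarray:
    """Water-equivalent depth at each z-plane center along a (possibly
    tilted) ray parameterized by its position at the split plane."""
    zc = phantom.axis_centers(2)
    dz = phantom.spacing[2]
    t = SPLIT_PLANE_MM - zc
    xs = x_split + slope_x * t
    ys = y_split + slope_y * t
    ix = np.round((xs - phantom.origin[0]) / phantom.spacing[0]).astype(int)
    iy = np.round((ys - phantom.origin[1]) / phantom.spacing[1]).astype(int)
    ok = ((ix >= 0) & (ix < phantom.shape[0])
          & (iy >= 0) & (iy < phantom.shape[1]))
    rsp = np.zeros(zc.size)
    rsp[ok] = phantom.values[ix[ok], iy[ok], np.arange(zc.size)[ok]]
    # accumulate from the entry (+z) side; the plane value gets half its
    # own voxel
    csum = np.cumsum(rsp[::-1])[::-1] * dz
    return csum - 0.5 * rsp * dz


# ---------------------------------------------------------------------------
# lateral kernel and beam splitting

def lateral_gaussian(x, y, cx, cy, sigma_x, sigma_y):
    """Normalized bivariate Gaussian (plane integral = 1), mm^-2."""
    if np.any(np.asarray(sigma_x) <= 0) or np.any(np.asarray(sigma_y) <= 0):
        raise DoseEngineError("sigma must be positive")
    gx = np.exp(-((np.asarray(x) - cx) ** 2) / (2.0 * sigma_x ** 2))
    gy = np.exp(-((np.asarray(y) - cy) ** 2) / (2.0 * sigma_y ** 2))
    return gx * gy / (2.0 * np.pi * sigma_x * sigma_y)


def _mcs_sigma(kernel: PencilBeamKernel, weq):
    p = kernel.sigma_mcs_params
    return p["coeff"] * np.maximum(np.asarray(weq, float), 0.0) ** p["power"]


def _fragment_sigma(kernel: PencilBeamKernel, n: int, weq):
    p = kernel.sigma_fragment_params
    if n == 2:
        return p["s2_0"] + p["s2_k"] * np.asarray(weq, float)
    return p["s3_0"] + p["s3_k"] * np.asarray(weq, float)


def _optics_cov(kernel: PencilBeamKernel, axis: str):
    """Per-axis phase-space covariance at the split plane (waist at z=0)."""
    o = kernel.sigma_optics
    sig = o[f"sigma_{axis}"]
    th = o[f"theta_{axis}"]
    L = SPLIT_PLANE_MM
    return (sig * sig + th * th * L * L, -th * th * L, th * th)


def sigma_at_depth(kernel: PencilBeamKernel, n: int, z, weq):
    """(sigma_x, sigma_y) of component n at plane z with medium depth weq.

    Component 1 combines the optics drift term (waist at the isocenter)
    with in-medium multiple-Coulomb-scattering growth in quadrature;
    components 2 and 3 are isotropic and grow linearly with depth.
    """
    if n not in (1, 2, 3):
        raise DoseEngineError(f"component index must be 1..3, got {n}")
    z = np.asarray(z, float)
    if n == 1:
        o = kernel.sigma_optics
        mcs2 = _mcs_sigma(kernel, weq) ** 2
        sx = np.sqrt(o["sigma_x"] ** 2 + (o["theta_x"] * z) ** 2 + mcs2)
        sy = np.sqrt(o["sigma_y"] ** 2 + (o["theta_y"] * z) ** 2 + mcs2)
        return sx, sy
    s = _fragment_sigma(kernel, n, weq)
    return s, s


@lru_cache(maxsize=32)
def _subsigma_fraction(n_per_axis: int, tol: float = 0.005) -> float:
    """Smallest sub-beam variance fraction f^2 for which the N-node
    Gauss-Hermite mixture stays within ``tol`` of the parent Gaussian
    density (sup norm, relative to the parent peak)."""
    if n_per_axis <= 1:
        return 1.0
    h, wh = np.polynomial.hermite.hermgauss(n_per_axis)
    w = wh / math.sqrt(math.pi)
    x = np.linspace(0.0, 6.0, 1201)
    parent = np.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)

    def sup_err(f2):
        mu = math.sqrt(2.0 * (1.0 - f2)) * h
        s = math.sqrt(f2)
        dens = np.sum(w[:, None] * np.exp(
            -((x[None, :] - mu[:, None]) ** 2) / (2 * f2))
            / (s * math.sqrt(2 * math.pi)), axis=0)
        return float(np.max(np.abs(dens - parent))) * math.sqrt(2 * math.pi)

    lo, hi = 1.0 / n_per_axis ** 2, 1.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if sup_err(mid) < tol:
            hi = mid
        else:
            lo = mid
    return hi


def _axis_split(cov, n: int):
    """Split one phase-space axis into n sub-beams (offset, slope, weight,
    sub-covariance); the weighted mixture preserves moments up to order 5."""
    sxx, sxt, stt = cov
    if n == 1:
        return [(0.0, 0.0, 1.0, cov)]
    f2 = _subsigma_fraction(n)
    h, wh = np.polynomial.hermite.hermgauss(n)
    w = wh / math.sqrt(math.pi)
    spread = (1.0 - f2) * sxx
    sub_cov = (f2 * sxx, f2 * sxt, stt - (1.0 - f2) * sxt * sxt / sxx)
    out = []
    for hk, wk in zip(h, w):
        mu = math.sqrt(2.0 * spread) * hk
        slope = (sxt / sxx) * mu
        out.append((mu, slope, wk, sub_cov))
    return out


def split_beam(spot: Spot, kernel: PencilBeamKernel, n_per_axis: int = 3,
               split_plane: float = SPLIT_PLANE_MM) -> list[SubBeam]:
    """Split the first component into n x n deflected sub-beams.

    Splitting happens once, at the plane ``split_plane`` mm upstream of the
    isocenter, by Gauss-Hermite decomposition of the per-axis phase-space
    Gaussian; sub-beam weights multiply across axes and sum to 1.
    """
    if n_per_axis < 1:
        raise DoseEngineError("n_per_axis must be >= 1")
    if split_plane != SPLIT_PLANE_MM:
        # the split plane enters the covariance propagation globally
        raise DoseEngineError("only the 700 mm split plane is supported")
    cov_x = _optics_cov(kernel, "x")
    cov_y = _optics_cov(kernel, "y")
    subs = []
    for (mx, slx, wx, cx) in _axis_split(cov_x, n_per_axis):
        for (my, sly, wy, cy) in _axis_split(cov_y, n_per_axis):
            subs.append(SubBeam(parent=spot, weight=wx * wy,
                                x0=mx, y0=my, slope_x=slx, slope_y=sly,
                                cov_x=cx, cov_y=cy))
    return subs


# ---------------------------------------------------------------------------
# dose computation

def dose_components(f1g1: float, f2g2: float, f3g3: float, ratio: float):
    """Partition one spot contribution into (carbon, fragment) doses.

    Carbon gets component 1 plus the carbon share (1-R) of component 2;
    fragments get the rest; the sum equals the total exactly.
    """
    r = np.asarray(ratio, float)
    if np.any((r < 0) | (r > 1)):
        raise DoseEngineError("fragment ratio must lie in [0, 1]")
    d_c = f1g1 + (1.0 - r) * f2g2
    d_f = r * f2g2 + f3g3
    return d_c, d_f


def _check_spot(spot: Spot, library: BeamDataLibrary):
    fx, fy = library.machine.field_max
    if abs(spot.x) > fx / 2 or abs(spot.y) > fy / 2:
        raise DoseEngineError(
            f"spot ({spot.x}, {spot.y}) outside the {fx} x {fy} mm field")
    library.kernel(spot.energy_index)


class _Scorer:
    def __init__(self, phantom: VoxelPhantom, track: bool, lqm=None):
        shape = phantom.shape
        self.phantom = phantom
        self.track = track
        self.lqm = lqm
        if track:
            self.carbon = np.zeros(shape)
            self.fragment = np.zeros(shape)
            self.alpha_num = np.zeros(shape) if lqm else None
            self.beta_num = np.zeros(shape) if lqm else None
            self.physical = None
        else:
            self.physical = np.zeros(shape)
            self.carbon = self.fragment = None
            self.alpha_num = self.beta_num = None

    def add(self, w, f_z, cx_z, cy_z, sx_z, sy_z, carbon_w, frag_w,
            let_c=None, let_f=None):
        ph = self.phantom
        xc, yc = ph.axis_centers(0), ph.axis_centers(1)
        reach_x = _SIGMA_REACH * float(np.max(sx_z))
        reach_y = _SIGMA_REACH * float(np.max(sy_z))
        ix0 = int(np.searchsorted(xc, np.min(cx_z) - reach_x))
        ix1 = int(np.searchsorted(xc, np.max(cx_z) + reach_x))
        iy0 = int(np.searchsorted(yc, np.min(cy_z) - reach_y))
        iy1 = int(np.searchsorted(yc, np.max(cy_z) + reach_y))
        if ix0 >= ix1 or iy0 >= iy1:
            return
        xs = xc[ix0:ix1]
        ys = yc[iy0:iy1]
        gx = np.exp(-((xs[None, :] - cx_z[:, None]) ** 2)
                    / (2.0 * sx_z[:, None] ** 2)) / (
            np.sqrt(2 * np.pi) * sx_z[:, None])
        gy = np.exp(-((ys[None, :] - cy_z[:, None]) ** 2)
                    / (2.0 * sy_z[:, None] ** 2)) / (
            np.sqrt(2 * np.pi) * sy_z[:, None])
        sl = (slice(ix0, ix1), slice(iy0, iy1), slice(None))

        def dep(target, fz):
            target[sl] += np.einsum("z,zx,zy->xyz", w * fz, gx, gy,
                                    optimize=True)

        if not self.track:
            dep(self.physical, f_z)
            return
        dep(self.carbon, f_z * carbon_w)
        dep(self.fragment, f_z * frag_w)
        if self.lqm is not None:
            table_c, table_f = self.lqm
            a_c = np.interp(let_c, table_c.let, table_c.alpha)
            b_c = np.interp(let_c, table_c.let, table_c.beta)
            a_f = np.interp(let_f, table_f.let, table_f.alpha)
            b_f = np.interp(let_f, table_f.let, table_f.beta)
            dep(self.alpha_num, f_z * (carbon_w * a_c + frag_w * a_f))
            dep(self.beta_num, f_z * (carbon_w * b_c + frag_w * b_f))

    def result(self, phantom: VoxelPhantom) -> DoseGrid:
        if self.track:
            physical = self.carbon + self.fragment
        else:
            physical = self.physical
        return DoseGrid(spacing=phantom.spacing, origin=phantom.origin,
                        physical=physical, carbon=self.carbon,
                        fragment=self.fragment, alpha_num=self.alpha_num,
                        beta_num=self.beta_num)


def compute_dose(plan: list[Spot], phantom: VoxelPhantom,
                 library: BeamDataLibrary, n_split: int = 3,
                 track_components: bool = False, lqm=None) -> DoseGrid:
    """Sum the triple-Gaussian spot doses of a plan over the phantom.

    Component 1 is evaluated per sub-beam with each sub-beam's own
    effective depth along its deflected axis; components 2 and 3 use the
    effective depth of the spot's central axis.  ``lqm`` is an optional
    pair of (carbon, fragment) LQM tables; when given (together with
    ``track_components``) the dose-weighted alpha/beta accumulators for the
    mixed-beam model are scored as well.
    """
    if lqm is not None:
        track_components = True
    scorer = _Scorer(phantom, track_components, lqm)
    zc = phantom.axis_centers(2)
    for spot in plan:
        if spot.w == 0.0:
            continue
        _check_spot(spot, library)
        kernel = library.kernel(spot.energy_index)
        corr = kernel.absolute_correction
        weq_axis = _wepl_profile(phantom, spot.x, spot.y, 0.0, 0.0)
        weq_axis = weq_axis + spot.rs_weq
        ratio = fragment_ratio_at_depth(kernel, weq_axis)
        let_c = np.interp(weq_axis, kernel.depth_grid, kernel.letd_carbon)
        let_f = np.interp(weq_axis, kernel.depth_grid, kernel.letd_fragment)
        ones = np.ones_like(zc)
        for n in (2, 3):
            f = idd_at_depth(kernel, n, weq_axis) * corr
            s, _ = sigma_at_depth(kernel, n, zc, weq_axis)
            cw = (1.0 - ratio) if n == 2 else np.zeros_like(ratio)
            fw = ratio if n == 2 else np.ones_like(ratio)
            scorer.add(spot.w, f, spot.x * ones, spot.y * ones, s, s,
                       cw, fw, let_c, let_f)
        for sb in split_beam(spot, kernel, n_split):
            weq = _wepl_profile(phantom, spot.x + sb.x0, spot.y + sb.y0,
                                sb.slope_x, sb.slope_y) + spot.rs_weq
            f1 = idd_at_depth(kernel, 1, weq) * corr
            mcs2 = _mcs_sigma(kernel, weq) ** 2
            sx = np.sqrt(sb.optics_var_at(zc, "x") + mcs2)
            sy = np.sqrt(sb.optics_var_at(zc, "y") + mcs2)
            cx, cy = sb.center_at(zc)
            lc = np.interp(weq, kernel.depth_grid, kernel.letd_carbon)
            lf = np.interp(weq, kernel.depth_grid, kernel.letd_fragment)
            scorer.add(spot.w * sb.weight, f1, cx, cy, sx, sy,
                       np.ones_like(weq), np.zeros_like(weq), lc, lf)
    return scorer.result(phantom)


def compute_field_dose_water(plan: list[Spot], phantom: VoxelPhantom,
                             library: BeamDataLibrary) -> DoseGrid:
    """Layered fast path for a uniform phantom and a Cartesian spot map.

    Exploits translation invariance in a homogeneous medium: within an
    energy layer whose spots form an x-grid times y-grid with equal MU, the
    lateral sum of Gaussians separates into per-axis convolutions on the
    voxel lattice.  Identical (to rounding) to the per-spot sum with
    ``n_split=1``; valid only for untilted beams without range shifters.
    """
    if not phantom.is_uniform():
        raise DoseEngineError("fast path requires a uniform phantom")
    if any(s.rs_weq != 0.0 for s in plan):
        raise DoseEngineError("fast path does not support range shifters")
    rsp = float(phantom.values.flat[0])
    zc = phantom.axis_centers(2)
    weq = (phantom.z_top_face - zc) * rsp  # depth from entry face to center
    xc, yc = phantom.axis_centers(0), phantom.axis_centers(1)
    dose = np.zeros(phantom.shape)

    layers: dict[tuple, list[Spot]] = {}
    for s in plan:
        if s.w == 0.0:
            continue
        _check_spot(s, library)
        layers.setdefault((s.energy_index, s.w), []).append(s)

    for (ei, w), spots in layers.items():
        kernel = library.kernel(ei)
        corr = kernel.absolute_correction
        uxs = np.array(sorted({s.x for s in spots}))
        uys = np.array(sorted({s.y for s in spots}))
        if len(spots) != uxs.size * uys.size:
            raise DoseEngineError("fast path requires a full Cartesian "
                                  "spot grid per layer")
        ix = np.round((uxs - phantom.origin[0]) / phantom.spacing[0])
        iy = np.round((uys - phantom.origin[1]) / phantom.spacing[1])
        if (np.max(np.abs(uxs - (phantom.origin[0] + ix * phantom.spacing[0])))
                > 1e-9 or
            np.max(np.abs(uys - (phantom.origin[1] + iy * phantom.spacing[1])))
                > 1e-9):
            raise DoseEngineError("fast path requires voxel-aligned spots")
        comb_x = np.zeros(xc.size)
        comb_y = np.zeros(yc.size)
        comb_x[ix.astype(int)] = 1.0
        comb_y[iy.astype(int)] = 1.0
        for n in (1, 2, 3):
            f = idd_at_depth(kernel, n, weq) * corr
            sx, sy = sigma_at_depth(kernel, n, zc, weq)
            sx = np.broadcast_to(np.asarray(sx, float), zc.shape)
            sy = np.broadcast_to(np.asarray(sy, float), zc.shape)
            for iz in range(zc.size):
                if f[iz] == 0.0:
                    continue
                kx = _lattice_gauss(sx[iz], phantom.spacing[0])
                ky = _lattice_gauss(sy[iz], phantom.spacing[1])
                gx = np.convolve(comb_x, kx)[
                    (kx.size - 1) // 2:][:comb_x.size]
                gy = np.convolve(comb_y, ky)[
                    (ky.size - 1) // 2:][:comb_y.size]
                dose[:, :, iz] += (w * f[iz]) * np.outer(gx, gy)
    return DoseGrid(spacing=phantom.spacing, origin=phantom.origin,
                    physical=dose)


def _lattice_gauss(sigma: float, dx: float) -> np.ndarray:
    k = int(math.ceil(_SIGMA_REACH * sigma / dx))
    u = np.arange(-k, k + 1) * dx
    return np.exp(-u * u / (2 * sigma * sigma)) / (
        math.sqrt(2 * math.pi) * sigma)


def depth_dose_profile(grid: DoseGrid, x: float, y: float):
    """(depth below entry face, dose) along -z at lateral position (x, y)."""
    xc, yc = grid.axis_centers(0), grid.axis_centers(1)
    ix = int(np.argmin(np.abs(xc - x)))
    iy = int(np.argmin(np.abs(yc - y)))
    zc = grid.axis_centers(2)
    z_face = zc[-1] + grid.spacing[2] / 2.0
    depth = z_face - zc
    order = np.argsort(depth)
    return depth[order], grid.physical[ix, iy, :][order]


# ---------------------------------------------------------------------------
# transit dose and control points

def transit_dose(path_xy, speeds, current: float,
                 max_spacing: float = 1.0) -> list[list[TransitDeposit]]:
    """MU deposited while the beam moves between consecutive spots.

    Each segment's period is set by the slower scanning axis; its MU is
    current x period, spread over equally spaced point deposits no farther
    apart than ``max_spacing`` mm.
    """
    vx, vy = speeds
    out = []
    pts = [np.asarray(p, float) for p in path_xy]
    for a, b in zip(pts[:-1], pts[1:]):
        dxy = b - a
        length = float(np.hypot(*dxy))
        if length == 0.0:
            out.append([])
            continue
        if (abs(dxy[0]) > 0 and vx <= 0) or (abs(dxy[1]) > 0 and vy <= 0):
            raise DoseEngineError("zero scan speed on a moving axis")
        period = max(abs(dxy[0]) / vx if vx > 0 else 0.0,
                     abs(dxy[1]) / vy if vy > 0 else 0.0)
        mu = current * period
        n = max(1, int(math.ceil(length / max_spacing)))
        frac = (np.arange(n) + 0.5) / n
        out.append([TransitDeposit(x=float(a[0] + f * dxy[0]),
                                   y=float(a[1] + f * dxy[1]),
                                   mu=mu / n) for f in frac])
    return out


def sequence_control_points(plan: list[Spot], machine,
                            current: float | None = None,
                            speeds=(2.0e4, 2.0e4),
                            spm_threshold: float = 0.00018,
                            short_dose_threshold: float = 0.00018,
                            stop_time_s: float = 90e-6,
                            ratio_tol: float = 0.01) -> list[ControlPoint]:
    """Cut the ordered spot sequence into control points.

    A new control point starts at: (1) a stationary spot dose below the
    short-dose threshold; (2) a change of range (different energy); (3) a
    beam-stop time strictly below 90 us; (4) a moving-segment dose below
    the 0.00018 MU spot-position-monitor threshold; (5) a stopping:moving
    dose ratio away from 1:1.
    """
    if not plan:
        raise DoseEngineError("empty plan")
    if current is None:
        current = machine.dose_rate_range[1]
    lo, hi = machine.dose_rate_range
    if not lo <= current <= hi:
        raise DoseEngineError(f"current {current} outside machine range")
    vx, vy = speeds

    cps = []
    start = 0
    reason = "start"
    period = plan[0].w / current
    for k in range(1, len(plan)):
        prev, cur = plan[k - 1], plan[k]
        dx, dy = cur.x - prev.x, cur.y - prev.y
        move = max(abs(dx) / vx, abs(dy) / vy)
        seg_mu = current * move
        trigger = None
        if cur.energy_index != prev.energy_index:
            trigger = "range_change"
        elif cur.w < short_dose_threshold:
            trigger = "short_dose"
        elif cur.w / current < stop_time_s:
            trigger = "short_stop_time"
        elif seg_mu < spm_threshold:
            trigger = "spm_dose_low"
        elif seg_mu > 0 and abs(cur.w / seg_mu - 1.0) > ratio_tol:
            trigger = "dose_ratio"
        if trigger is not None:
            cps.append(ControlPoint(index=len(cps), first_spot=start,
                                    last_spot=k - 1, current=current,
                                    reason=reason, period=period))
            start, reason, period = k, trigger, 0.0
        else:
            period += move
        period += cur.w / current
    cps.append(ControlPoint(index=len(cps), first_spot=start,
                            last_spot=len(plan) - 1, current=current,
                            reason=reason, period=period))
    return cps


# ---------------------------------------------------------------------------
# MU calibration against the reference irradiation

@dataclass(frozen=True)
class MUCalibration:
    """Record of the reference calibration: 1 MU = 1 cGy mean dose in a
    100 x 100 x 100 mm^3 water volume irradiated to 200 mm range."""

    scale: float                  # multiplier applied to the IDD tables
    dose_per_mu_before: float     # Gy/MU of the uncalibrated library
    total_mu: float               # MU of the reference plan
    n_spots: int
    reference: dict


def _reference_plan(library: BeamDataLibrary, spot_spacing: float):
    from .planning import FieldSpec, generate_spot_map, optimize_sobp_weights
    fs = FieldSpec(field_size=(100.0, 100.0), range_mm=200.0,
                   sobp_mm=100.0, spot_spacing=spot_spacing,
                   prescription=2.0, prescription_kind="physical")
    spots = generate_spot_map(fs, library.machine, library)
    weighted = optimize_sobp_weights(spots, library, target=2.0,
                                     plateau=(102.0, 198.0))
    return fs, weighted


def mu_calibration(library: BeamDataLibrary, spot_spacing: float = 6.0,
                   grid_spacing: float = 2.0):
    """Scale the library so the reference irradiation yields 1 cGy/MU.

    Returns ``(calibrated_library, record)``.  The reference field (100 x
    100 mm^2, 200 mm range, 100 mm SOBP) is computed in water on the fixed
    2 mm grid and averaged over the central 100 x 100 x 100 mm^3 volume.
    """
    max_range = max(library.machine.range_per_energy)
    if max_range < 200.0:
        raise DoseEngineError("library must cover 200 mm range for the "
                              "reference calibration")
    fs, plan = _reference_plan(library, spot_spacing)
    phantom = water_box(lateral_mm=160.0, depth_mm=208.0,
                        spacing=grid_spacing, surface_z=0.0)
    grid = compute_field_dose_water(plan, phantom, library)
    xc, yc, zc = (grid.axis_centers(i) for i in range(3))
    depth = phantom.z_top_face - zc
    mx = np.abs(xc) <= 50.0
    my = np.abs(yc) <= 50.0
    mz = (depth >= 100.0) & (depth <= 200.0)
    mean_dose = float(grid.physical[np.ix_(mx, my, mz)].mean())
    total_mu = float(sum(s.w for s in plan))
    dose_per_mu = mean_dose / total_mu
    scale = 0.01 / dose_per_mu
    kernels = [replace(k, idd=k.idd * scale) for k in library.kernels]
    record = MUCalibration(
        scale=scale, dose_per_mu_before=dose_per_mu, total_mu=total_mu,
        n_spots=len(plan),
        reference={"volume_mm": [100.0, 100.0, 100.0], "range_mm": 200.0,
                   "spot_spacing_mm": spot_spacing,
                   "grid_spacing_mm": grid_spacing})
    machine = replace(library.machine, mu_per_cgy_reference={
        "scale": scale, "definition": "1 MU = 1 cGy mean dose, "
        "100x100x100 mm^3 at 200 mm range"})
    calibrated = BeamDataLibrary(machine=machine, kernels=kernels,
                                 metadata=dict(library.metadata,
                                               mu_calibrated=True))
    return calibrated, record


def mu_for_reference_dose(calibrated: BeamDataLibrary,
                          dose_gy: float = 2.0,
                          spot_spacing: float = 6.0,
                          grid_spacing: float = 2.0) -> float:
    """Total MU that delivers ``dose_gy`` mean dose to the reference
    volume, recomputed from scratch with the calibrated library."""
    fs, plan = _reference_plan(calibrated, spot_spacing)
    phantom = water_box(lateral_mm=160.0, depth_mm=208.0,
                        spacing=grid_spacing, surface_z=0.0)
    grid = compute_field_dose_water(plan, phantom, calibrated)
    xc, yc, zc = (grid.axis_centers(i) for i in range(3))
    depth = phantom.z_top_face - zc
    sel = np.ix_(np.abs(xc) <= 50.0, np.abs(yc) <= 50.0,
                 (depth >= 100.0) & (depth <= 200.0))
    mean_dose = float(grid.physical[sel].mean())
    total_mu = float(sum(s.w for s in plan))
    return total_mu * dose_gy / mean_dose
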