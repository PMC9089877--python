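"""Stoichiometric CT-number-to-RSP calibration.

The calibration chain: (1) fit a Schneider-style parameterization of the
scanner's attenuation (photoelectric Z^3.62, coherent Z^1.86 and Compton
terms) to inserts of known composition and measured Hounsfield number;
(2) predict theoretical CT numbers for a set of representative body
tissues; (3) compute each tissue's stopping-power ratio relative to water
(RSP) with the Bethe-Bloch formula, without energy-dependent corrections,
at the reference velocity beta = 0.481 (131.0 MeV/u); (4) assemble a
clamped piecewise-linear HU-to-RSP table whose upper clamp is the RSP of
gold.  A composite range uncertainty combines per-tissue RSP uncertainties
with path-length weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ElementData", "MaterialComposition", "ScannerModel", "HUtoRSPTable",
    "CalibrationConfig", "CalibrationError", "ELEMENTS", "WATER",
    "REPRESENTATIVE_TISSUES", "GOLD",
    "beta_from_kinetic_energy", "mean_excitation_energy",
    "relative_stopping_power", "fit_scanner_model", "build_hu_rsp_table",
    "lookup_rsp", "composite_range_uncertainty",
]

ELECTRON_REST_MEV = 0.51099895000
AMU_REST_MEV = 931.49410242


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class ElementData:
    symbol: str
    Z: int
    A: float          # g/mol
    I: float          # mean excitation energy, eV

    def __post_init__(self):
        if self.Z < 1 or self.A <= 0 or self.I <= 0:
            raise CalibrationError(f"invalid element data for {self.symbol}")


# Condensed-phase-adjusted mean excitation energies (eV), ICRU-style; with
# Bragg additivity these place water near its 75.3 eV reference value.
ELEMENTS: dict[str, ElementData] = {e.symbol: e for e in [
    ElementData("H", 1, 1.008, 21.8),
    ElementData("C", 6, 12.011, 81.0),
    ElementData("N", 7, 14.007, 90.0),
    ElementData("O", 8, 15.999, 106.0),
    ElementData("Na", 11, 22.990, 149.0),
    ElementData("Mg", 12, 24.305, 156.0),
    ElementData("P", 15, 30.974, 173.0),
    ElementData("S", 16, 32.06, 180.0),
    ElementData("Cl", 17, 35.45, 174.0),
    ElementData("K", 19, 39.098, 190.0),
    ElementData("Ca", 20, 40.078, 191.0),
    ElementData("Fe", 26, 55.845, 286.0),
    ElementData("I", 53, 126.904, 491.0),
    ElementData("Au", 79, 196.967, 790.0),
]}


@dataclass(frozen=True)
class MaterialComposition:
    """Elemental mass fractions, density, and optionally a measured HU."""

    name: str
    fractions: dict
    density: float
    measured_hu: float | None = None

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise CalibrationError(
                f"{self.name}: mass fractions sum to {total}, not 1")
        if self.density <= 0:
            raise CalibrationError(f"{self.name}: density must be positive")


WATER = MaterialComposition("water", {"H": 0.1119, "O": 0.8881}, 1.0)
GOLD = MaterialComposition("gold", {"Au": 1.0}, 19.32)

# Synthetic stand-ins for the 11 representative body tissues of the
# reference-adult tabulations (compositions/densities emulated, not copied
# from any published table).
REPRESENTATIVE_TISSUES: list[MaterialComposition] = [
    MaterialComposition("lung_inflated", {
        "H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "Na": 0.002,
        "P": 0.002, "S": 0.003, "Cl": 0.003, "K": 0.002}, 0.26),
    MaterialComposition("adipose", {
        "H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "Na": 0.001,
        "S": 0.001, "Cl": 0.001}, 0.95),
    MaterialComposition("breast", {
        "H": 0.106, "C": 0.332, "N": 0.030, "O": 0.527, "Na": 0.001,
        "P": 0.001, "S": 0.002, "Cl": 0.001}, 1.02),
    MaterialComposition("muscle", {
        "H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710, "Na": 0.001,
        "P": 0.002, "S": 0.003, "Cl": 0.001, "K": 0.004}, 1.05),
    MaterialComposition("liver", {
        "H": 0.102, "C": 0.139, "N": 0.030, "O": 0.716, "Na": 0.002,
        "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003}, 1.06),
    MaterialComposition("skin", {
        "H": 0.100, "C": 0.204, "N": 0.042, "O": 0.645, "Na": 0.002,
        "P": 0.001, "S": 0.002, "Cl": 0.003, "K": 0.001}, 1.09),
    MaterialComposition("brain", {
        "H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712, "Na": 0.002,
        "P": 0.004, "S": 0.002, "Cl": 0.003, "K": 0.003}, 1.04),
    MaterialComposition("blood", {
        "H": 0.102, "C": 0.110, "N": 0.033, "O": 0.745, "Na": 0.001,
        "P": 0.001, "S": 0.002, "Cl": 0.003, "Fe": 0.001,
        "K": 0.002}, 1.06),
    MaterialComposition("cartilage", {
        "H": 0.096, "C": 0.099, "N": 0.022, "O": 0.744, "Na": 0.005,
        "P": 0.022, "S": 0.009, "Cl": 0.003}, 1.10),
    MaterialComposition("spongiosa", {
        "H": 0.085, "C": 0.404, "N": 0.028, "O": 0.367, "Na": 0.001,
        "P": 0.034, "S": 0.002, "Cl": 0.002, "K": 0.001,
        "Ca": 0.074, "Fe": 0.002}, 1.18),
    MaterialComposition("cortical_bone", {
        "H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
        "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}, 1.92),
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Reference conditions of the RSP computation and Eq-9 inputs."""

    I_water: float = 75.3                 # eV
    kinetic_energy: float = 131.0         # MeV/u -> beta = 0.481
    sigma_lung: float = 6.6               # % RSP uncertainty per tissue class
    sigma_soft: float = 1.4
    sigma_bone: float = 2.2

    @property
    def beta(self) -> float:
        return beta_from_kinetic_energy(self.kinetic_energy)


@dataclass
class ScannerModel:
    """Fitted coefficients of the theoretical CT-number formula.

    mu ~ sum_i (rho w_i/A_i) * (Z_i + k1 Z_i^3.62 + k2 Z_i^1.86); HU is the
    ratio to water minus one, times 1000, so water predicts HU 0 exactly.
    """

    k_photoelectric: float
    k_coherent: float
    residuals_hu: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def predicted_hu(self, mat: MaterialComposition) -> float:
        return _theoretical_hu(mat, self.k_photoelectric, self.k_coherent)


@dataclass
class HUtoRSPTable:
    """Clamped piecewise-linear CT-number-to-RSP map."""

    hu: np.ndarray
    rsp: np.ndarray
    clamp_low: float
    clamp_high: float

    def __post_init__(self):
        self.hu = np.asarray(self.hu, float)
        self.rsp = np.asarray(self.rsp, float)
        if self.hu.size != self.rsp.size or self.hu.size < 2:
            raise CalibrationError("table needs >= 2 matched breakpoints")
        if np.any(np.diff(self.hu) <= 0):
            raise CalibrationError("HU breakpoints must strictly increase")
        if np.any(self.rsp <= 0) or self.clamp_low <= 0 or self.clamp_high <= 0:
            raise CalibrationError("RSP values must be positive")


def beta_from_kinetic_energy(energy_mev_per_u: float) -> float:
    """v/c from kinetic energy per nucleon (relativistic, amu rest mass)."""
    if energy_mev_per_u < 0:
        raise CalibrationError("kinetic energy must be non-negative")
    gamma = 1.0 + energy_mev_per_u / AMU_REST_MEV
    return math.sqrt(1.0 - 1.0 / (gamma * gamma))


def _is_water(mat: MaterialComposition) -> bool:
    if mat.name.lower() == "water":
        return True
    frac = mat.fractions
    return (set(frac) == {"H", "O"}
            and abs(frac["H"] - 0.1119) < 1e-3
            and abs(frac["O"] - 0.8881) < 1e-3)


def mean_excitation_energy(mat: MaterialComposition,
                           elements: dict = ELEMENTS,
                           cfg: CalibrationConfig | None = None) -> float:
    """Bragg-additivity mean excitation energy (eV).

    ln I = sum(w Z/A ln I_el) / sum(w Z/A).  Water is special-cased to the
    configured reference I_water, as additivity does not reproduce the
    condensed-water value exactly.
    """
    if cfg is not None and _is_water(mat):
        return cfg.I_water
    num = den = 0.0
    for sym, w in mat.fractions.items():
        if sym not in elements:
            raise CalibrationError(f"unknown element symbol {sym!r}")
        el = elements[sym]
        t = w * el.Z / el.A
        num += t * math.log(el.I)
        den += t
    return math.exp(num / den)


def _electron_density_rel(mat: MaterialComposition,
                          elements: dict = ELEMENTS) -> float:
    def zoa(m):
        return sum(w * elements[s].Z / elements[s].A
                   for s, w in m.fractions.items())
    return mat.density * zoa(mat) / (WATER.density * zoa(WATER))


def relative_stopping_power(mat: MaterialComposition,
                            cfg: CalibrationConfig = CalibrationConfig(),
                            elements: dict = ELEMENTS) -> float:
    """Bethe-Bloch RSP without energy-dependent corrections.

    RSP = (rho_e/rho_e,w) * [ln(2 m_e c^2 b^2 / (I (1-b^2))) - b^2]_mat
                          / [same with I_water].
    """
    beta = cfg.beta
    if not 0.0 < beta < 1.0:
        raise CalibrationError("beta must lie in (0, 1)")
    b2 = beta * beta
    arg_const = 2.0 * ELECTRON_REST_MEV * 1e6 * b2 / (1.0 - b2)  # eV
    i_mat = cfg.I_water if _is_water(mat) else mean_excitation_energy(
        mat, elements, cfg)
    num = math.log(arg_const / i_mat) - b2
    den = math.log(arg_const / cfg.I_water) - b2
    if num <= 0 or den <= 0:
        raise CalibrationError(
            f"Bethe-Bloch bracket non-positive for {mat.name} at "
            f"beta={beta:.3f} (I too large for this velocity)")
    return _electron_density_rel(mat, elements) * num / den


# ---------------------------------------------------------------------------
# scanner model fit and table construction

_P_PHOTO = 3.62
_P_COHER = 1.86


def _attenuation(mat: MaterialComposition, k1: float, k2: float,
                 elements: dict = ELEMENTS) -> float:
    acc = 0.0
    for sym, w in mat.fractions.items():
        if sym not in elements:
            raise CalibrationError(f"unknown element symbol {sym!r}")
        el = elements[sym]
        acc += mat.density * w / el.A * (
            el.Z + k1 * el.Z ** _P_PHOTO + k2 * el.Z ** _P_COHER)
    return acc


def _theoretical_hu(mat, k1, k2, elements: dict = ELEMENTS) -> float:
    mu_rel = _attenuation(mat, k1, k2, elements) / _attenuation(
        WATER, k1, k2, elements)
    return 1000.0 * (mu_rel - 1.0)


def fit_scanner_model(inserts: list[MaterialComposition],
                      elements: dict = ELEMENTS) -> ScannerModel:
    """Least-squares fit of the two cross-section weights to measured HU."""
    usable = [m for m in inserts if m.measured_hu is not None]
    if len(usable) < 4:
        raise CalibrationError("need >= 4 inserts with measured HU")
    keys = [tuple(sorted(m.fractions.items())) + (round(m.density, 6),)
            for m in usable]
    if len(set(keys)) < 3:
        raise CalibrationError("insert set is degenerate (compositions do "
                               "not span the calibration space)")
    measured = np.array([m.measured_hu for m in usable])

    def resid(k):
        return np.array([_theoretical_hu(m, k[0], k[1], elements)
                         for m in usable]) - measured

    sol = least_squares(resid, x0=[1e-4, 1e-3], method="lm", xtol=1e-15,
                        ftol=1e-15, gtol=1e-15)
    model = ScannerModel(k_photoelectric=float(sol.x[0]),
                         k_coherent=float(sol.x[1]),
                         residuals_hu=resid(sol.x))
    return model


def build_hu_rsp_table(model: ScannerModel,
                       tissues: list[MaterialComposition],
                       cfg: CalibrationConfig = CalibrationConfig(),
                       hu_round: float = 0.1,
                       hu_cap: float = 3071.0) -> HUtoRSPTable:
    """Tissue breakpoints (predicted HU, Bethe-Bloch RSP), clamped.

    Gold, computed with the same calibration, is registered as the final
    breakpoint at the scanner's HU cap (12-bit default), so the map is
    continuous and every lookup above the cap returns the gold RSP; the
    low clamp is the smallest tabulated RSP.  Tissues whose rounded HU
    coincide are merged by averaging their RSP (keeps the map a function).
    """
    if len(tissues) < 2:
        raise CalibrationError("need at least two tissues")
    pts: dict[float, list[float]] = {}
    for t in tissues:
        hu = round(model.predicted_hu(t) / hu_round) * hu_round
        pts.setdefault(hu, []).append(relative_stopping_power(t, cfg))
    gold_rsp = relative_stopping_power(GOLD, cfg)
    if max(pts) < hu_cap:
        pts[hu_cap] = [gold_rsp]
    hu = np.array(sorted(pts))
    rsp = np.array([float(np.mean(pts[h])) for h in hu])
    return HUtoRSPTable(hu=hu, rsp=rsp,
                        clamp_low=float(rsp.min()),
                        clamp_high=gold_rsp)


def lookup_rsp(table: HUtoRSPTable, hu) -> float | np.ndarray:
    """Piecewise-linear in the calibrated band, clamped outside it."""
    return np.interp(hu, table.hu, table.rsp,
                     left=table.clamp_low, right=table.clamp_high)


def composite_range_uncertainty(w_lung: float, w_soft: float, w_bone: float,
                                sigma_lung: float, sigma_soft: float,
                                sigma_bone: float) -> float:
    """Path-weighted composite range uncertainty (%)."""
    if min(w_lung, w_soft, w_bone) < 0:
        raise CalibrationError("weights must be non-negative")
    if abs(w_lung + w_soft + w_bone - 1.0) > 1e-9:
        raise CalibrationError("weights must sum to 1")
    return w_lung * sigma_lung + w_soft * sigma_soft + w_bone * sigma_bone


def export_table(table: HUtoRSPTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# clamp_low {table.clamp_low!r}\n")
        fh.write(f"# clamp_high {table.clamp_high!r}\n")
        fh.write("# HU\tRSP\n")
        for h, r in zip(table.hu, table.rsp):
            fh.write(f"{float(h)!r}\t{float(r)!r}\n")


def import_table(path) -> HUtoRSPTable:
    clamps = {}
    hu, rsp = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] in ("clamp_low", "clamp_high"):
                    clamps[parts[0]] = float(parts[1])
                continue
            h, r = line.split()
            hu.append(float(h))
            rsp.append(float(r))
    if "clamp_low" not in clamps or "clamp_high" not in clamps:
        raise CalibrationError("table file missing clamp header lines")
    return HUtoRSPTable(np.array(hu), np.array(rsp),
                        clamps["clamp_low"], clamps["clamp_high"])
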