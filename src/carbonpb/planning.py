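"""Plan construction: rectangular spot maps, SOBP weight optimization and
machine-constraint validation.

Commissioning fields are uniform boxes: a lateral Cartesian spot grid per
energy layer, layers chosen so the pristine-peak depths tile the SOBP
interval on the machine's 3 mm depth lattice, and per-layer MU weights
found by non-negative least squares against a flat central-axis physical
dose over the SOBP plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import nnls

from .beam_data import BeamDataLibrary, MachineSpec, idd_at_depth
from .physical_dose import DoseEngineError, Spot, sigma_at_depth

__all__ = [
    "PlanError", "FieldSpec", "PlanSummary", "generate_spot_map",
    "optimize_sobp_weights", "sobp_depth_dose",
    "validate_machine_constraints", "summarize_plan", "round_mu",
]


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class FieldSpec:
    """A rectangular uniform field: size, range, SOBP width, spot spacing
    and the prescription at the SOBP center."""

    field_size: tuple[float, float]
    range_mm: float
    sobp_mm: float
    spot_spacing: float | None = None
    prescription: float = 2.0
    prescription_kind: str = "physical"   # "physical" Gy | "biological" Gy(RBE)

    def __post_init__(self):
        if min(self.field_size) <= 0 or self.range_mm <= 0:
            raise PlanError("field size and range must be positive")
        if not 0 <= self.sobp_mm <= self.range_mm:
            raise PlanError("SOBP width must lie in [0, range]")
        if self.prescription_kind not in ("physical", "biological"):
            raise PlanError("prescription kind must be physical|biological")


@dataclass(frozen=True)
class PlanSummary:
    n_spots: int
    total_mu: float
    energy_layers: tuple[int, ...]
    violations: tuple


def _lateral_positions(extent: float, spacing: float) -> np.ndarray:
    n = int(np.floor(extent / spacing + 1e-9)) + 1
    return (np.arange(n) - (n - 1) / 2.0) * spacing


def generate_spot_map(field: FieldSpec, machine: MachineSpec,
                      library: BeamDataLibrary) -> list[Spot]:
    """Cartesian spot positions per energy layer covering the field.

    Layers are the machine's nominal selections whose ranges fall in
    [range - SOBP, range]; spot spacing defaults to 0.7 x the in-air sigma
    of the deepest layer at the isocenter.
    """
    fx, fy = machine.field_max
    if field.field_size[0] > fx or field.field_size[1] > fy:
        raise PlanError(
            f"field {field.field_size} exceeds the machine maximum "
            f"{machine.field_max}")
    ranges = np.asarray(machine.range_per_energy)
    if field.range_mm > ranges.max() + machine.depth_increment / 2:
        raise PlanError("requested range beyond the machine maximum")
    if field.sobp_mm == 0.0:
        layers = [int(np.argmin(np.abs(ranges - field.range_mm)))]
    else:
        sel = (ranges >= field.range_mm - field.sobp_mm - 1e-9) \
            & (ranges <= field.range_mm + 1e-9)
        layers = [int(i) for i in np.nonzero(sel)[0]]
        if not layers:
            raise PlanError("no energy layers available in the SOBP window")

    spacing = field.spot_spacing
    if spacing is None:
        deep = library.kernel(layers[-1])
        spacing = 0.7 * deep.sigma_optics["sigma_x"]
    xs = _lateral_positions(field.field_size[0], spacing)
    ys = _lateral_positions(field.field_size[1], spacing)
    spots = []
    for ei in layers:
        for x in xs:
            for y in ys:
                spots.append(Spot(x=float(x), y=float(y),
                                  energy_index=ei, w=0.0))
    return spots


def _central_axis_response(spots: list[Spot], library: BeamDataLibrary,
                           depths: np.ndarray) -> tuple[np.ndarray, list]:
    """Matrix A[d, layer]: central-axis water dose per unit spot MU."""
    layers = sorted({s.energy_index for s in spots})
    by_layer = {ei: [s for s in spots if s.energy_index == ei]
                for ei in layers}
    A = np.zeros((depths.size, len(layers)))
    z = -depths  # water surface at the isocenter plane
    for col, ei in enumerate(layers):
        kernel = library.kernel(ei)
        corr = kernel.absolute_correction
        lateral = by_layer[ei]
        for n in (1, 2, 3):
            f = idd_at_depth(kernel, n, depths) * corr
            sx, sy = sigma_at_depth(kernel, n, z, depths)
            sx = np.broadcast_to(np.asarray(sx, float), depths.shape)
            sy = np.broadcast_to(np.asarray(sy, float), depths.shape)
            xs = np.array([s.x for s in lateral])
            ys = np.array([s.y for s in lateral])
            gsum = np.zeros(depths.size)
            for k in range(depths.size):
                gx = np.exp(-xs ** 2 / (2 * sx[k] ** 2))
                gy = np.exp(-ys ** 2 / (2 * sy[k] ** 2))
                gsum[k] = np.sum(gx * gy) / (2 * np.pi * sx[k] * sy[k])
            A[:, col] += f * gsum
    return A, layers


def round_mu(w: float, machine: MachineSpec) -> float:
    return round(w / machine.mu_resolution) * machine.mu_resolution


def optimize_sobp_weights(spots: list[Spot], library: BeamDataLibrary,
                          target: float | None = None,
                          plateau: tuple[float, float] | None = None,
                          target_profile=None,
                          depth_step: float = 1.0,
                          apply_resolution: bool = True) -> list[Spot]:
    """Assign per-layer MU by non-negative least squares.

    Either a flat ``target`` (Gy) over ``plateau`` (depth interval, mm) or
    an explicit ``target_profile=(depths, values)`` may be given.  Weights
    are uniform across a layer's lateral grid and rounded to the machine
    MU resolution.
    """
    if not spots:
        raise PlanError("no spots to optimize")
    if target_profile is not None:
        depths = np.asarray(target_profile[0], float)
        t = np.asarray(target_profile[1], float)
    else:
        if target is None or plateau is None:
            raise PlanError("give target+plateau or target_profile")
        lo, hi = plateau
        if hi <= lo:
            raise PlanError("empty plateau")
        depths = np.arange(lo, hi + depth_step / 2, depth_step)
        t = np.full(depths.size, float(target))
        max_range = max(library.machine.range_per_energy)
        if depths.max() > max_range + library.machine.depth_increment:
            raise PlanError("target deeper than the machine maximum range")
    A, layers = _central_axis_response(spots, library, depths)
    w, _ = nnls(A, t)
    weight = dict(zip(layers, w))
    out = []
    for s in spots:
        wl = weight[s.energy_index]
        if apply_resolution:
            wl = round_mu(wl, library.machine)
        out.append(replace(s, w=float(wl)))
    return out


def sobp_depth_dose(plan: list[Spot], library: BeamDataLibrary,
                    depths: np.ndarray) -> np.ndarray:
    """Central-axis water depth dose of a weighted plan (Gy)."""
    A, layers = _central_axis_response(plan, library, np.asarray(depths,
                                                                 float))
    per_layer = {}
    for s in plan:
        if s.energy_index in per_layer:
            if abs(per_layer[s.energy_index] - s.w) > 1e-12:
                raise PlanError("sobp_depth_dose expects uniform layer MU")
        per_layer[s.energy_index] = s.w
    w = np.array([per_layer[ei] for ei in layers])
    return A @ w


def validate_machine_constraints(spots: list[Spot],
                                 machine: MachineSpec) -> list[dict]:
    """Flag MU-limit, resolution and geometry violations (read-only).

    Spot MU is rounded to the machine resolution before the bound checks;
    spots exactly at a bound pass.
    """
    findings = []
    fx, fy = machine.field_max
    eps = machine.mu_resolution * 1e-6  # spots exactly at a bound pass
    for i, s in enumerate(spots):
        w = round_mu(s.w, machine)
        if w < machine.mu_min - eps:
            findings.append({"spot": i, "kind": "mu_below_min",
                             "value": w, "limit": machine.mu_min})
        elif w > machine.mu_max + eps:
            findings.append({"spot": i, "kind": "mu_above_max",
                             "value": w, "limit": machine.mu_max})
        if abs(s.x) > fx / 2 or abs(s.y) > fy / 2:
            findings.append({"spot": i, "kind": "out_of_field",
                             "value": (s.x, s.y), "limit": machine.field_max})
        if s.rs_weq:
            lattice = s.rs_weq / machine.depth_increment
            if abs(lattice - round(lattice)) > 1e-9:
                findings.append({"spot": i, "kind": "off_lattice_depth",
                                 "value": s.rs_weq,
                                 "limit": machine.depth_increment})
    return findings


def summarize_plan(spots: list[Spot], machine: MachineSpec) -> PlanSummary:
    total = sum(round_mu(s.w, machine) for s in spots)
    return PlanSummary(
        n_spots=len(spots),
        total_mu=float(total),
        energy_layers=tuple(sorted({s.energy_index for s in spots})),
        violations=tuple(
            (f["spot"], f["kind"])
            for f in validate_machine_constraints(spots, machine)))
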