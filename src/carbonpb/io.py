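"""Plan, profile and dose-grid file I/O.

Plan files follow the spot-file / control-point-file split of the delivery
system, as delimited text with a commented header.  The spot file columns
are: spot index, energy index, x (mm), y (mm), MU.  The control-point file
columns are: index, first spot, last spot, current (MU/s), reason code.
Dose grids are written as a JSON sidecar header (shape, spacing, origin,
axis order) plus a flat float32 binary array.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .physical_dose import (ControlPoint, DoseEngineError, DoseGrid, Spot,
                            VoxelPhantom, build_slab_phantom,
                            heterogeneous_slab_phantom, water_box)
from .qa import DoseProfile

__all__ = [
    "write_spot_file", "read_spot_file", "write_control_point_file",
    "read_control_point_file", "save_dose_grid", "load_dose_grid",
    "write_profile", "read_profile", "phantom_from_spec",
]


def write_spot_file(spots: list[Spot], path) -> None:
    with open(path, "w") as fh:
        fh.write("# carbonpb spot position file v1\n")
        fh.write("# index\tenergy_index\tx_mm\ty_mm\tmu\trs_weq_mm\n")
        for i, s in enumerate(spots):
            fh.write(f"{i}\t{s.energy_index}\t{s.x!r}\t{s.y!r}\t{s.w!r}"
                     f"\t{s.rs_weq!r}\n")


def read_spot_file(path) -> list[Spot]:
    spots = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise DoseEngineError(f"malformed spot record: {line!r}")
            rs = float(parts[5]) if len(parts) == 6 else 0.0
            spots.append(Spot(x=float(parts[2]), y=float(parts[3]),
                              energy_index=int(parts[1]),
                              w=float(parts[4]), rs_weq=rs))
    return spots


def write_control_point_file(cps: list[ControlPoint], path) -> None:
    with open(path, "w") as fh:
        fh.write("# carbonpb control point file v1\n")
        fh.write("# index\tfirst_spot\tlast_spot\tcurrent_mu_s\treason"
                 "\tperiod_s\n")
        for c in cps:
            fh.write(f"{c.index}\t{c.first_spot}\t{c.last_spot}"
                     f"\t{c.current!r}\t{c.reason}\t{c.period!r}\n")


def read_control_point_file(path) -> list[ControlPoint]:
    cps = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split()
            cps.append(ControlPoint(index=int(p[0]), first_spot=int(p[1]),
                                    last_spot=int(p[2]), current=float(p[3]),
                                    reason=p[4], period=float(p[5])))
    return cps


def save_dose_grid(grid: DoseGrid, basename) -> None:
    base = Path(basename)
    arrays = {"physical": grid.physical}
    for name in ("carbon", "fragment"):
        arr = getattr(grid, name)
        if arr is not None:
            arrays[name] = arr
    header = {
        "format": "carbonpb-dosegrid", "version": 1,
        "shape": list(grid.physical.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
        "axis_order": "xyz",
        "dtype": "float32",
        "arrays": sorted(arrays),
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))
    for name, arr in arrays.items():
        arr.astype(np.float32).tofile(base.parent / f"{base.name}.{name}.f32")


def load_dose_grid(basename) -> DoseGrid:
    base = Path(basename)
    header = json.loads(base.with_suffix(".json").read_text())
    shape = tuple(header["shape"])

    def read(name):
        p = base.parent / f"{base.name}.{name}.f32"
        if not p.exists():
            return None
        return np.fromfile(p, dtype=np.float32).astype(float).reshape(shape)

    return DoseGrid(spacing=tuple(header["spacing_mm"]),
                    origin=tuple(header["origin_mm"]),
                    physical=read("physical"),
                    carbon=read("carbon"), fragment=read("fragment"))


def write_profile(profile: DoseProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# position_mm\tvalue\n")
        for p, v in zip(profile.positions, profile.values):
            fh.write(f"{float(p)!r}\t{float(v)!r}\n")


def read_profile(path) -> DoseProfile:
    data = np.loadtxt(path)
    return DoseProfile(positions=data[:, 0], values=data[:, 1])


def phantom_from_spec(spec: dict | str) -> VoxelPhantom:
    """Build a phantom from a YAML/dict description.

    Supported: {type: water, lateral_mm, depth_mm, spacing_mm, rsp},
    {type: heterogeneous_slab}, and {type: slabs, bounds, regions} where
    regions are [x0, x1, y0, y1, z0, z1, rsp] boxes.
    """
    if isinstance(spec, (str, Path)):
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    kind = spec.get("type")
    if kind == "water":
        return water_box(lateral_mm=spec.get("lateral_mm", 160.0),
                         depth_mm=spec.get("depth_mm", 160.0),
                         spacing=spec.get("spacing_mm", 2.0),
                         surface_z=spec.get("surface_z_mm", 0.0),
                         rsp=spec.get("rsp", 1.0))
    if kind == "heterogeneous_slab":
        return heterogeneous_slab_phantom(
            spacing=spec.get("spacing_mm", 2.0),
            water_depth=spec.get("water_depth_mm", 160.0))
    if kind == "slabs":
        return build_slab_phantom(
            regions=[tuple(r) for r in spec["regions"]],
            bounds=tuple(tuple(b) for b in spec["bounds"]),
            spacing=spec.get("spacing_mm", 2.0),
            default_rsp=spec.get("default_rsp", 0.0))
    raise DoseEngineError(f"unknown phantom type {kind!r}")
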