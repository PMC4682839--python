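"""File formats: TIFF+JSON z-stacks, PLY/STL surfaces, legacy VTK fields.

Stacks are stored as one multi-page TIFF per time stack (slice order =
z order, bottom-up) with a JSON sidecar carrying per-slice z and t, the
pixel size and the true bit depth (12-bit data lives in 16-bit TIFF
containers, standard practice).  Surfaces round-trip through binary PLY
with per-vertex float scalars as named properties; STL carries geometry
only.  Flow/shear fields are written as legacy ASCII VTK structured points
(readable by ParaView); only files written by this package are read back.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
import trimesh

from .flow import FlowField, ShearField, ChannelGeometry
from .types import InvalidParameterError, SliceImage, TriSurface, ZStack


class ParseError(InvalidParameterError):
    pass


# ----------------------------------------------------------------------
# z-stacks
# ----------------------------------------------------------------------

def write_zstack(stack: ZStack, tiff_path, json_path=None) -> None:
    tiff_path = Path(tiff_path)
    if json_path is None:
        json_path = tiff_path.with_suffix(".json")
    data = stack.as_volume()
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    tifffile.imwrite(tiff_path, data)
    meta = {
        "stack_index": stack.index,
        "pixel_size_um": stack.pixel_size_um,
        "bit_depth": stack.slices[0].bit_depth,
        "slices": [{"z_um": s.z_um, "t_s": s.t_s} for s in stack.slices],
    }
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_zstack(tiff_path, json_path=None) -> ZStack:
    tiff_path = Path(tiff_path)
    if json_path is None:
        json_path = tiff_path.with_suffix(".json")
    try:
        meta = json.loads(Path(json_path).read_text())
    except FileNotFoundError:
        raise ParseError(f"missing metadata sidecar {json_path}")
    for key in ("pixel_size_um", "bit_depth", "slices"):
        if key not in meta:
            raise ParseError(f"metadata field '{key}' missing in {json_path}")
    data = tifffile.imread(tiff_path)
    if data.ndim == 2:
        data = data[None]
    if len(data) != len(meta["slices"]):
        raise ParseError(
            f"{tiff_path}: {len(data)} pages but {len(meta['slices'])} "
            "slice records"
        )
    slices = [
        SliceImage(
            data=page,
            z_um=rec["z_um"],
            t_s=rec["t_s"],
            pixel_size_um=meta["pixel_size_um"],
            bit_depth=meta["bit_depth"],
        )
        for page, rec in zip(data, meta["slices"])
    ]
    return ZStack(slices=slices, index=int(meta.get("stack_index", 0)))


def write_stacks(stacks: list[ZStack], out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for st in stacks:
        p = out_dir / f"stack_{st.index:04d}.tif"
        write_zstack(st, p)
        paths.append(p)
    return paths


def read_stacks(in_dir) -> list[ZStack]:
    in_dir = Path(in_dir)
    stacks = [read_zstack(p) for p in sorted(in_dir.glob("stack_*.tif"))]
    if not stacks:
        raise ParseError(f"no stack_*.tif files in {in_dir}")
    return sorted(stacks, key=lambda s: s.t_start)


# ----------------------------------------------------------------------
# surfaces
# ----------------------------------------------------------------------

def write_surface(surface: TriSurface, path) -> None:
    """PLY (binary, with per-vertex float scalar channels) or STL (geometry)."""
    path = Path(path)
    mesh = surface.mesh.copy()
    if path.suffix.lower() == ".ply":
        for name, values in surface.scalars.items():
            mesh.vertex_attributes[name] = np.asarray(values, dtype=np.float32)
        mesh.export(path, encoding="binary")
    elif path.suffix.lower() == ".stl":
        if surface.scalars:
            warnings.warn("STL stores geometry only; scalar channels dropped")
        mesh.export(path)
    else:
        raise InvalidParameterError(f"unsupported surface format {path.suffix}")


def read_surface(path) -> TriSurface:
    path = Path(path)
    mesh = trimesh.load(path, process=False, force="mesh")
    scalars = {}
    if path.suffix.lower() == ".ply":
        sources = dict(getattr(mesh, "vertex_attributes", {}))
        raw = getattr(mesh, "metadata", {}).get("_ply_raw", {})
        vert = raw.get("vertex", {}).get("data")
        if vert is not None and vert.dtype.names:
            for name in vert.dtype.names:
                if name not in ("x", "y", "z"):
                    sources.setdefault(name, vert[name])
        for name, values in sources.items():
            values = np.asarray(values).squeeze()
            if values.ndim == 1 and len(values) == len(mesh.vertices):
                scalars[name] = values.astype(np.float64)
    else:
        warnings.warn(f"{path.suffix} carries no scalar channels")
        # STL may contain duplicated vertices; merge for watertightness
        mesh.merge_vertices()
    return TriSurface(mesh=mesh, scalars=scalars)


# ----------------------------------------------------------------------
# flow fields (legacy ASCII VTK structured points)
# ----------------------------------------------------------------------

def write_field(field: FlowField, path, shear: ShearField | None = None) -> None:
    """Cell-centred velocity (and γ_local) as legacy VTK STRUCTURED_POINTS."""
    path = Path(path)
    nx, ny, nz = field.shape
    hx, hy, hz = field.spacing_um
    U = field.center_velocity()
    lines = [
        "# vtk DataFile Version 3.0",
        "thrombotrace flow field (um grid, m/s velocities)",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {hx / 2:.17g} {hy / 2:.17g} {hz / 2:.17g}",
        f"SPACING {hx:.17g} {hy:.17g} {hz:.17g}",
        f"POINT_DATA {nx * ny * nz}",
        "VECTORS velocity double",
    ]
    # VTK orders x fastest
    Uf = np.transpose(U, (2, 1, 0, 3)).reshape(-1, 3)
    lines += [f"{a:.17g} {b:.17g} {c:.17g}" for a, b, c in Uf]
    lines.append("SCALARS solid int 1")
    lines.append("LOOKUP_TABLE default")
    sf = np.transpose(field.solid.astype(int), (2, 1, 0)).ravel()
    lines += [" ".join(map(str, sf[i:i + 9])) for i in range(0, len(sf), 9)]
    if shear is not None:
        lines.append("SCALARS gamma_local double 1")
        lines.append("LOOKUP_TABLE default")
        gf = np.transpose(shear.gamma, (2, 1, 0)).ravel()
        lines += [" ".join(f"{g:.17g}" for g in gf[i:i + 9])
                  for i in range(0, len(gf), 9)]
    path.write_text("\n".join(lines) + "\n")


def read_field_arrays(path) -> dict[str, np.ndarray]:
    """Read back velocity/γ arrays from a VTK file written by write_field."""
    toks = Path(path).read_text().split("\n")
    dims = None
    spacing = None
    i = 0
    arrays: dict[str, np.ndarray] = {}
    while i < len(toks):
        line = toks[i].strip()
        if line.startswith("DIMENSIONS"):
            dims = tuple(int(t) for t in line.split()[1:4])
        elif line.startswith("SPACING"):
            spacing = tuple(float(t) for t in line.split()[1:4])
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            n = dims[0] * dims[1] * dims[2]
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(t) for t in toks[i].split())
                i += 1
            arr = np.array(vals).reshape(dims[2], dims[1], dims[0], 3)
            arrays[name] = np.transpose(arr, (2, 1, 0, 3))
            continue
        elif line.startswith("SCALARS"):
            name, typ = line.split()[1:3]
            n = dims[0] * dims[1] * dims[2]
            vals = []
            i += 2  # skip LOOKUP_TABLE
            while len(vals) < n:
                vals.extend(float(t) for t in toks[i].split())
                i += 1
            arr = np.array(vals).reshape(dims[2], dims[1], dims[0])
            arrays[name] = np.transpose(arr, (2, 1, 0))
            continue
        i += 1
    if dims is None:
        raise ParseError(f"{path}: no DIMENSIONS header found")
    arrays["_spacing_um"] = np.array(spacing)
    return arrays


# ----------------------------------------------------------------------
# config
# ----------------------------------------------------------------------

def load_channel_geometry(path) -> ChannelGeometry:
    """Channel geometry from a YAML/JSON config file."""
    import yaml

    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: expected a mapping")
    chan = cfg.get("channel", cfg)
    try:
        return ChannelGeometry(
            width_mm=chan["width_mm"],
            height_mm=chan["height_mm"],
            length_mm=chan.get("length_mm", 100.0),
            flow_ml_min=chan.get("flow_ml_min", 1.44),
            viscosity_cP=chan.get("viscosity_cP", 2.8),
            density_kg_m3=chan.get("density_kg_m3"),
        )
    except KeyError as e:
        raise ParseError(f"{path}: missing channel field {e}")
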