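"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* geometry and imaging are in micrometres (μm), time in seconds;
* x is the flow direction, y the channel width, z the height;
* z = 0 is the capillary floor to which thrombi are attached;
* slices of a z-stack are horizontal (constant-z) planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh


class ThrombotraceError(Exception):
    """Base class for errors raised by this package."""


class InvalidParameterError(ThrombotraceError, ValueError):
    pass


class DegenerateInputError(ThrombotraceError, ValueError):
    pass


class MeshError(ThrombotraceError, ValueError):
    pass


@dataclass
class SliceImage:
    """A single confocal optical section.

    ``data`` is a 2D intensity array indexed ``[row, col]``; rows advance
    along +y and columns along +x, so ``data[j, i]`` sits at the pixel
    centre ``x = (i + 0.5) * pixel_size - width/2`` (the image is centred
    on x = y = 0).
    """

    data: np.ndarray
    z_um: float
    t_s: float
    pixel_size_um: float
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise InvalidParameterError("slice data must be 2D")
        if not (self.pixel_size_um > 0):
            raise InvalidParameterError("pixel size must be > 0")
        if not (math.isfinite(self.z_um) and math.isfinite(self.t_s)):
            raise InvalidParameterError("z and t must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinates (μm) of pixel centres as 1D arrays."""
        ny, nx = self.data.shape
        ps = self.pixel_size_um
        x = (np.arange(nx) + 0.5) * ps - nx * ps / 2.0
        y = (np.arange(ny) + 0.5) * ps - ny * ps / 2.0
        return x, y


@dataclass
class ZStack:
    """An ordered set of slices acquired bottom-up in a single scan."""

    slices: list[SliceImage]
    index: int = 0

    def __post_init__(self) -> None:
        zs = [s.z_um for s in self.slices]
        if any(b < a for a, b in zip(zs, zs[1:])):
            raise InvalidParameterError("slices must be sorted by increasing z")
        ts = [s.t_s for s in self.slices]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise InvalidParameterError("slice timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    @property
    def z_um(self) -> np.ndarray:
        return np.array([s.z_um for s in self.slices])

    @property
    def t_s(self) -> np.ndarray:
        return np.array([s.t_s for s in self.slices])

    @property
    def t_start(self) -> float:
        return float(self.slices[0].t_s)

    @property
    def t_end(self) -> float:
        return float(self.slices[-1].t_s)

    @property
    def pixel_size_um(self) -> float:
        return self.slices[0].pixel_size_um

    def as_volume(self) -> np.ndarray:
        """Stack slice data into a (nz, ny, nx) array."""
        return np.stack([s.data for s in self.slices], axis=0)


@dataclass
class ContourSlice:
    """Closed boundary polygons extracted from one slice."""

    z_um: float
    t_s: float
    polygons: list[np.ndarray]          # each (N, 2) of (x, y) μm, closed implied
    labels: list[int] = field(default_factory=list)
    touches_border: list[bool] = field(default_factory=list)


@dataclass
class TriSurface:
    """Triangulated thrombus surface in μm with optional per-vertex scalars."""

    mesh: trimesh.Trimesh
    scalars: dict[str, np.ndarray] = field(default_factory=dict)
    t_s: float | None = None

    @classmethod
    def from_arrays(
        cls,
        vertices: np.ndarray,
        faces: np.ndarray,
        scalars: dict[str, np.ndarray] | None = None,
        t_s: float | None = None,
    ) -> "TriSurface":
        mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        return cls(mesh=mesh, scalars=dict(scalars or {}), t_s=t_s)

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self.mesh.faces)

    @property
    def volume_um3(self) -> float:
        """Enclosed volume by the signed-tetrahedron (divergence) sum."""
        return float(self.mesh.volume)

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    def require_watertight(self, what: str = "surface") -> None:
        if not self.is_watertight:
            counts = np.bincount(self.mesh.edges_unique_inverse)
            open_edges = int(np.sum(counts != 2))
            raise MeshError(
                f"{what} is not watertight: {open_edges} edges not shared by "
                "exactly two triangles"
            )

    def copy(self) -> "TriSurface":
        return TriSurface(
            mesh=self.mesh.copy(),
            scalars={k: np.array(v) for k, v in self.scalars.items()},
            t_s=self.t_s,
        )

    def with_scalar(self, name: str, values: np.ndarray) -> "TriSurface":
        values = np.asarray(values)
        if len(values) != len(self.mesh.vertices):
            raise InvalidParameterError(
                f"scalar '{name}' length {len(values)} != vertex count "
                f"{len(self.mesh.vertices)}"
            )
        out = self.copy()
        out.scalars[name] = values
        return out
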