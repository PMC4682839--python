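"""Segmentation and 3D surface reconstruction of confocal z-stacks.

The reconstruction chain mirrors standard confocal practice: native 12-bit
sections are mapped to 8-bit, thresholded (fixed or Otsu over the whole
stack), sub-pixel boundaries are extracted per slice, the binary slices are
stacked into a volume, iso-surfaced at level 0.5, capped at the capillary
wall (z = 0) and smoothed with a volume-preserving ripple filter that
removes the stair-step artefacts between z-slices.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import trimesh
from skimage import measure as sk_measure

from .types import (
    ContourSlice,
    DegenerateInputError,
    InvalidParameterError,
    MeshError,
    SliceImage,
    TriSurface,
    ZStack,
)

log = logging.getLogger(__name__)

#: default minimum component area: a 2 μm-diameter disk (single platelet scale)
PLATELET_DIAMETER_UM = 2.0
DEFAULT_MIN_AREA_UM2 = math.pi * (PLATELET_DIAMETER_UM / 2.0) ** 2


def convert_to_8bit(image: SliceImage) -> SliceImage:
    """Map native bit depth to 8-bit by a fixed linear scale.

    value_8 = round_half_up(value · 255 / (2^bitdepth − 1)); deterministic.
    """
    if image.bit_depth < 8:
        raise InvalidParameterError("bit depth must be >= 8")
    full = 2**image.bit_depth - 1
    scaled = np.floor(image.data.astype(np.float64) * 255.0 / full + 0.5)
    data = np.clip(scaled, 0, 255).astype(np.uint8)
    return SliceImage(
        data=data,
        z_um=image.z_um,
        t_s=image.t_s,
        pixel_size_um=image.pixel_size_um,
        bit_depth=8,
    )


def stack_otsu_threshold(stack: ZStack | list[SliceImage]) -> int | None:
    """Otsu threshold over the pooled 8-bit histogram of a whole stack.

    A single threshold for all slices keeps segmentation consistent along z.
    Returns None (with a warning) for blank/constant stacks.
    """
    slices = list(stack)
    data = np.concatenate([s.data.ravel() for s in slices])
    if data.min() == data.max():
        warnings.warn("blank stack: Otsu threshold undefined, masks will be empty")
        return None
    from skimage.filters import threshold_otsu

    # threshold_otsu separates with `img > thr`; our masks use `img >= thr`
    return int(math.floor(threshold_otsu(data))) + 1


def segment_slice(
    image: SliceImage,
    threshold: float | str = "auto",
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> np.ndarray:
    """Threshold one 8-bit slice into a binary mask.

    ``mask = image >= threshold``; "auto" computes Otsu on this slice alone
    (prefer :func:`segment_stack` so all slices share one stack threshold).
    Connected components smaller than ``min_area_um2`` (default: the area of
    a 2 μm platelet disk) are removed as segmentation specks.
    """
    if image.bit_depth != 8:
        raise InvalidParameterError("segment_slice expects an 8-bit image")
    if threshold == "auto":
        thr = stack_otsu_threshold([image])
        if thr is None:
            return np.zeros(image.shape, dtype=bool)
    else:
        thr = float(threshold)
    mask = image.data >= thr
    return _remove_specks(mask, image.pixel_size_um, min_area_um2)


def segment_stack(
    stack: ZStack,
    threshold: float | str = "auto",
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> list[np.ndarray]:
    """Segment every slice of a stack with a common threshold."""
    if threshold == "auto":
        thr = stack_otsu_threshold(stack)
        if thr is None:
            return [np.zeros(s.shape, dtype=bool) for s in stack]
    else:
        thr = float(threshold)
    return [
        _remove_specks(s.data >= thr, s.pixel_size_um, min_area_um2) for s in stack
    ]


def _remove_specks(mask: np.ndarray, pixel_size_um: float, min_area_um2: float):
    if min_area_um2 <= 0:
        return mask
    min_px = int(math.ceil(min_area_um2 / pixel_size_um**2))
    if min_px <= 1:
        return mask
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def extract_contours(
    mask: np.ndarray,
    pixel_size_um: float,
    z_um: float = 0.0,
    t_s: float = 0.0,
) -> ContourSlice:
    """Sub-pixel closed boundary polygons of each connected component.

    Polygons are the 0.5 iso-contours of the (zero-padded) mask, in μm with
    the image centred on x = y = 0, wound counter-clockwise (material
    inside).  Components touching the image border are closed along the
    border and flagged.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask)
    polys: list[np.ndarray] = []
    comp_labels: list[int] = []
    border_flags: list[bool] = []
    ny, nx = mask.shape
    for lab in range(1, n + 1):
        comp = labels == lab
        touches = bool(
            comp[0, :].any() or comp[-1, :].any()
            or comp[:, 0].any() or comp[:, -1].any()
        )
        padded = np.pad(comp.astype(float), 1)
        contours = sk_measure.find_contours(padded, 0.5)
        if not contours:
            continue
        # one component can yield several contours (outer + holes); keep the
        # longest as the outer boundary, drop interior holes
        outer = max(contours, key=len)
        rc = outer - 1.0  # undo pad
        # rows -> y, cols -> x; pixel i centre at (i + 0.5)ps − extent/2
        x = (rc[:, 1] + 0.5) * pixel_size_um - nx * pixel_size_um / 2.0
        y = (rc[:, 0] + 0.5) * pixel_size_um - ny * pixel_size_um / 2.0
        poly = np.column_stack([x, y])
        if np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        if _signed_area(poly) < 0:
            poly = poly[::-1]
        polys.append(poly)
        comp_labels.append(lab)
        border_flags.append(touches)
    return ContourSlice(
        z_um=z_um, t_s=t_s, polygons=polys, labels=comp_labels,
        touches_border=border_flags,
    )


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(poly: np.ndarray) -> float:
    """Enclosed area of a closed polygon (shoelace, absolute)."""
    return abs(_signed_area(np.asarray(poly, dtype=float)))


@dataclass(frozen=True)
class SmoothingConfig:
    """Ripple-filter parameters.

    ``lamb`` steps of graph-Laplacian smoothing per iteration, optionally
    followed by an inflation step ``mu`` (Taubin-style); shrinkage is
    compensated exactly afterwards by rescaling about the base plane, so
    the plain Laplacian default keeps its strong inter-slice ripple
    attenuation without net volume loss.
    """

    enabled: bool = True
    lamb: float = 0.5
    mu: float = 0.0
    iterations: int = 20


def build_surface(
    masks: list[np.ndarray],
    z_um: np.ndarray,
    pixel_size_um: float,
    smoothing: SmoothingConfig | None = None,
    t_s: float | None = None,
) -> TriSurface:
    """Reconstruct a watertight surface from stacked binary slices.

    The binary slices are stacked with their metadata z-spacing, mirrored
    about the wall plane so the iso-surface passes smoothly through z = 0,
    iso-surfaced at level 0.5 (marching cubes) and cut and capped exactly at
    z = 0.  Optional ripple filtering per ``smoothing``.
    """
    z_um = np.asarray(z_um, dtype=float)
    if len(masks) != len(z_um):
        raise InvalidParameterError("masks and z_um lengths differ")
    order = np.argsort(z_um)
    z_um = z_um[order]
    masks = [np.asarray(masks[i], dtype=bool) for i in order]
    dz = np.diff(z_um)
    if len(dz) and not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-9):
        raise InvalidParameterError("slice z-positions must be uniformly spaced")
    dz0 = float(dz[0]) if len(dz) else 1.0

    # drop guard slices below the wall (blank by construction)
    keep = z_um >= -dz0 / 2.0
    if np.any(~keep):
        for i in np.nonzero(~keep)[0]:
            if masks[i].any():
                warnings.warn("non-empty slice below the wall plane dropped")
        masks = [m for m, k in zip(masks, keep) if k]
        z_um = z_um[keep]
    populated = [i for i, m in enumerate(masks) if m.any()]
    if len(populated) < 2:
        raise DegenerateInputError(
            "need at least 2 slices with non-empty masks to build a surface"
        )

    vol = np.stack(masks, axis=0).astype(np.float32)  # (nz, ny, nx)
    z0 = float(z_um[0])
    # pad all-around with background so the iso-surface closes
    vol_pad = np.pad(vol, 1)
    verts, faces, _, _ = sk_measure.marching_cubes(
        vol_pad, level=0.5, spacing=(dz0, pixel_size_um, pixel_size_um)
    )
    # array axes (z, y, x) -> world (x, y, z); undo padding offset and centre x/y
    nz, ny, nx = vol.shape
    verts_xyz = np.column_stack(
        [
            verts[:, 2] - pixel_size_um + 0.5 * pixel_size_um - nx * pixel_size_um / 2.0,
            verts[:, 1] - pixel_size_um + 0.5 * pixel_size_um - ny * pixel_size_um / 2.0,
            verts[:, 0] - dz0 + z0,
        ]
    )
    # the closing skirt below the bottom slice hangs between z0 - dz and z0;
    # flatten it onto the wall plane so the surface is capped exactly at z = 0
    verts_xyz[verts_xyz[:, 2] < z0, 2] = z0
    mesh = trimesh.Trimesh(vertices=verts_xyz, faces=faces, process=False)
    mesh.merge_vertices()
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.process(validate=False)
    if mesh.volume < 0:
        mesh.invert()
    surface = TriSurface(mesh=mesh, t_s=t_s)
    surface.require_watertight("reconstructed surface")
    if smoothing is None:
        smoothing = SmoothingConfig()
    if smoothing.enabled:
        surface = ripple_filter(surface, smoothing)
    return surface


def build_surface_from_stack(
    stack: ZStack,
    threshold: float | str = "auto",
    smoothing: SmoothingConfig | None = None,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> TriSurface:
    """Segment a stack (12-bit in, 8-bit conversion included) and reconstruct."""
    eight = ZStack(
        slices=[convert_to_8bit(s) for s in stack], index=stack.index
    )
    masks = segment_stack(eight, threshold=threshold, min_area_um2=min_area_um2)
    t_mid = 0.5 * (stack.t_start + stack.t_end)
    return build_surface(
        masks, stack.z_um, stack.pixel_size_um, smoothing=smoothing, t_s=t_mid
    )


def ripple_filter(
    surface: TriSurface, config: SmoothingConfig | None = None
) -> TriSurface:
    """Attenuate inter-slice stair-step ripples, preserving volume.

    Iterated graph-Laplacian smoothing with the wall ring pinned to z = 0,
    followed by an exact volume restore by rescaling about the base plane,
    so the enclosed volume changes by far less than the 1 % contract.
    """
    if config is None:
        config = SmoothingConfig()
    mesh = surface.mesh
    v = np.array(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces)
    n = len(v)
    # uniform graph Laplacian L = D^{-1} A - I from unique edges
    edges = mesh.edges_unique
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sp.csr_matrix((np.ones(2 * len(edges)), (i, j)), shape=(n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    W = sp.diags(1.0 / deg) @ A

    on_wall = np.abs(v[:, 2]) < 1e-9
    vol_in = float(mesh.volume)
    factors = (config.lamb, config.mu) if config.mu else (config.lamb,)
    for _ in range(config.iterations):
        for factor in factors:
            v = v + factor * (W @ v - v)
            v[on_wall, 2] = 0.0
    out = trimesh.Trimesh(vertices=v, faces=f, process=False)
    if out.volume < 0:
        out.invert()
    vol_out = float(out.volume)
    if vol_out > 0 and vol_in > 0:
        s = (vol_in / vol_out) ** (1.0 / 3.0)
        c = out.vertices.mean(axis=0)
        c[2] = 0.0  # scale about the base plane so the wall stays at z = 0
        out.vertices = c + s * (out.vertices - c)
    return TriSurface(mesh=out, scalars=dict(surface.scalars), t_s=surface.t_s)


def surface_metrics(surface: TriSurface) -> dict[str, float]:
    """Volume and bounding-box dimensions of a watertight surface.

    L is the extent along flow (x), W across the channel (y), H the height
    (z); volume by the divergence-theorem signed-tetrahedron sum.
    """
    surface.require_watertight("surface_metrics input")
    lo, hi = surface.mesh.bounds
    return {
        "volume_um3": float(surface.mesh.volume),
        "length_um": float(hi[0] - lo[0]),
        "width_um": float(hi[1] - lo[1]),
        "height_um": float(hi[2] - lo[2]),
    }
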