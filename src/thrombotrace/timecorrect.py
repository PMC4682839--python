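"""Time-correction of growing z-stacks by same-height contour morphing.

Each slice of an acquired z-stack belongs to a different instant, so a
direct reconstruction of a growing thrombus is time-skewed.  This module
morphs the segmented contours at each z-level between consecutive time
stacks and resamples an *instantaneous* z-stack at any requested timepoint
t* inside the correctable window.

The morph evolves the boundary as a level set: the contour at the first
timepoint is the initial zero level set of a signed-distance field (SDF)
which is driven toward the SDF of the second timepoint; the fixed point of
that evolution traces the zero level sets of linearly blended SDFs, which is
what is computed here.  The formulation is symmetric in its endpoints,
handles topology changes (splits/merges) for free, and appearance or
disappearance of a component becomes inflation from / deflation to a
collapse point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import measure as sk_measure

from .reconstruct import (
    SmoothingConfig,
    build_surface,
    convert_to_8bit,
    segment_stack,
)
from .types import (
    InvalidParameterError,
    ThrombotraceError,
    TriSurface,
    ZStack,
)

#: default intermediate time increment (s): the same order as the residual
#: time band a real instantaneous stack carries
DEFAULT_INCREMENT_S = 0.060


class OutOfWindowError(ThrombotraceError, ValueError):
    pass


# ----------------------------------------------------------------------
# signed-distance machinery
# ----------------------------------------------------------------------

def signed_distance(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """SDF of a binary mask: negative inside, positive outside, in μm."""
    mask = np.asarray(mask, dtype=bool)
    if mask.any():
        d_out = ndi.distance_transform_edt(~mask, sampling=pixel_size_um)
        d_in = ndi.distance_transform_edt(mask, sampling=pixel_size_um)
        return d_out - d_in
    return np.full(mask.shape, np.inf)


def _collapse_sdf(
    shape: tuple[int, int], pixel_size_um: float, center_rc: tuple[float, float]
) -> np.ndarray:
    """SDF of a component collapsed to a point (uniform positive distance)."""
    r = np.arange(shape[0])[:, None] - center_rc[0]
    c = np.arange(shape[1])[None, :] - center_rc[1]
    return np.hypot(r, c) * pixel_size_um


def blend_masks(
    mask1: np.ndarray, mask2: np.ndarray, s: float, pixel_size_um: float
) -> np.ndarray:
    """Intermediate mask at morph parameter s ∈ [0, 1] via linear SDF blending."""
    m1 = np.asarray(mask1, dtype=bool)
    m2 = np.asarray(mask2, dtype=bool)
    if s <= 0.0:
        return m1.copy()
    if s >= 1.0:
        return m2.copy()
    if not m1.any() and not m2.any():
        return np.zeros(m1.shape, dtype=bool)
    if m1.any():
        s1 = signed_distance(m1, pixel_size_um)
    else:
        s1 = _collapse_sdf(m1.shape, pixel_size_um, _centroid_rc(m2))
    if m2.any():
        s2 = signed_distance(m2, pixel_size_um)
    else:
        s2 = _collapse_sdf(m2.shape, pixel_size_um, _centroid_rc(m1))
    return (1.0 - s) * s1 + s * s2 < 0.0


def _centroid_rc(mask: np.ndarray) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    return float(rr.mean()), float(cc.mean())


# ----------------------------------------------------------------------
# contour-level morphing
# ----------------------------------------------------------------------

def _validate_simple(poly: np.ndarray) -> None:
    from shapely.geometry import Polygon

    if len(poly) >= 4 and not Polygon(poly).is_valid:
        raise InvalidParameterError("input polygon is self-intersecting")


def _rasterize(polys, pixel_size_um, shape, origin_xy) -> np.ndarray:
    from skimage.draw import polygon as sk_polygon

    mask = np.zeros(shape, dtype=bool)
    for poly in polys:
        rows = (np.asarray(poly)[:, 1] - origin_xy[1]) / pixel_size_um - 0.5
        cols = (np.asarray(poly)[:, 0] - origin_xy[0]) / pixel_size_um - 0.5
        rr, cc = sk_polygon(rows, cols, shape=shape)
        mask[rr, cc] = True
    return mask


def _contours_from_sdf(sdf: np.ndarray, pixel_size_um: float, origin_xy):
    polys = []
    finite = np.isfinite(sdf)
    if not finite.all():
        return polys
    for rc in sk_measure.find_contours(sdf, 0.0):
        x = (rc[:, 1] + 0.5) * pixel_size_um + origin_xy[0]
        y = (rc[:, 0] + 0.5) * pixel_size_um + origin_xy[1]
        poly = np.column_stack([x, y])
        if np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        if len(poly) >= 3:
            polys.append(poly)
    return polys


def morph_pair(
    contour_t1: np.ndarray | list[np.ndarray] | None,
    contour_t2: np.ndarray | list[np.ndarray] | None,
    n_intermediates: int,
    pixel_size_um: float = 0.31,
) -> list[list[np.ndarray]]:
    """Generate ``n_intermediates`` contours transitioning contour_t1 → contour_t2.

    Inputs are closed simple polygons in μm (or lists thereof, or None/empty
    for an absent component).  Intermediate k (1-based) is the zero level set
    at blend parameter s = k/(n+1).  Topology changes and empty ↔ non-empty
    transitions are handled by the SDF representation.
    """
    def as_list(c):
        if c is None:
            return []
        if isinstance(c, np.ndarray):
            return [c]
        return list(c)

    p1, p2 = as_list(contour_t1), as_list(contour_t2)
    for poly in p1 + p2:
        _validate_simple(np.asarray(poly))
    pts = np.concatenate([np.asarray(p) for p in p1 + p2]) if (p1 or p2) else None
    if pts is None:
        return [[] for _ in range(n_intermediates)]
    margin = 4.0 * pixel_size_um + 0.1 * float(
        np.ptp(pts, axis=0).max() if len(pts) else 1.0
    )
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = (
        int(math.ceil((hi[1] - lo[1]) / pixel_size_um)),
        int(math.ceil((hi[0] - lo[0]) / pixel_size_um)),
    )
    origin = (float(lo[0]), float(lo[1]))
    m1 = _rasterize(p1, pixel_size_um, shape, origin)
    m2 = _rasterize(p2, pixel_size_um, shape, origin)
    out = []
    for k in range(1, n_intermediates + 1):
        s = k / (n_intermediates + 1.0)
        if not m1.any() and not m2.any():
            out.append([])
            continue
        s1 = (
            signed_distance(m1, pixel_size_um)
            if m1.any()
            else _collapse_sdf(shape, pixel_size_um, _centroid_rc(m2))
        )
        s2 = (
            signed_distance(m2, pixel_size_um)
            if m2.any()
            else _collapse_sdf(shape, pixel_size_um, _centroid_rc(m1))
        )
        out.append(_contours_from_sdf((1 - s) * s1 + s * s2, pixel_size_um, origin))
    return out


def assign_frame_times(
    t_a: float, t_b: float, n_intermediates: int
) -> np.ndarray:
    """Timestamps of n intermediates between acquired times t_a < t_b.

    Intermediate k of n gets t = t_a + k·(t_b − t_a)/(n + 1): linear in the
    morph parameter.  Acquired frames keep their metadata times exactly.
    """
    if not (t_b > t_a):
        raise InvalidParameterError("acquired timestamps must be increasing")
    k = np.arange(1, n_intermediates + 1)
    return t_a + k * (t_b - t_a) / (n_intermediates + 1)


# ----------------------------------------------------------------------
# timelines across stacks
# ----------------------------------------------------------------------

@dataclass
class ZLevelTimeline:
    """Acquired (timestamp, mask) frames at one z-level, in time order."""

    z_um: float
    times: np.ndarray              # acquired timestamps, strictly increasing
    masks: list[np.ndarray]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError(
                f"timestamps at z={self.z_um} must be strictly increasing"
            )


@dataclass
class ContourTimeline:
    """Per-z-level acquired frames plus the intermediate sampling increment."""

    levels: list[ZLevelTimeline]
    pixel_size_um: float
    increment_s: float = DEFAULT_INCREMENT_S
    stack_windows: list[tuple[float, float]] = field(default_factory=list)

    @property
    def correctable_window(self) -> tuple[float, float]:
        """(end of first stack's acquisition, start of last stack's acquisition)."""
        if len(self.stack_windows) < 2:
            raise InvalidParameterError("need at least 2 stacks for time-correction")
        return (self.stack_windows[0][1], self.stack_windows[-1][0])


@dataclass
class InstantaneousStack:
    """A z-stack resampled to (nearly) a single timepoint t*."""

    t_star_s: float
    z_um: np.ndarray
    masks: list[np.ndarray]
    frame_times_s: np.ndarray
    pixel_size_um: float

    @property
    def dt_sample_span_s(self) -> float:
        """Residual time spread across the selected frames (max − min)."""
        return float(self.frame_times_s.max() - self.frame_times_s.min())


def build_timeline(
    stacks: list[ZStack],
    threshold: float | str = "auto",
    increment_s: float = DEFAULT_INCREMENT_S,
    z_tolerance_um: float | None = None,
) -> ContourTimeline:
    """Segment all stacks and pair same-z slices across time.

    A single Otsu threshold over all stacks keeps the segmentation
    consistent in time.  Slices are paired by z-position from metadata with
    a tolerance of half a slice thickness.
    """
    if len(stacks) < 2:
        raise InvalidParameterError("need at least 2 stacks")
    eight = [
        ZStack(slices=[convert_to_8bit(s) for s in st], index=st.index)
        for st in stacks
    ]
    if threshold == "auto":
        from .reconstruct import stack_otsu_threshold

        pooled = [s for st in eight for s in st]
        thr = stack_otsu_threshold(pooled)
        if thr is None:
            thr = 256  # blank: all masks empty
    else:
        thr = float(threshold)
    masks_per_stack = [segment_stack(st, threshold=thr) for st in eight]

    ps = stacks[0].pixel_size_um
    z_ref = stacks[0].z_um
    dz = float(np.median(np.diff(z_ref))) if len(z_ref) > 1 else 1.0
    tol = z_tolerance_um if z_tolerance_um is not None else dz / 2.0

    levels = []
    for iz, z in enumerate(z_ref):
        times, masks = [], []
        for st, mlist in zip(stacks, masks_per_stack):
            zs = st.z_um
            j = int(np.argmin(np.abs(zs - z)))
            if abs(zs[j] - z) > tol:
                continue
            times.append(st.slices[j].t_s)
            masks.append(mlist[j])
        if len(times) == len(stacks):
            levels.append(
                ZLevelTimeline(z_um=float(z), times=np.asarray(times), masks=masks)
            )
        else:
            warnings.warn(f"z-level {z} not present in all stacks; skipped")
    windows = [(st.t_start, st.t_end) for st in stacks]
    return ContourTimeline(
        levels=levels, pixel_size_um=ps, increment_s=increment_s,
        stack_windows=windows,
    )


def sample_instantaneous(
    timeline: ContourTimeline, t_star: float
) -> InstantaneousStack:
    """Resample the timeline into an instantaneous z-stack at t*.

    For each z-level the acquired-or-intermediate frame whose timestamp is
    nearest t* is selected; with intermediate increment δ the realized
    ΔT_sample_span is at most 2δ.
    """
    lo, hi = timeline.correctable_window
    if not (lo <= t_star <= hi):
        raise OutOfWindowError(
            f"t*={t_star:.3f} s outside the correctable window "
            f"[{lo:.3f}, {hi:.3f}] s (after the first stack's acquisition, "
            "before the last stack's start)"
        )
    zs, masks, times = [], [], []
    for lev in timeline.levels:
        ts = lev.times
        if t_star <= ts[0]:
            idx_b = 0
        else:
            idx_b = int(np.searchsorted(ts, t_star, side="right") - 1)
        idx_b = min(idx_b, len(ts) - 2)
        ta, tb = float(ts[idx_b]), float(ts[idx_b + 1])
        n = max(0, int(round((tb - ta) / timeline.increment_s)) - 1)
        cand_t = np.concatenate([[ta], assign_frame_times(ta, tb, n), [tb]])
        k = int(np.argmin(np.abs(cand_t - t_star)))
        t_sel = float(cand_t[k])
        s = (t_sel - ta) / (tb - ta)
        mask = blend_masks(
            lev.masks[idx_b], lev.masks[idx_b + 1], s, timeline.pixel_size_um
        )
        zs.append(lev.z_um)
        masks.append(mask)
        times.append(t_sel)
    return InstantaneousStack(
        t_star_s=float(t_star),
        z_um=np.asarray(zs),
        masks=masks,
        frame_times_s=np.asarray(times),
        pixel_size_um=timeline.pixel_size_um,
    )


def time_corrected_surface(
    stacks: list[ZStack],
    t_star: float,
    threshold: float | str = "auto",
    increment_s: float = DEFAULT_INCREMENT_S,
    smoothing: SmoothingConfig | None = None,
) -> tuple[TriSurface, InstantaneousStack]:
    """Instantaneous surface at t*: sample, stack, iso-surface, ripple-filter."""
    timeline = build_timeline(stacks, threshold=threshold, increment_s=increment_s)
    inst = sample_instantaneous(timeline, t_star)
    surface = build_surface(
        inst.masks, inst.z_um, inst.pixel_size_um, smoothing=smoothing, t_s=t_star
    )
    return surface, inst
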