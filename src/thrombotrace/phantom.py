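"""Synthetic growing thrombus geometries and a simulated confocal acquisition.

A confocal microscope images a z-stack slice by slice, bottom-up.  While the
stack is being scanned a thrombus keeps growing, so the acquired stack is
*time-skewed*: each slice belongs to a different instant.  This module
generates wall-attached implicit geometries (semi-ellipsoids, optionally with
smooth lobes) that grow in time, and renders them through a realistic
acquisition schedule (scan + transfer dead time, per-slice timestamps).
Every phantom also exposes its exact instantaneous volume and cross-sections,
which act as the ground truth for the time-correction machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .types import InvalidParameterError, SliceImage, ZStack

GrowthFn = Callable[[np.ndarray], np.ndarray]
"""Multiplicative semi-axis growth: g(t) with g(0) = 1, applied as a(t) = a0·g(t)."""


def linear_growth(rate_per_s: float) -> GrowthFn:
    """a(t) = a0·(1 + r·t)."""
    def g(t):
        return 1.0 + rate_per_s * np.asarray(t, dtype=float)
    return g


def exponential_growth(rate_per_s: float) -> GrowthFn:
    """a(t) = a0·exp(r·t)."""
    def g(t):
        return np.exp(rate_per_s * np.asarray(t, dtype=float))
    return g


def logistic_growth(rate_per_s: float, capacity_ratio: float = 2.0) -> GrowthFn:
    """Logistic semi-axis growth saturating at ``capacity_ratio``×a0.

    Thrombus growth decelerates as aggregates consolidate; a logistic curve
    is the default non-linear growth shape.  g(0) = 1 exactly.
    """
    if capacity_ratio <= 1.0:
        raise InvalidParameterError("capacity_ratio must be > 1")
    K = capacity_ratio

    def g(t):
        t = np.asarray(t, dtype=float)
        return K / (1.0 + (K - 1.0) * np.exp(-rate_per_s * K / (K - 1.0) * t))
    return g


def no_growth() -> GrowthFn:
    def g(t):
        return np.ones_like(np.asarray(t, dtype=float))
    return g


def rate_for_volume_ratio(ratio: float, duration_s: float) -> float:
    """Per-axis exponential rate so the volume grows by ``ratio`` in ``duration_s``.

    With equal exponential growth on all three semi-axes the volume scales as
    exp(3·r·t); r = ln(ratio)/(3·duration).  Used e.g. to hit a 12 % volume
    increase over one 3.5 s stack period.
    """
    if ratio <= 0 or duration_s <= 0:
        raise InvalidParameterError("ratio and duration must be > 0")
    return math.log(ratio) / (3.0 * duration_s)


@dataclass
class PhantomGeometry:
    """Wall-attached implicit geometry: a (possibly lobed) growing semi-ellipsoid.

    The interior at time t is ``{rho(p, t) <= 1 + eps(direction), z >= 0}``
    where rho is the ellipsoidal radius ``|(x/a(t), y/b(t), z/c(t))|`` and
    eps a smooth angular lobe perturbation (zero for a pure semi-ellipsoid).
    """

    a0: float
    b0: float
    c0: float
    growth: tuple[GrowthFn, GrowthFn, GrowthFn]
    lobe_amplitude: float = 0.0
    n_lobes: int = 0
    seed: int | None = None
    # internal, derived from seed: lobe harmonic coefficients/phases
    _lobe_params: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if min(self.a0, self.b0, self.c0) <= 0:
            raise InvalidParameterError("semi-axes must be > 0")
        min_axis = min(self.a0, self.b0, self.c0)
        if self.lobe_amplitude < 0:
            raise InvalidParameterError("lobe amplitude must be >= 0")
        if self.lobe_amplitude >= min_axis:
            raise InvalidParameterError(
                "lobe amplitude must be smaller than the smallest semi-axis "
                "(self-intersection risk)"
            )
        if self.lobe_amplitude > 0 and not self._lobe_params:
            rng = np.random.default_rng(self.seed)
            n = max(1, self.n_lobes)
            # low-order azimuthal harmonics with random phases; a z-direction
            # half-cosine keeps the perturbation attached smoothly at the wall
            self._lobe_params = {
                "orders": np.arange(1, n + 1),
                "amps": rng.uniform(0.5, 1.0, size=n),
                "phases": rng.uniform(0.0, 2.0 * np.pi, size=n),
            }

    # -- geometry --------------------------------------------------------
    def semi_axes(self, t: float) -> tuple[float, float, float]:
        ga, gb, gc = self.growth
        return (
            float(self.a0 * ga(t)),
            float(self.b0 * gb(t)),
            float(self.c0 * gc(t)),
        )

    def _eps(self, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
        """Relative radial lobe perturbation for scaled coordinates."""
        if self.lobe_amplitude == 0.0:
            return np.zeros(np.broadcast(xs, ys, zs).shape)
        p = self._lobe_params
        phi = np.arctan2(ys, xs)
        r = np.sqrt(xs * xs + ys * ys + zs * zs)
        with np.errstate(invalid="ignore"):
            cos_theta = np.where(r > 0, zs / np.maximum(r, 1e-30), 0.0)
        # vanish at the pole and at the wall (theta = pi/2) smoothly
        weight = np.clip(1.0 - cos_theta**2, 0.0, 1.0)
        w = np.zeros_like(phi)
        for m, A, ph in zip(p["orders"], p["amps"], p["phases"]):
            w = w + A * np.cos(m * phi + ph)
        w = w / np.sum(p["amps"])  # |w| <= 1
        rel = self.lobe_amplitude / min(self.a0, self.b0, self.c0)
        return rel * weight * w

    def inside(self, x, y, z, t: float) -> np.ndarray:
        """Boolean indicator of the interior at time t (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        a, b, c = self.semi_axes(t)
        xs, ys, zs = x / a, y / b, z / c
        rho = np.sqrt(xs * xs + ys * ys + zs * zs)
        eps = self._eps(xs, ys, zs)
        return (rho <= 1.0 + eps) & (z >= 0.0)

    def volume_um3(self, t: float, resolution_um: float = 0.25) -> float:
        """Exact instantaneous volume.

        Closed form (2/3)·π·a·b·c for the pure semi-ellipsoid; midpoint voxel
        quadrature at ``resolution_um`` for lobed geometries.
        """
        a, b, c = self.semi_axes(t)
        if self.lobe_amplitude == 0.0:
            return 2.0 / 3.0 * math.pi * a * b * c
        rel = self.lobe_amplitude / min(self.a0, self.b0, self.c0)
        ext = 1.0 + rel
        h = resolution_um
        x = np.arange(-a * ext, a * ext + h, h)
        y = np.arange(-b * ext, b * ext + h, h)
        z = np.arange(h / 2.0, c * ext + h, h)
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return float(np.count_nonzero(self.inside(X, Y, Z, t))) * h**3

    def cross_section_area_um2(
        self, z: float, t: float, resolution_um: float = 0.1
    ) -> float:
        """Exact area of the constant-z cross-section at time t."""
        a, b, c = self.semi_axes(t)
        if z < 0 or z > c * (1.0 + self.lobe_amplitude / min(self.a0, self.b0, self.c0)):
            return 0.0
        if self.lobe_amplitude == 0.0:
            if z > c:
                return 0.0
            s = 1.0 - (z / c) ** 2
            return math.pi * a * s**0.5 * b * s**0.5 if s > 0 else 0.0
        ext = 1.0 + self.lobe_amplitude / min(self.a0, self.b0, self.c0)
        h = resolution_um
        x = np.arange(-a * ext, a * ext + h, h)
        y = np.arange(-b * ext, b * ext + h, h)
        X, Y = np.meshgrid(x, y, indexing="ij")
        return float(np.count_nonzero(self.inside(X, Y, np.full_like(X, z), t))) * h**2

    def apex_um(self, t: float) -> float:
        """Height of the highest material point at time t."""
        a, b, c = self.semi_axes(t)
        return c  # lobe weight vanishes at the pole

    def bounding_box_um(self, t: float) -> tuple[float, float, float]:
        """(L, W, H) of the axis-aligned bounding box at time t."""
        a, b, c = self.semi_axes(t)
        rel = self.lobe_amplitude / min(self.a0, self.b0, self.c0)
        # lobes perturb mostly equatorial directions; bound conservatively
        if self.lobe_amplitude == 0.0:
            return 2 * a, 2 * b, c
        h = 0.2
        ext = 1.0 + rel
        x = np.arange(-a * ext, a * ext + h, h)
        y = np.arange(-b * ext, b * ext + h, h)
        z = np.arange(h / 2, c * ext + h, h)
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        m = self.inside(X, Y, Z, t)
        if not m.any():
            return 0.0, 0.0, 0.0
        return (
            float(X[m].max() - X[m].min()),
            float(Y[m].max() - Y[m].min()),
            float(Z[m].max()),
        )


def make_semi_ellipsoid_phantom(
    a0: float,
    b0: float,
    c0: float,
    growth_rates: float | Sequence[float] | Sequence[GrowthFn] | None = None,
    kind: str = "exponential",
    seed: int | None = None,
) -> PhantomGeometry:
    """Half-ellipsoid x²/a(t)² + y²/b(t)² + z²/c(t)² ≤ 1, z ≥ 0.

    ``growth_rates`` may be a single rate, three per-axis rates, three
    ready-made growth callables, or None (static).  ``kind`` selects the
    growth shape for numeric rates: "linear", "exponential" or "logistic".
    """
    if min(a0, b0, c0) <= 0:
        raise InvalidParameterError("semi-axes must be > 0")
    growth = _resolve_growth(growth_rates, kind)
    return PhantomGeometry(a0=a0, b0=b0, c0=c0, growth=growth, seed=seed)


def make_lobed_phantom(
    a0: float = 37.5,
    b0: float = 6.0,
    c0: float = 30.0,
    n_lobes: int = 4,
    lobe_amplitude: float = 1.2,
    growth_rates: float | Sequence[float] | Sequence[GrowthFn] | None = None,
    kind: str = "exponential",
    seed: int | None = None,
) -> PhantomGeometry:
    """Lobed semi-ellipsoid; defaults give a typical ~75 × 12 × 30 μm thrombus."""
    if min(a0, b0, c0) <= 0:
        raise InvalidParameterError("semi-axes must be > 0")
    if lobe_amplitude >= min(a0, b0, c0):
        raise InvalidParameterError(
            "lobe amplitude must be smaller than the smallest semi-axis"
        )
    growth = _resolve_growth(growth_rates, kind)
    return PhantomGeometry(
        a0=a0,
        b0=b0,
        c0=c0,
        growth=growth,
        lobe_amplitude=lobe_amplitude,
        n_lobes=n_lobes,
        seed=seed,
    )


def _resolve_growth(growth_rates, kind: str) -> tuple[GrowthFn, GrowthFn, GrowthFn]:
    makers = {
        "linear": linear_growth,
        "exponential": exponential_growth,
        "logistic": logistic_growth,
    }
    if kind not in makers:
        raise InvalidParameterError(f"unknown growth kind '{kind}'")
    make = makers[kind]
    if growth_rates is None:
        return (no_growth(), no_growth(), no_growth())
    if callable(growth_rates):
        return (growth_rates, growth_rates, growth_rates)
    if np.isscalar(growth_rates):
        g = make(float(growth_rates))
        return (g, g, g)
    items = list(growth_rates)
    if len(items) != 3:
        raise InvalidParameterError("growth_rates must be scalar or length 3")
    out = []
    for it in items:
        out.append(it if callable(it) else make(float(it)))
    return tuple(out)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Timing and sampling of the simulated confocal scan.

    Defaults follow the imaging protocol this package emulates: 0.5 μm
    slices at 0.31 μm/pixel, a 1.2 s bottom-up scan per stack and 2.3 s of
    data transfer between stacks (3.5 s stack period).
    """

    slice_thickness_um: float = 0.5
    pixel_size_um: float = 0.31
    width_px: int = 512
    height_px: int = 512
    scan_s: float = 1.2
    transfer_s: float = 2.3
    n_slices: int = 70
    n_stacks: int = 3
    guard_slices: int = 2           # blank slices scanned below the wall
    bit_depth: int = 12
    foreground_fraction: float = 0.75
    noise_sigma: float = 0.0        # additive Gaussian, in native intensity units
    salt_pepper_prob: float = 0.0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("slice_thickness_um", "pixel_size_um", "scan_s", "transfer_s"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be > 0")
        if self.n_slices < 1 or self.n_stacks < 1:
            raise InvalidParameterError("n_slices and n_stacks must be >= 1")
        if self.guard_slices < 0 or self.guard_slices >= self.n_slices:
            raise InvalidParameterError("guard_slices must be in [0, n_slices)")

    @property
    def slice_dt_s(self) -> float:
        """Per-slice timestamp increment = scan duration / number of slices."""
        return self.scan_s / self.n_slices

    @property
    def stack_period_s(self) -> float:
        """Scan + transfer time between consecutive stack starts."""
        return self.scan_s + self.transfer_s

    @property
    def foreground_value(self) -> int:
        return int(round(self.foreground_fraction * (2**self.bit_depth - 1)))

    def slice_z_um(self, k: int) -> float:
        return (k - self.guard_slices) * self.slice_thickness_um

    def slice_time_s(self, stack: int, k: int) -> float:
        return stack * self.stack_period_s + k * self.slice_dt_s


def render_slice(
    phantom: PhantomGeometry,
    z_um: float,
    t_s: float,
    schedule: AcquisitionSchedule,
    rng: np.random.Generator | None = None,
) -> SliceImage:
    """Render the phantom's cross-section at (z, t) as a confocal section.

    Foreground pixels take a constant fraction of full scale (default 75 % of
    the 12-bit range); background is 0.  Slices below the wall (z < 0) or
    above the apex are blank.  Optional seeded Gaussian + salt-and-pepper
    noise; off by default.
    """
    ps = schedule.pixel_size_um
    nx, ny = schedule.width_px, schedule.height_px
    x = (np.arange(nx) + 0.5) * ps - nx * ps / 2.0
    y = (np.arange(ny) + 0.5) * ps - ny * ps / 2.0
    img = np.zeros((ny, nx), dtype=np.uint16)
    if z_um >= 0.0:
        X, Y = np.meshgrid(x, y)
        mask = phantom.inside(X, Y, np.full_like(X, z_um), t_s)
        img[mask] = schedule.foreground_value
    if rng is not None and (schedule.noise_sigma > 0 or schedule.salt_pepper_prob > 0):
        data = img.astype(float)
        if schedule.noise_sigma > 0:
            data = data + rng.normal(0.0, schedule.noise_sigma, size=data.shape)
        if schedule.salt_pepper_prob > 0:
            full = 2**schedule.bit_depth - 1
            r = rng.random(data.shape)
            data[r < schedule.salt_pepper_prob / 2.0] = 0
            data[r > 1.0 - schedule.salt_pepper_prob / 2.0] = full
        img = np.clip(np.rint(data), 0, 2**schedule.bit_depth - 1).astype(np.uint16)
    return SliceImage(
        data=img,
        z_um=float(z_um),
        t_s=float(t_s),
        pixel_size_um=ps,
        bit_depth=schedule.bit_depth,
    )


def acquire_zstacks(
    phantom: PhantomGeometry, schedule: AcquisitionSchedule
) -> list[ZStack]:
    """Simulate the full time-skewed acquisition.

    Slice k of stack m is rendered from the phantom at its own timestamp
    ``t = m·(scan + transfer) + k·(scan / n_slices)``, scanning bottom-up, so
    a growing phantom yields the characteristic skew: lower slices are
    "older" than upper slices of the same stack.
    """
    stacks: list[ZStack] = []
    for m in range(schedule.n_stacks):
        rng = (
            np.random.default_rng((schedule.noise_seed, m))
            if schedule.noise_seed is not None
            else None
        )
        slices = []
        for k in range(schedule.n_slices):
            z = schedule.slice_z_um(k)
            t = schedule.slice_time_s(m, k)
            slices.append(render_slice(phantom, z, t, schedule, rng=rng))
        stacks.append(ZStack(slices=slices, index=m))
    return stacks
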