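"""Steady incompressible Newtonian flow in a rectangular microcapillary.

The blood-perfusion experiment this package models drives whole blood
through a 100 mm glass capillary of 2 × 0.2 mm cross-section at
1.44 ml/min, i.e. a nominal wall shear rate of 6Q/(wh²) = 1800 s⁻¹ in the
parallel-plate approximation.  This module provides

* the channel bookkeeping (nominal wall shear, hydraulic diameter, aspect
  ratio, Reynolds number),
* the exact Fourier-series solution for fully developed duct flow,
* a desk-scale steady Navier–Stokes solver on a staggered (MAC) grid with a
  voxelized no-slip thrombus obstacle, using pseudo-transient incremental
  pressure-correction iteration (implicit diffusion, explicit upwind
  advection, exact discrete projection each step), and
* the local shear-rate field γ = √(2 D:D), D = ½(∇U + ∇Uᵀ).

Internally the solver works in SI units; the public surface speaks μm for
geometry and m/s for velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from ._ray import MeshIntersector
from .types import InvalidParameterError, ThrombotraceError, TriSurface


class ConvergenceError(ThrombotraceError, RuntimeError):
    pass


# ----------------------------------------------------------------------
# channel geometry
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular microcapillary and its perfusion parameters.

    Dimensions in mm, flow rate in ml/min, viscosity in cP; height is the
    small dimension (h ≤ w).  Density is optional and only needed for the
    Reynolds number and the transient terms of the solver.
    """

    width_mm: float = 2.0
    height_mm: float = 0.2
    length_mm: float = 100.0
    flow_ml_min: float = 1.44
    viscosity_cP: float = 2.8
    density_kg_m3: float | None = None

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "length_mm", "viscosity_cP"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be > 0")
        if self.flow_ml_min < 0:
            raise InvalidParameterError("flow rate must be >= 0")
        if self.height_mm > self.width_mm:
            raise InvalidParameterError("height must not exceed width (h <= w)")

    # unit helpers
    @property
    def flow_mm3_s(self) -> float:
        return self.flow_ml_min * 1000.0 / 60.0

    @property
    def viscosity_Pa_s(self) -> float:
        return self.viscosity_cP * 1e-3

    @property
    def mean_velocity_m_s(self) -> float:
        return self.flow_mm3_s / (self.width_mm * self.height_mm) * 1e-3


def nominal_wall_shear(geom: ChannelGeometry) -> float:
    """Nominal wall shear rate γ_w = 6Q/(w·h²) in s⁻¹ (parallel-plate form)."""
    return 6.0 * geom.flow_mm3_s / (geom.width_mm * geom.height_mm**2)


def hydraulic_diameter(geom: ChannelGeometry) -> float:
    """D_h = 2wh/(w+h) in mm (4·area/perimeter of the rectangle)."""
    return 2.0 * geom.width_mm * geom.height_mm / (geom.width_mm + geom.height_mm)


def aspect_ratio(geom: ChannelGeometry) -> float:
    """AR = h/w (dimensionless, ≤ 1)."""
    return geom.height_mm / geom.width_mm


def reynolds(geom: ChannelGeometry, density_kg_m3: float | None = None) -> float:
    """Re = ρ·U_mean·D_h/μ based on the hydraulic diameter."""
    rho = density_kg_m3 if density_kg_m3 is not None else geom.density_kg_m3
    if rho is None:
        raise InvalidParameterError(
            "density is required for the Reynolds number; pass density_kg_m3"
        )
    return rho * geom.mean_velocity_m_s * hydraulic_diameter(geom) * 1e-3 / (
        geom.viscosity_Pa_s
    )


# ----------------------------------------------------------------------
# analytic rectangular-duct (Poiseuille) solution
# ----------------------------------------------------------------------

def _cosh_ratio(a: np.ndarray, b: float) -> np.ndarray:
    """cosh(a)/cosh(b) computed stably for large arguments (|a| <= b)."""
    a = np.asarray(a, dtype=float)
    return np.exp(np.abs(a) - b) * (1.0 + np.exp(-2.0 * np.abs(a))) / (
        1.0 + math.exp(-2.0 * b)
    )


def _duct_pressure_scale(geom: ChannelGeometry, n_terms: int = 101) -> float:
    """G/μ (1/(m·s)) such that the series profile integrates to Q."""
    w = geom.width_mm * 1e-3
    h = geom.height_mm * 1e-3
    Q = geom.flow_mm3_s * 1e-9
    series = 0.0
    for n in range(1, n_terms + 1, 2):
        series += math.tanh(n * math.pi * w / (2.0 * h)) / n**5
    factor = h**3 * w / 12.0 * (1.0 - 192.0 * h / (math.pi**5 * w) * series)
    return Q / factor


def analytic_duct_velocity(
    geom: ChannelGeometry, y_um, z_um, rel_tol: float = 1e-8
) -> np.ndarray:
    """Fully developed axial velocity u(y, z) in m/s.

    y ∈ [0, w], z ∈ [0, h] in μm; the Fourier series is truncated once the
    next term changes the result by less than ``rel_tol`` relative.
    """
    w = geom.width_mm * 1e-3
    h = geom.height_mm * 1e-3
    y = np.asarray(y_um, dtype=float) * 1e-6
    z = np.asarray(z_um, dtype=float) * 1e-6
    y, z = np.broadcast_arrays(y, z)
    if np.any((y < -1e-12) | (y > w + 1e-12) | (z < -1e-12) | (z > h + 1e-12)):
        raise InvalidParameterError("point outside the duct cross-section")
    Gmu = _duct_pressure_scale(geom)
    u = np.zeros_like(y)
    scale = 4.0 * h**2 / math.pi**3 * Gmu
    n = 1
    while True:
        term = (
            scale
            / n**3
            * (1.0 - _cosh_ratio(n * math.pi * (y - w / 2.0) / h,
                                 n * math.pi * w / (2.0 * h)))
            * np.sin(n * math.pi * z / h)
        )
        u = u + term
        bound = scale / n**3  # envelope of the next terms
        if bound < rel_tol * max(float(np.max(np.abs(u))), 1e-300) or n > 20001:
            break
        n += 2
    return u


def analytic_duct_wall_shear(geom: ChannelGeometry, y_um, rel_tol: float = 1e-10):
    """du/dz at the floor (z = 0) in s⁻¹, as a function of y (μm)."""
    w = geom.width_mm * 1e-3
    h = geom.height_mm * 1e-3
    y = np.asarray(y_um, dtype=float) * 1e-6
    Gmu = _duct_pressure_scale(geom)
    g = np.zeros_like(y)
    scale = 4.0 * h / math.pi**2 * Gmu
    n = 1
    while True:
        term = scale / n**2 * (
            1.0 - _cosh_ratio(n * math.pi * (y - w / 2.0) / h,
                              n * math.pi * w / (2.0 * h))
        )
        g = g + term
        if scale / n**2 < rel_tol * max(float(np.max(np.abs(g))), 1e-300) or n > 200001:
            break
        n += 2
    return g


class AnalyticDuctField:
    """Empty-duct velocity/shear sampler with the tracer-field protocol.

    The duct spans x ∈ [0, L], y ∈ [0, w], z ∈ [0, h] (μm).  The flow is
    unidirectional, so pathlines are straight lines in x.
    """

    def __init__(self, geom: ChannelGeometry, length_um: float | None = None):
        self.geom = geom
        self.length_um = (
            float(length_um) if length_um is not None else geom.length_mm * 1e3
        )
        self.width_um = geom.width_mm * 1e3
        self.height_um = geom.height_mm * 1e3
        self.x_inlet_um = 0.0

    @property
    def bounds_um(self):
        return (
            np.array([0.0, 0.0, 0.0]),
            np.array([self.length_um, self.width_um, self.height_um]),
        )

    def velocity_um_s(self, points_um: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        y = np.clip(p[:, 1], 0.0, self.width_um)
        z = np.clip(p[:, 2], 0.0, self.height_um)
        u = analytic_duct_velocity(self.geom, y, z) * 1e6
        out = np.zeros_like(p)
        out[:, 0] = u
        return out

    def gamma_s(self, points_um: np.ndarray) -> np.ndarray:
        """Local shear rate √((du/dy)² + (du/dz)²) by central differences."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        eps = 1e-2  # μm
        y = np.clip(p[:, 1], eps, self.width_um - eps)
        z = np.clip(p[:, 2], eps, self.height_um - eps)
        dudy = (
            analytic_duct_velocity(self.geom, y + eps, z)
            - analytic_duct_velocity(self.geom, y - eps, z)
        ) / (2 * eps * 1e-6)
        dudz = (
            analytic_duct_velocity(self.geom, y, z + eps)
            - analytic_duct_velocity(self.geom, y, z - eps)
        ) / (2 * eps * 1e-6)
        return np.hypot(dudy, dudz)


# ----------------------------------------------------------------------
# staggered-grid solver
# ----------------------------------------------------------------------

# beyond-edge boundary codes for the 7-point operators
_WALL_HALF = "wall_half"   # no-slip wall half a spacing beyond: ghost = -value
_NEUMANN = "neumann"       # zero gradient: ghost = value
_BLOCK = "block"           # no coupling beyond (used by the pressure operator)


def _laplacian(shape, spacing, side_bc, fixed, insulate_fixed=False):
    """Sparse 7-point Laplacian on a box grid with mixed boundary handling.

    ``side_bc[axis] = (minus, plus)`` gives the beyond-edge rule per side;
    ``fixed`` is a boolean mask of Dirichlet nodes (their rows are zero;
    the caller adds whatever diagonal it needs there).  With
    ``insulate_fixed`` couplings between free and fixed nodes are dropped
    entirely (zero-flux, as the pressure equation needs at solid cells);
    otherwise fixed neighbours keep their off-diagonals so their Dirichlet
    values enter the stencil through the solution vector.
    """
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    fixed = fixed.reshape(shape)
    diag = np.zeros(shape)
    rows, cols, vals = [], [], []
    free = ~fixed
    for axis in range(3):
        h2 = spacing[axis] ** 2
        for sign in (-1, 1):
            sl_src = [slice(None)] * 3
            sl_edge = [slice(None)] * 3
            if sign < 0:
                sl_src[axis] = slice(1, None)
                sl_edge[axis] = slice(0, 1)
            else:
                sl_src[axis] = slice(0, -1)
                sl_edge[axis] = slice(-1, None)
            inner = np.zeros(shape, dtype=bool)
            inner[tuple(sl_src)] = True
            has_nb = inner & free
            nb_fixed = np.roll(fixed, -sign, axis=axis)
            if insulate_fixed:
                has_nb &= ~nb_fixed
            nb_idx = np.roll(idx, -sign, axis=axis)
            r = idx[has_nb]
            c = nb_idx[has_nb]
            rows.append(r)
            cols.append(c)
            vals.append(np.full(len(r), 1.0 / h2))
            diag[has_nb] -= 1.0 / h2
            # beyond-edge handling
            edge = np.zeros(shape, dtype=bool)
            edge[tuple(sl_edge)] = True
            edge &= free
            bc = side_bc[axis][0 if sign < 0 else 1]
            if bc == _WALL_HALF:
                # no-slip/Dirichlet-0 surface half a spacing beyond the node:
                # ghost = -value, so this side contributes -2/h² to the diagonal
                diag[edge] -= 2.0 / h2
            elif bc == _NEUMANN:
                pass  # ghost = value: no contribution from this side
            elif bc == _BLOCK:
                pass
            else:
                raise ValueError(f"unknown bc {bc}")
    r = idx[free]
    rows.append(r)
    cols.append(r)
    vals.append(diag[free])
    L = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return L


@dataclass
class FlowField:
    """Converged staggered-grid solution around an (optional) obstacle.

    Velocities in m/s on the MAC grid, pressure in Pa, geometry in μm.
    ``u`` has shape (nx+1, ny, nz) at x-faces, ``v`` (nx, ny+1, nz),
    ``w`` (nx, ny, nz+1); ``p`` and ``solid`` are cell-centred.
    """

    geom: ChannelGeometry
    shape: tuple[int, int, int]
    spacing_um: tuple[float, float, float]
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    solid: np.ndarray
    residuals: list[float] = field(default_factory=list)
    converged: bool = True
    inlet_profile: np.ndarray | None = None

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * h for n, h in zip(self.shape, self.spacing_um))

    def cell_centers_um(self):
        return tuple(
            (np.arange(n) + 0.5) * h
            for n, h in zip(self.shape, self.spacing_um)
        )

    def center_velocity(self) -> np.ndarray:
        """(nx, ny, nz, 3) velocity resampled to cell centres (m/s)."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        out = np.stack([uc, vc, wc], axis=-1)
        out[self.solid] = 0.0
        return out

    def divergence(self) -> np.ndarray:
        """Discrete divergence per cell (1/s); ~0 in fluid cells."""
        dx, dy, dz = (h * 1e-6 for h in self.spacing_um)
        div = (
            (self.u[1:] - self.u[:-1]) / dx
            + (self.v[:, 1:] - self.v[:, :-1]) / dy
            + (self.w[:, :, 1:] - self.w[:, :, :-1]) / dz
        )
        div[self.solid] = 0.0
        return div

    def flux_m3_s(self, i: int) -> float:
        """Volumetric flux through the x-face plane i (0..nx)."""
        dy, dz = self.spacing_um[1] * 1e-6, self.spacing_um[2] * 1e-6
        return float(np.sum(self.u[i]) * dy * dz)

    def tracer_field(self, shear: "ShearField | None" = None) -> "GridTracerField":
        return GridTracerField(self, shear)


def voxelize_obstacle(
    surface: TriSurface, shape, spacing_um, origin_um=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Cell-centred inside mask of a watertight surface on the solver grid."""
    surface.require_watertight("flow obstacle")
    nx, ny, nz = shape
    hx, hy, hz = spacing_um
    ox, oy, oz = origin_um
    lo, hi = surface.mesh.bounds
    solid = np.zeros(shape, dtype=bool)
    i0 = max(0, int((lo[0] - ox) // hx) - 1)
    i1 = min(nx, int((hi[0] - ox) // hx) + 2)
    j0 = max(0, int((lo[1] - oy) // hy) - 1)
    j1 = min(ny, int((hi[1] - oy) // hy) + 2)
    k0 = max(0, int((lo[2] - oz) // hz) - 1)
    k1 = min(nz, int((hi[2] - oz) // hz) + 2)
    if i1 <= i0 or j1 <= j0 or k1 <= k0:
        return solid
    xs = ox + (np.arange(i0, i1) + 0.5) * hx
    ys = oy + (np.arange(j0, j1) + 0.5) * hy
    zs = oz + (np.arange(k0, k1) + 0.5) * hz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = MeshIntersector(surface.mesh).contains(pts)
    solid[i0:i1, j0:j1, k0:k1] = inside.reshape(X.shape)
    return solid


def solve_steady_flow(
    geom: ChannelGeometry,
    obstacle: TriSurface | None = None,
    shape: tuple[int, int, int] = (16, 64, 32),
    domain_length_um: float | None = None,
    tol: float = 1e-8,
    max_steps: int = 20000,
    cfl: float = 0.5,
    density_kg_m3: float | None = None,
) -> FlowField:
    """March the incompressible Navier–Stokes equations to steady state.

    Staggered MAC grid over x ∈ [0, L], y ∈ [0, w], z ∈ [0, h]; the inlet
    imposes the analytic fully developed profile directly (equivalent to the
    long entrance region, far cheaper), the outlet holds a fixed pressure,
    and all walls plus the voxelized obstacle are no-slip.  Each pseudo-time
    step treats diffusion implicitly (pre-factorised sparse solves), advects
    explicitly with first-order upwinding, and projects onto the
    divergence-free space exactly.  Converged when the normalized
    steady-state residual (max velocity change per advective time unit)
    drops below ``tol``.
    """
    nx, ny, nz = shape
    w_um = geom.width_mm * 1e3
    h_um = geom.height_mm * 1e3
    L_um = (
        float(domain_length_um)
        if domain_length_um is not None
        else 2.0 * w_um
    )
    hx, hy, hz = L_um / nx, w_um / ny, h_um / nz
    dx, dy, dz = hx * 1e-6, hy * 1e-6, hz * 1e-6
    rho = (
        density_kg_m3
        if density_kg_m3 is not None
        else (geom.density_kg_m3 if geom.density_kg_m3 is not None else 1000.0)
    )
    nu = geom.viscosity_Pa_s / rho

    # obstacle voxelization
    if obstacle is not None:
        lo, hi = obstacle.mesh.bounds
        if (
            lo[0] < 0 or hi[0] > L_um or lo[1] < 0 or hi[1] > w_um
            or lo[2] < -1e-9 or hi[2] > h_um
        ):
            raise InvalidParameterError(
                "obstacle does not fit inside the channel domain"
            )
        solid = voxelize_obstacle(obstacle, shape, (hx, hy, hz))
    else:
        solid = np.zeros(shape, dtype=bool)

    # inlet profile at u-face (y, z) cell centres, rescaled to match Q exactly
    yc = (np.arange(ny) + 0.5) * hy
    zc = (np.arange(nz) + 0.5) * hz
    Yc, Zc = np.meshgrid(yc, zc, indexing="ij")
    u_in = analytic_duct_velocity(geom, Yc, Zc)
    Q = geom.flow_mm3_s * 1e-9
    flux = float(u_in.sum() * dy * dz)
    if flux > 0:
        u_in = u_in * (Q / flux)

    # fixed (Dirichlet-0 or inlet) face masks
    fixed_u = np.zeros((nx + 1, ny, nz), dtype=bool)
    fixed_u[0] = True
    solid_pad = np.pad(solid, ((1, 1), (0, 0), (0, 0)))
    fixed_u |= solid_pad[:-1] | solid_pad[1:]
    fixed_v = np.zeros((nx, ny + 1, nz), dtype=bool)
    fixed_v[:, 0] = True
    fixed_v[:, -1] = True
    solid_pad = np.pad(solid, ((0, 0), (1, 1), (0, 0)))
    fixed_v |= solid_pad[:, :-1] | solid_pad[:, 1:]
    fixed_w = np.zeros((nx, ny, nz + 1), dtype=bool)
    fixed_w[:, :, 0] = True
    fixed_w[:, :, -1] = True
    solid_pad = np.pad(solid, ((0, 0), (0, 0), (1, 1)))
    fixed_w |= solid_pad[:, :, :-1] | solid_pad[:, :, 1:]

    spacing = (dx, dy, dz)
    Lu = _laplacian(
        (nx + 1, ny, nz), spacing,
        ((_NEUMANN, _NEUMANN), (_WALL_HALF, _WALL_HALF), (_WALL_HALF, _WALL_HALF)),
        fixed_u,
    )
    Lv = _laplacian(
        (nx, ny + 1, nz), spacing,
        ((_WALL_HALF, _NEUMANN), (_NEUMANN, _NEUMANN), (_WALL_HALF, _WALL_HALF)),
        fixed_v,
    )
    Lw = _laplacian(
        (nx, ny, nz + 1), spacing,
        ((_WALL_HALF, _NEUMANN), (_WALL_HALF, _WALL_HALF), (_NEUMANN, _NEUMANN)),
        fixed_w,
    )
    # pressure Poisson: zero-flux at walls/inlet/solid, Dirichlet 0 at the
    # outlet face; solid couplings are insulated in the assembly
    Lp = _laplacian(
        shape, spacing,
        ((_BLOCK, _WALL_HALF), (_BLOCK, _BLOCK), (_BLOCK, _BLOCK)),
        solid, insulate_fixed=True,
    )

    # explicit-advection CFL limit: with no obstacle the flow stays
    # unidirectional, so only the x-CFL binds; with an obstacle, transverse
    # velocities appear and the smallest spacing governs
    u_scale = max(2.0 * float(u_in.max()), 1e-12)
    dt = cfl * (min(dx, dy, dz) if solid.any() else dx) / u_scale

    class _VelocitySolver:
        """CG on the free-face Helmholtz system (I/dt − ν∇²), SPD and
        strongly diagonally dominant, Jacobi-preconditioned."""

        def __init__(self, L, fixed, fixed_values):
            n = L.shape[0]
            A = sp.eye(n, format="csr") / dt - nu * L
            f = fixed.ravel()
            self.free = ~f
            Af = A[self.free]
            self.Aff = sp.csr_matrix(Af[:, self.free])
            # constant RHS correction from Dirichlet faces (inlet profile)
            xfix = fixed_values.ravel()[f]
            self.bcorr = Af[:, f] @ xfix
            d = self.Aff.diagonal()
            self.M = spla.LinearOperator(
                self.Aff.shape, matvec=lambda x: x / d
            )
            self.prev = None

        def solve(self, rhs_full):
            b = rhs_full.ravel()[self.free] - self.bcorr
            x, info = spla.cg(
                self.Aff, b, x0=self.prev, M=self.M, rtol=1e-10, atol=0.0
            )
            if info != 0:
                raise ConvergenceError("velocity Helmholtz CG failed")
            self.prev = x
            return x

    uin_full = np.zeros((nx + 1, ny, nz))
    uin_full[0] = u_in
    Su = _VelocitySolver(Lu, fixed_u, uin_full)
    Sv = _VelocitySolver(Lv, fixed_v, np.zeros((nx, ny + 1, nz)))
    Sw = _VelocitySolver(Lw, fixed_w, np.zeros((nx, ny, nz + 1)))

    # pressure Poisson on fluid cells: direct sparse factorisation, reused
    # every step so each projection is exact to machine precision
    free_p = ~solid.ravel()
    App = sp.csc_matrix((-Lp)[free_p][:, free_p])
    lu_p = spla.splu(App)

    def solve_pressure(rhs_full):
        b = rhs_full.ravel()[free_p]
        out = np.zeros(np.prod(shape))
        out[free_p] = lu_p.solve(b)
        return out.reshape(shape)

    # initial condition: developed profile everywhere, fixed faces zeroed
    u = np.broadcast_to(u_in, (nx + 1, ny, nz)).copy()
    u[fixed_u] = 0.0
    u[0] = u_in
    v = np.zeros((nx, ny + 1, nz))
    w = np.zeros((nx, ny, nz + 1))
    p = np.zeros(shape)

    U_ref = max(float(u_in.max()), 1e-12)
    T_adv = L_um * 1e-6 / U_ref
    residuals: list[float] = []
    converged = False

    def upwind_conv(comp, adv_x, adv_y, adv_z):
        """First-order upwind advective derivative adv·∇comp."""
        g = np.pad(comp, 1, mode="edge")
        out = np.zeros_like(comp)
        for axis, (a, h) in enumerate(zip((adv_x, adv_y, adv_z), (dx, dy, dz))):
            sl_c = [slice(1, -1)] * 3
            sl_m = list(sl_c)
            sl_m[axis] = slice(0, -2)
            sl_p = list(sl_c)
            sl_p[axis] = slice(2, None)
            back = (g[tuple(sl_c)] - g[tuple(sl_m)]) / h
            fwd = (g[tuple(sl_p)] - g[tuple(sl_c)]) / h
            out += np.where(a > 0, a * back, a * fwd)
        return out

    def avg_to_u(vv, ww):
        # v, w averaged to u-face locations (nx+1, ny, nz)
        vc = 0.5 * (vv[:, :-1, :] + vv[:, 1:, :])      # cell centres
        v4 = np.concatenate([vc[:1], 0.5 * (vc[1:] + vc[:-1]), vc[-1:]], axis=0)
        wc = 0.5 * (ww[:, :, :-1] + ww[:, :, 1:])
        w4 = np.concatenate([wc[:1], 0.5 * (wc[1:] + wc[:-1]), wc[-1:]], axis=0)
        return v4, w4

    def avg_to_v(uu, ww):
        u4 = 0.5 * (uu[:-1] + uu[1:])
        u4 = np.concatenate(
            [u4[:, :1], 0.5 * (u4[:, 1:] + u4[:, :-1]), u4[:, -1:]], axis=1
        )
        w4 = 0.5 * (ww[:, :, :-1] + ww[:, :, 1:])
        w4 = np.concatenate(
            [w4[:, :1], 0.5 * (w4[:, 1:] + w4[:, :-1]), w4[:, -1:]], axis=1
        )
        return u4, w4

    def avg_to_w(uu, vv):
        u4 = 0.5 * (uu[:-1] + uu[1:])
        u4 = np.concatenate(
            [u4[:, :, :1], 0.5 * (u4[:, :, 1:] + u4[:, :, :-1]), u4[:, :, -1:]],
            axis=2,
        )
        v4 = 0.5 * (vv[:, :-1] + vv[:, 1:])
        v4 = np.concatenate(
            [v4[:, :, :1], 0.5 * (v4[:, :, 1:] + v4[:, :, :-1]), v4[:, :, -1:]],
            axis=2,
        )
        return u4, v4

    for step in range(max_steps):
        # advection terms
        vu, wu = avg_to_u(v, w)
        conv_u = upwind_conv(u, u, vu, wu)
        uv, wv = avg_to_v(u, w)
        conv_v = upwind_conv(v, uv, v, wv)
        uw, vw = avg_to_w(u, v)
        conv_w = upwind_conv(w, uw, vw, w)

        # pressure gradients at faces (interior only)
        gpx = np.zeros_like(u)
        gpx[1:-1] = (p[1:] - p[:-1]) / dx
        gpx[-1] = (0.0 - p[-1]) / (dx / 2.0)  # outlet face holds p = 0
        gpy = np.zeros_like(v)
        gpy[:, 1:-1] = (p[:, 1:] - p[:, :-1]) / dy
        gpz = np.zeros_like(w)
        gpz[:, :, 1:-1] = (p[:, :, 1:] - p[:, :, :-1]) / dz

        bu = u / dt - conv_u - gpx / rho
        bv = v / dt - conv_v - gpy / rho
        bw = w / dt - conv_w - gpz / rho

        us = np.zeros_like(u)
        us.ravel()[Su.free] = Su.solve(bu)
        us[0] = u_in
        vs = np.zeros_like(v)
        vs.ravel()[Sv.free] = Sv.solve(bv)
        ws = np.zeros_like(w)
        ws.ravel()[Sw.free] = Sw.solve(bw)

        # projection: solve ∇²φ = ρ div(u*)/dt, correct to divergence-free
        div = (
            (us[1:] - us[:-1]) / dx
            + (vs[:, 1:] - vs[:, :-1]) / dy
            + (ws[:, :, 1:] - ws[:, :, :-1]) / dz
        )
        rhs = -(rho / dt) * div
        rhs[solid] = 0.0
        phi = solve_pressure(rhs)

        un = us.copy()
        un[1:-1] -= dt / rho * (phi[1:] - phi[:-1]) / dx
        un[-1] -= dt / rho * (0.0 - phi[-1]) / (dx / 2.0)
        un[fixed_u] = 0.0
        un[0] = u_in
        vn = vs.copy()
        vn[:, 1:-1] -= dt / rho * (phi[:, 1:] - phi[:, :-1]) / dy
        vn[fixed_v] = 0.0
        wn = ws.copy()
        wn[:, :, 1:-1] -= dt / rho * (phi[:, :, 1:] - phi[:, :, :-1]) / dz
        wn[fixed_w] = 0.0
        p = p + phi

        res = max(
            float(np.max(np.abs(un - u))),
            float(np.max(np.abs(vn - v))),
            float(np.max(np.abs(wn - w))),
        ) * T_adv / (U_ref * dt)
        residuals.append(res)
        u, v, w = un, vn, wn
        if res < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"flow solver did not reach tol={tol:g} in {max_steps} steps "
            f"(last residual {residuals[-1]:.3e})"
        )
    return FlowField(
        geom=geom,
        shape=shape,
        spacing_um=(hx, hy, hz),
        u=u,
        v=v,
        w=w,
        p=p,
        solid=solid,
        residuals=residuals,
        converged=converged,
        inlet_profile=u_in,
    )


# ----------------------------------------------------------------------
# shear-rate field
# ----------------------------------------------------------------------

@dataclass
class ShearField:
    """Local shear rate γ = √(2 D:D) (s⁻¹) and the rate-of-strain tensor."""

    gamma: np.ndarray               # (nx, ny, nz)
    D: np.ndarray                   # (nx, ny, nz, 3, 3), 1/s
    spacing_um: tuple[float, float, float]


def shear_from_gradients(grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """γ and D from a velocity-gradient array ∇U with shape (..., 3, 3).

    Follows the rheological convention D = ½(∇U + ∇Uᵀ), γ = √(2 D:D), which
    recovers the imposed rate in simple shear and vanishes for rigid-body
    rotation.
    """
    D = 0.5 * (grad + np.swapaxes(grad, -1, -2))
    gamma = np.sqrt(2.0 * np.einsum("...ij,...ij->...", D, D))
    return gamma, D


def compute_shear_field(field: FlowField) -> ShearField:
    """Shear-rate field on cell centres.

    Central differences in the interior; boundary-adjacent cells difference
    against explicit no-slip wall values (and the inlet profile), so
    near-wall gradients account for the walls rather than being one-sidedly
    extrapolated.  Cells inside the obstacle report γ = 0.
    """
    hx, hy, hz = (h * 1e-6 for h in field.spacing_um)
    nx, ny, nz = field.shape
    U = field.center_velocity()  # (nx, ny, nz, 3)
    # extended grids with wall/inlet nodes carrying boundary values
    x = np.concatenate([[0.0], (np.arange(nx) + 0.5) * hx, [nx * hx]])
    y = np.concatenate([[0.0], (np.arange(ny) + 0.5) * hy, [ny * hy]])
    z = np.concatenate([[0.0], (np.arange(nz) + 0.5) * hz, [nz * hz]])
    Ue = np.zeros((nx + 2, ny + 2, nz + 2, 3))
    Ue[1:-1, 1:-1, 1:-1] = U
    # inlet: the imposed profile; outlet: zero-gradient copy
    if field.inlet_profile is not None:
        Ue[0, 1:-1, 1:-1, 0] = field.inlet_profile
    Ue[-1, 1:-1, 1:-1] = Ue[-2, 1:-1, 1:-1]
    # walls stay zero (no-slip)
    grad = np.empty((nx, ny, nz, 3, 3))
    for c in range(3):
        gx = np.gradient(Ue[..., c], x, axis=0)
        gy = np.gradient(Ue[..., c], y, axis=1)
        gz = np.gradient(Ue[..., c], z, axis=2)
        grad[..., c, 0] = gx[1:-1, 1:-1, 1:-1]
        grad[..., c, 1] = gy[1:-1, 1:-1, 1:-1]
        grad[..., c, 2] = gz[1:-1, 1:-1, 1:-1]
    gamma, D = shear_from_gradients(grad)
    gamma[field.solid] = 0.0
    return ShearField(gamma=gamma, D=D, spacing_um=field.spacing_um)


def floor_wall_shear(field: FlowField) -> np.ndarray:
    """Wall shear rate at z = 0 per (x, y) column, s⁻¹.

    Quadratic one-sided stencil through the wall and the first two
    cell-centre velocities: du/dz|₀ = (9u₀ − u₁)/(3Δz); exact for the
    parabolic near-wall profile.
    """
    dz = field.spacing_um[2] * 1e-6
    U = field.center_velocity()
    su = (9.0 * U[:, :, 0, 0] - U[:, :, 1, 0]) / (3.0 * dz)
    sv = (9.0 * U[:, :, 0, 1] - U[:, :, 1, 1]) / (3.0 * dz)
    return np.hypot(su, sv)


# ----------------------------------------------------------------------
# tracer-field protocol over a solved grid
# ----------------------------------------------------------------------

class ArrayTracerField:
    """Tracer field over cell-centred arrays (e.g. read back from VTK).

    Walls are padded with no-slip zeros; without the staggered data the
    inlet plane clamps to the first cell column, adequate for tracing well
    inside the domain.
    """

    def __init__(self, U_m_s, spacing_um, gamma=None, solid=None):
        U = np.asarray(U_m_s, dtype=float)
        nx, ny, nz, _ = U.shape
        hx, hy, hz = spacing_um
        self.shape = (nx, ny, nz)
        self.spacing_um = tuple(spacing_um)
        self.solid = (
            np.asarray(solid, dtype=bool)
            if solid is not None
            else np.zeros((nx, ny, nz), dtype=bool)
        )
        x = np.concatenate([[0.0], (np.arange(nx) + 0.5) * hx, [nx * hx]])
        y = np.concatenate([[0.0], (np.arange(ny) + 0.5) * hy, [ny * hy]])
        z = np.concatenate([[0.0], (np.arange(nz) + 0.5) * hz, [nz * hz]])
        Ue = np.zeros((nx + 2, ny + 2, nz + 2, 3))
        Ue[1:-1, 1:-1, 1:-1] = U * 1e6
        Ue[0, 1:-1, 1:-1] = Ue[1, 1:-1, 1:-1]
        Ue[-1, 1:-1, 1:-1] = Ue[-2, 1:-1, 1:-1]
        self._interp = RegularGridInterpolator(
            (x, y, z), Ue, bounds_error=False, fill_value=None
        )
        self._gamma_interp = None
        if gamma is not None:
            G = np.zeros((nx + 2, ny + 2, nz + 2))
            G[1:-1, 1:-1, 1:-1] = gamma
            G[0], G[-1] = G[1], G[-2]
            G[:, 0], G[:, -1] = G[:, 1], G[:, -2]
            G[:, :, 0], G[:, :, -1] = G[:, :, 1], G[:, :, -2]
            self._gamma_interp = RegularGridInterpolator(
                (x, y, z), G, bounds_error=False, fill_value=None
            )
        self.x_inlet_um = 0.0

    @property
    def bounds_um(self):
        return np.zeros(3), np.array(
            [n * h for n, h in zip(self.shape, self.spacing_um)]
        )

    def velocity_um_s(self, points_um) -> np.ndarray:
        return self._interp(np.atleast_2d(np.asarray(points_um, dtype=float)))

    def gamma_s(self, points_um) -> np.ndarray:
        if self._gamma_interp is None:
            raise InvalidParameterError("no shear data in this field")
        return self._gamma_interp(np.atleast_2d(np.asarray(points_um, dtype=float)))

    def in_solid(self, points_um) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        hx, hy, hz = self.spacing_um
        nx, ny, nz = self.shape
        i = np.clip((p[:, 0] // hx).astype(int), 0, nx - 1)
        j = np.clip((p[:, 1] // hy).astype(int), 0, ny - 1)
        k = np.clip((p[:, 2] // hz).astype(int), 0, nz - 1)
        return self.solid[i, j, k]


class GridTracerField:
    """Trilinear velocity/shear sampler over a solved FlowField (μm, μm/s)."""

    def __init__(self, field: FlowField, shear: ShearField | None = None):
        self.field = field
        nx, ny, nz = field.shape
        hx, hy, hz = field.spacing_um
        xc, yc, zc = field.cell_centers_um()
        # extended axes with wall/inlet planes carrying boundary values
        self._x = np.concatenate([[0.0], xc, [nx * hx]])
        self._y = np.concatenate([[0.0], yc, [ny * hy]])
        self._z = np.concatenate([[0.0], zc, [nz * hz]])
        U = field.center_velocity() * 1e6  # μm/s
        Ue = np.zeros((nx + 2, ny + 2, nz + 2, 3))
        Ue[1:-1, 1:-1, 1:-1] = U
        if field.inlet_profile is not None:
            Ue[0, 1:-1, 1:-1, 0] = field.inlet_profile * 1e6
        Ue[-1, 1:-1, 1:-1] = Ue[-2, 1:-1, 1:-1]
        self._interp = RegularGridInterpolator(
            (self._x, self._y, self._z), Ue, bounds_error=False, fill_value=None
        )
        self._gamma_interp = None
        if shear is not None:
            G = np.zeros((nx + 2, ny + 2, nz + 2))
            G[1:-1, 1:-1, 1:-1] = shear.gamma
            # walls keep the adjacent-cell shear (clamped)
            G[0] = G[1]
            G[-1] = G[-2]
            G[:, 0] = G[:, 1]
            G[:, -1] = G[:, -2]
            G[:, :, 0] = G[:, :, 1]
            G[:, :, -1] = G[:, :, -2]
            self._gamma_interp = RegularGridInterpolator(
                (self._x, self._y, self._z), G, bounds_error=False, fill_value=None
            )
        self.x_inlet_um = 0.0

    @property
    def bounds_um(self):
        ext = self.field.extent_um
        return np.zeros(3), np.array(ext)

    def velocity_um_s(self, points_um) -> np.ndarray:
        return self._interp(np.atleast_2d(np.asarray(points_um, dtype=float)))

    def gamma_s(self, points_um) -> np.ndarray:
        if self._gamma_interp is None:
            raise InvalidParameterError("no shear field attached to tracer field")
        return self._gamma_interp(np.atleast_2d(np.asarray(points_um, dtype=float)))

    def in_solid(self, points_um) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        hx, hy, hz = self.field.spacing_um
        nx, ny, nz = self.field.shape
        i = np.clip((p[:, 0] // hx).astype(int), 0, nx - 1)
        j = np.clip((p[:, 1] // hy).astype(int), 0, ny - 1)
        k = np.clip((p[:, 2] // hz).astype(int), 0, nz - 1)
        return self.field.solid[i, j, k]
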