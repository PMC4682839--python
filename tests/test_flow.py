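"""Channel bookkeeping, analytic duct solution and the steady flow solver."""

import math

import numpy as np
import pytest

from thrombotrace.flow import (
    ChannelGeometry,
    FlowField,
    analytic_duct_velocity,
    analytic_duct_wall_shear,
    aspect_ratio,
    compute_shear_field,
    floor_wall_shear,
    hydraulic_diameter,
    nominal_wall_shear,
    reynolds,
    shear_from_gradients,
    solve_steady_flow,
)
from thrombotrace.types import InvalidParameterError


class TestChannelGeometry:
    def test_nominal_wall_shear_linearity(self, capillary):
        base = nominal_wall_shear(capillary)
        doubled = nominal_wall_shear(
            ChannelGeometry(flow_ml_min=2 * capillary.flow_ml_min)
        )
        assert doubled == pytest.approx(2 * base)
        zero = ChannelGeometry(flow_ml_min=0.0)
        assert nominal_wall_shear(zero) == 0.0

    def test_square_duct_hydraulic_diameter(self):
        g = ChannelGeometry(width_mm=0.5, height_mm=0.5)
        assert hydraulic_diameter(g) == pytest.approx(0.5)

    def test_reynolds_requires_density(self, capillary):
        with pytest.raises(InvalidParameterError, match="density"):
            reynolds(capillary)
        assert reynolds(capillary, 1000.0) == pytest.approx(7.79, abs=0.05)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidParameterError):
            ChannelGeometry(width_mm=-1.0)
        with pytest.raises(InvalidParameterError):
            ChannelGeometry(width_mm=0.1, height_mm=0.2)


class TestAnalyticDuct:
    def test_walls_are_zero(self, capillary):
        for y, z in [(0.0, 100.0), (2000.0, 100.0), (1000.0, 0.0), (1000.0, 200.0)]:
            assert analytic_duct_velocity(capillary, y, z) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_quadrature_recovers_flow_rate(self, capillary):
        y = np.linspace(0, 2000, 401)
        z = np.linspace(0, 200, 201)
        Y, Z = np.meshgrid(y, z, indexing="ij")
        u = analytic_duct_velocity(capillary, Y, Z)
        Q = np.trapezoid(np.trapezoid(u, z * 1e-6, axis=1), y * 1e-6)
        assert Q == pytest.approx(capillary.flow_mm3_s * 1e-9, rel=1e-3)

    def test_parallel_plate_limit(self):
        """w ≫ h: centreline velocity tends to (3/2)·Q/(wh)."""
        g = ChannelGeometry(width_mm=200.0, height_mm=0.2, flow_ml_min=1.44)
        u_c = analytic_duct_velocity(g, 100_000.0, 100.0)
        u_plate = 1.5 * g.flow_mm3_s * 1e-9 / (g.width_mm * g.height_mm * 1e-6)
        assert float(u_c) == pytest.approx(u_plate, rel=0.005)

    def test_point_outside_rejected(self, capillary):
        with pytest.raises(InvalidParameterError):
            analytic_duct_velocity(capillary, -5.0, 50.0)

    def test_wall_shear_consistent_with_profile(self, capillary):
        """Termwise-differentiated wall shear matches a finite difference."""
        y = 1000.0
        eps = 0.05
        fd = float(analytic_duct_velocity(capillary, y, eps)) / (eps * 1e-6)
        assert float(analytic_duct_wall_shear(capillary, y)) == pytest.approx(
            fd, rel=1e-3
        )


class TestSolver:
    def test_centerline_velocity(self, capillary, empty_channel_field):
        uc = empty_channel_field.center_velocity()
        u_num = uc[4, :, :, 0].max()
        u_ana = float(analytic_duct_velocity(capillary, 1000.0, 100.0))
        assert u_num == pytest.approx(u_ana, rel=0.03)

    def test_wall_shear_mid_width(self, capillary, empty_channel_field):
        ws = floor_wall_shear(empty_channel_field)
        _, yc, _ = empty_channel_field.cell_centers_um()
        j = len(yc) // 2
        ana = float(analytic_duct_wall_shear(capillary, yc[j]))
        assert ws[4, j] == pytest.approx(ana, rel=0.05)

    def test_divergence_free(self, empty_channel_field):
        div = np.abs(empty_channel_field.divergence()).max()
        u_scale = np.abs(empty_channel_field.u).max()
        dx = empty_channel_field.spacing_um[0] * 1e-6
        assert div <= 1e-8 * u_scale / dx

    def test_mass_conservation(self, capillary, empty_channel_field):
        Q = capillary.flow_mm3_s * 1e-9
        for i in range(0, 9, 2):
            assert empty_channel_field.flux_m3_s(i) == pytest.approx(
                Q, rel=0.005
            )

    def test_mid_width_symmetry(self, empty_channel_field):
        u = empty_channel_field.u
        assert np.abs(u - u[:, ::-1, :]).max() <= 1e-7 * np.abs(u).max()

    def test_grid_convergence(self, capillary):
        """Centreline error vs analytic decreases monotonically."""
        u_ana = float(analytic_duct_velocity(capillary, 1000.0, 100.0))
        errs = []
        for shape in [(8, 32, 8), (8, 48, 16), (8, 64, 32)]:
            f = solve_steady_flow(
                capillary, shape=shape, domain_length_um=400.0, tol=1e-8
            )
            errs.append(abs(f.center_velocity()[4, :, :, 0].max() / u_ana - 1))
        assert errs[0] > errs[1] > errs[2]


class TestShearField:
    def _field_from_center_velocity(self, U, spacing_um):
        nx, ny, nz = U.shape[:3]
        # synthesize staggered arrays consistent with the cell-centred U
        f = FlowField(
            geom=ChannelGeometry(),
            shape=(nx, ny, nz),
            spacing_um=spacing_um,
            u=np.zeros((nx + 1, ny, nz)),
            v=np.zeros((nx, ny + 1, nz)),
            w=np.zeros((nx, ny, nz + 1)),
            p=np.zeros((nx, ny, nz)),
            solid=np.zeros((nx, ny, nz), dtype=bool),
            inlet_profile=None,
        )
        return f, U

    def test_simple_shear_recovers_rate(self):
        """U = (γ̇·z, 0, 0) → γ_local = γ̇ with the ½(∇U+∇Uᵀ) convention."""
        gdot = 123.0
        z = (np.arange(8) + 0.5) * 1e-6
        grad = np.zeros((4, 4, 8, 3, 3))
        grad[..., 0, 2] = gdot
        gamma, D = shear_from_gradients(grad)
        assert np.allclose(gamma, gdot)
        assert np.allclose(D[..., 0, 2], gdot / 2)

    def test_rigid_rotation_zero(self):
        omega = 50.0
        grad = np.zeros((4, 4, 4, 3, 3))
        grad[..., 0, 1] = -omega
        grad[..., 1, 0] = omega
        gamma, _ = shear_from_gradients(grad)
        assert np.allclose(gamma, 0.0)

    def test_empty_channel_floor_shear(self, capillary, empty_channel_field):
        """γ_local near the floor approaches the analytic wall shear."""
        sf = compute_shear_field(empty_channel_field)
        _, yc, zc = empty_channel_field.cell_centers_um()
        j = len(yc) // 2
        # analytic shear at the first cell-centre height
        eps = 0.5
        z0 = zc[0]
        ana = (
            float(analytic_duct_velocity(capillary, yc[j], z0 + eps))
            - float(analytic_duct_velocity(capillary, yc[j], z0 - eps))
        ) / (2 * eps * 1e-6)
        assert sf.gamma[4, j, 0] == pytest.approx(ana, rel=0.05)

    def test_gamma_nonnegative(self, empty_channel_field):
        sf = compute_shear_field(empty_channel_field)
        assert np.all(sf.gamma >= 0)


class TestObstacle:
    def test_crown_shear_exceeds_nominal_wall_value(self, obstacle_case):
        """A 30 μm thrombus in the 200 μm channel elevates γ above γ_w."""
        field = obstacle_case["field"]
        shear = obstacle_case["shear"]
        gw = nominal_wall_shear(obstacle_case["geom"])
        assert gw == pytest.approx(1800.0, rel=1e-6)
        crown = []
        nx, ny, nz = field.shape
        for i in range(nx):
            for j in range(ny):
                ks = np.nonzero(field.solid[i, j, :])[0]
                if len(ks) and ks.max() + 1 < nz:
                    crown.append(shear.gamma[i, j, ks.max() + 1])
        assert len(crown) > 0
        assert max(crown) > gw

    def test_solution_symmetric_about_mid_width(self, obstacle_case):
        u = obstacle_case["field"].u
        assert np.abs(u - u[:, ::-1, :]).max() <= 1e-6 * np.abs(u).max()

    def test_obstacle_flux_conserved(self, obstacle_case):
        field = obstacle_case["field"]
        geom = obstacle_case["geom"]
        Q = geom.flow_mm3_s * 1e-9
        for i in (2, 24, 46):
            assert field.flux_m3_s(i) == pytest.approx(Q, rel=0.005)

    def test_obstacle_outside_domain_rejected(self, obstacle_case, capillary):
        surf = obstacle_case["surface"].copy()
        surf.mesh.apply_translation([5000.0, 0.0, 0.0])
        with pytest.raises(InvalidParameterError, match="fit"):
            solve_steady_flow(
                obstacle_case["geom"], obstacle=surf, shape=(8, 8, 8),
                domain_length_um=400.0,
            )
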