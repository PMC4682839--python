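"""Pathline integration and shear-history summaries."""

import numpy as np
import pytest
import trimesh
from scipy.integrate import solve_ivp

from thrombotrace.flow import AnalyticDuctField, ChannelGeometry, analytic_duct_wall_shear
from thrombotrace.lagrangian import (
    Pathline,
    map_summaries,
    retrace_closure_um,
    seed_surface,
    summarize_pathline,
    thrombus_interaction_region,
    trace_backward,
    trace_forward_for,
)
from thrombotrace.types import InvalidParameterError, TriSurface


class UniformField:
    """Constant velocity c (μm/s): closed-form straight-line pathlines."""

    def __init__(self, c=(1000.0, 0.0, 0.0)):
        self.c = np.asarray(c, dtype=float)
        self.x_inlet_um = 0.0

    @property
    def bounds_um(self):
        return np.array([0.0, -1e9, -1e9]), np.array([1e6, 1e9, 1e9])

    def velocity_um_s(self, p):
        return np.tile(self.c, (len(np.atleast_2d(p)), 1))

    def gamma_s(self, p):
        return np.zeros(len(np.atleast_2d(p)))


class SwirlField:
    """Smooth 3D recirculating field for cross-checking the integrator."""

    x_inlet_um = -1e9

    @property
    def bounds_um(self):
        return np.array([-1e9] * 3), np.array([1e9] * 3)

    def velocity_um_s(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        return np.column_stack(
            [-y + 0.1 * z, x + 0.05 * np.sin(z), 0.2 * np.cos(x / 10.0)]
        ) * 100.0

    def gamma_s(self, p):
        return np.zeros(len(np.atleast_2d(p)))


class TestSeeding:
    def test_sphere_seeds_at_offset_radius(self):
        surf = TriSurface(mesh=trimesh.creation.icosphere(subdivisions=3, radius=10))
        seeds, valid = seed_surface(surf, offset_um=1.0)
        assert valid.all()
        r = np.linalg.norm([s.position_um for s in seeds], axis=1)
        assert r == pytest.approx(11.0, abs=0.05)

    def test_zero_offset_rejected(self):
        surf = TriSurface(mesh=trimesh.creation.icosphere(subdivisions=2, radius=5))
        with pytest.raises(InvalidParameterError, match="offset"):
            seed_surface(surf, offset_um=0.0)

    def test_seed_count_tracks_vertex_count(self, obstacle_case):
        surf = obstacle_case["surface"]
        seeds, valid = seed_surface(
            surf, 1.0, tracer_field=obstacle_case["tracer"]
        )
        assert len(seeds) == int(valid.sum())
        assert len(valid) == len(surf.vertices)
        assert len(seeds) > 0.5 * len(valid)


class TestTIR:
    @pytest.mark.parametrize("length,expected", [(75.0, 7.5), (100.0, 10.0)])
    def test_ten_percent_of_length(self, length, expected):
        m = trimesh.creation.box(extents=(length, 10.0, 10.0))
        m.apply_translation([length / 2, 0, 5.0])
        assert thrombus_interaction_region(TriSurface(mesh=m)) == pytest.approx(
            expected
        )

    def test_degenerate_length_rejected(self):
        # a flat patch in the y-z plane has zero extent along the flow axis
        flat = TriSurface.from_arrays(
            vertices=np.array([[0, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float),
            faces=np.array([[0, 1, 2]]),
        )
        with pytest.raises(InvalidParameterError, match="zero-length"):
            thrombus_interaction_region(flat)


class TestIntegrator:
    def test_uniform_field_straight_line(self):
        fld = UniformField((1000.0, 0.0, 0.0))
        seed = np.array([500.0, 3.0, 7.0])
        p = trace_backward(fld, seed, upstream_plane_um=100.0)
        assert p.termination == "upstream_plane"
        # x(t) = x0 − c·τ exactly; y, z constant
        assert np.allclose(p.positions_um[:, 1], 3.0)
        assert np.allclose(p.positions_um[:, 2], 7.0)
        tau = -p.t_s
        assert np.allclose(p.positions_um[:, 0], 500.0 - 1000.0 * tau, atol=1e-9)
        assert p.positions_um[-1, 0] == pytest.approx(100.0, abs=1e-6)

    def test_duct_pathlines_stay_transversally_fixed(self, capillary):
        fld = AnalyticDuctField(capillary, length_um=3000.0)
        for seed in ([2500.0, 400.0, 30.0], [2500.0, 1000.0, 150.0]):
            p = trace_backward(fld, np.array(seed))
            drift = max(
                np.abs(p.positions_um[:, 1] - seed[1]).max(),
                np.abs(p.positions_um[:, 2] - seed[2]).max(),
            )
            assert drift <= 1e-3
            assert p.termination == "inlet"

    def test_stagnation_detected_near_wall(self, capillary):
        fld = AnalyticDuctField(capillary, length_um=500.0)
        p = trace_backward(
            fld, np.array([400.0, 1000.0, 1e-7]), time_cap_s=0.5
        )
        assert p.termination in ("stagnation", "time_cap")

    def test_matches_scipy_on_smooth_field(self):
        """Endpoint agrees with scipy's RK45 at tight tolerance."""
        fld = SwirlField()
        seed = np.array([5.0, -3.0, 2.0])
        T = 0.05
        mine = trace_forward_for(fld, seed, T, rtol=1e-11, atol_um=1e-9)

        def f(t, x):
            return fld.velocity_um_s(x[None, :])[0]

        ref = solve_ivp(f, [0, T], seed, method="RK45", rtol=1e-12, atol=1e-12)
        assert np.linalg.norm(mine.positions_um[-1] - ref.y[:, -1]) <= 1e-5

    def test_retrace_closure_small_on_obstacle_flow(self, obstacle_case):
        tracer = obstacle_case["tracer"]
        seeds, _ = seed_surface(
            obstacle_case["surface"], 1.0, tracer_field=tracer
        )
        rng = np.random.default_rng(3)
        count = 0
        for i in rng.permutation(len(seeds)):
            p = trace_backward(tracer, seeds[i], upstream_plane_um=20.0)
            if p.termination != "upstream_plane":
                continue
            c = retrace_closure_um(tracer, seeds[i], upstream_plane_um=20.0)
            assert c <= 1e-3
            count += 1
            if count == 5:
                break
        assert count == 5

    def test_step_halving_invariance(self, obstacle_case):
        """With tolerance fixed, halving the max step moves endpoints <1 nm."""
        tracer = obstacle_case["tracer"]
        seeds, _ = seed_surface(
            obstacle_case["surface"], 1.0, tracer_field=tracer
        )
        seed = seeds[len(seeds) // 2]
        a = trace_backward(tracer, seed, upstream_plane_um=20.0)
        b = trace_backward(
            tracer, seed, upstream_plane_um=20.0, max_step_s=5e-4
        )
        if a.termination == b.termination == "upstream_plane":
            assert np.linalg.norm(
                a.positions_um[-1] - b.positions_um[-1]
            ) <= 1e-3

    def test_seed_inside_obstacle_rejected(self, obstacle_case):
        tracer = obstacle_case["tracer"]
        field = obstacle_case["field"]
        idx = np.argwhere(field.solid)[0]
        hx, hy, hz = field.spacing_um
        inside = (idx + 0.5) * np.array([hx, hy, hz])
        with pytest.raises(InvalidParameterError, match="obstacle"):
            trace_backward(tracer, inside)


class TestSummaries:
    def _path(self, t, gamma):
        t = np.asarray(t, dtype=float)
        pos = np.column_stack([np.linspace(0, 1, len(t))] * 3)
        return Pathline(t_s=t, positions_um=pos, gamma_s=np.asarray(gamma, float),
                        termination="inlet")

    def test_constant_samples(self):
        s = summarize_pathline(self._path([0, -1, -2], [5, 5, 5]))
        assert s.gamma_adhesion_s == s.gamma_peak_s == s.gamma_mean_s == 5.0

    def test_monotone_rise_to_seed(self):
        s = summarize_pathline(self._path([0, -1, -2], [9, 7, 4]))
        assert s.gamma_peak_s == s.gamma_adhesion_s == 9.0

    def test_linear_ramp_time_weighted_mean(self):
        """γ(τ) = τ on the 3 s window → trapezoidal mean 1.5."""
        t = -np.linspace(3.0, 0.0, 31)[::-1]  # 0 … −3
        g = -t
        s = summarize_pathline(self._path(t, g), window_s=3.0)
        assert s.gamma_mean_s == pytest.approx(1.5, abs=1e-6)
        assert s.gamma_peak_s == pytest.approx(3.0)

    def test_window_truncated_for_short_paths(self):
        s = summarize_pathline(self._path([0, -0.5, -1.0], [2, 4, 6]),
                               window_s=3.0)
        assert s.window_s == pytest.approx(1.0)

    def test_too_short_path_rejected(self):
        with pytest.raises(InvalidParameterError):
            summarize_pathline(self._path([0.0], [1.0]))

    def test_adhesion_shear_near_floor_matches_analytic(self, capillary):
        """γ sampled 1 μm above the floor ≈ the analytic wall shear."""
        fld = AnalyticDuctField(capillary, length_um=500.0)
        g = fld.gamma_s(np.array([[250.0, 1000.0, 1.0]])).item()
        ana = analytic_duct_wall_shear(capillary, np.array([1000.0])).item()
        assert g == pytest.approx(ana, rel=0.05)


class TestMapSummaries:
    def test_channels_and_missing_flags(self):
        surf = TriSurface(mesh=trimesh.creation.icosphere(subdivisions=1, radius=5))
        from thrombotrace.lagrangian import PathlineSummary

        summaries = {
            0: PathlineSummary(10.0, 20.0, 15.0, 3.0),
            2: PathlineSummary(1.0, 2.0, 1.5, 3.0),
        }
        m = map_summaries(surf, summaries)
        assert set(m.surface.scalars) >= {
            "gamma_adhesion", "gamma_peak", "gamma_mean"
        }
        assert m.surface.scalars["gamma_peak"][0] == 20.0
        assert np.isnan(m.surface.scalars["gamma_peak"][1])
        assert m.missing[1] and not m.missing[0]

    def test_index_out_of_range_rejected(self):
        surf = TriSurface(mesh=trimesh.creation.icosphere(subdivisions=1, radius=5))
        from thrombotrace.lagrangian import PathlineSummary

        with pytest.raises(InvalidParameterError):
            map_summaries(surf, {10_000: PathlineSummary(1, 1, 1, 3.0)})

    def test_growth_join(self, obstacle_case):
        """Joined table carries (γ_adhesion, γ_peak, γ_mean, growth)."""
        surf = obstacle_case["surface"]
        from thrombotrace.lagrangian import PathlineSummary

        growth = np.linspace(-1, 1, len(surf.vertices))
        m = map_summaries(surf, {0: PathlineSummary(1, 2, 1.5, 3.0)},
                          growth_um=growth)
        assert "growth_um" in m.surface.scalars
        assert len(m.surface.scalars["growth_um"]) == len(surf.vertices)


class TestGlobalInvariants:
    def test_peak_bounds_on_traced_paths(self, obstacle_case):
        tracer = obstacle_case["tracer"]
        seeds, _ = seed_surface(
            obstacle_case["surface"], 1.0, tracer_field=tracer
        )
        rng = np.random.default_rng(11)
        for i in rng.choice(len(seeds), size=8, replace=False):
            p = trace_backward(tracer, seeds[i])
            if len(p.t_s) < 2:
                continue
            s = summarize_pathline(p)
            assert s.gamma_peak_s >= s.gamma_adhesion_s - 1e-9
            assert s.gamma_peak_s >= s.gamma_mean_s - 1e-9
            assert s.gamma_adhesion_s >= 0
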