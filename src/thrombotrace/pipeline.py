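"""End-to-end pipeline: phantom → reconstruct → timecorrect → growth → flow → trace.

Mirrors the combined ex vivo / in silico workflow: synthetic acquisition of
a growing thrombus, time-corrected surface reconstruction at two
timepoints, growth mapping between them, a steady flow solve around the
earlier surface, and backward pathline tracing to put per-vertex shear
histories next to per-vertex growth.  Every stage writes its artifacts and
a manifest records inputs, outputs, parameters and checksums so a run is
reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth as growth_mod
from . import io as tio
from .flow import (
    ChannelGeometry,
    compute_shear_field,
    nominal_wall_shear,
    solve_steady_flow,
)
from .lagrangian import (
    map_summaries,
    seed_surface,
    summarize_pathline,
    thrombus_interaction_region,
    trace_backward,
)
from .phantom import (
    AcquisitionSchedule,
    acquire_zstacks,
    make_lobed_phantom,
)
from .reconstruct import surface_metrics
from .timecorrect import time_corrected_surface
from .types import ThrombotraceError

STAGES = ("phantom", "reconstruct", "timecorrect", "growth", "flow", "trace")


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    # phantom: a lobed thrombus-like geometry growing ~1 % volume per second
    phantom_a0_um: float = 20.0
    phantom_b0_um: float = 8.0
    phantom_c0_um: float = 14.0
    phantom_lobe_amplitude_um: float = 1.0
    phantom_n_lobes: int = 3
    growth_rate_per_s: float = 0.0033
    growth_kind: str = "exponential"
    seed: int = 0

    # acquisition
    width_px: int = 176
    height_px: int = 64
    n_slices: int = 36
    n_stacks: int = 4
    slice_thickness_um: float = 0.5
    pixel_size_um: float = 0.31
    scan_s: float = 1.2
    transfer_s: float = 2.3

    # segmentation / morphing
    threshold: str | float = "auto"
    increment_s: float = 0.06

    # timepoints for the growth pair (mid-scan of these stacks)
    stack_t1: int = 1
    stack_t2: int = 2

    # channel / solver (a desk-scale subsection of the microcapillary)
    channel_width_mm: float = 0.24
    channel_height_mm: float = 0.2
    channel_flow_ml_min: float = 0.1728  # nominal wall shear 1800 1/s
    viscosity_cP: float = 2.8
    domain_length_um: float = 300.0
    grid: tuple[int, int, int] = (30, 24, 16)
    solver_tol: float = 1e-7

    # tracing
    seed_offset_um: float = 1.0
    window_s: float = 3.0
    max_seeds: int = 120

    out_dir: str = "pipeline_out"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": [],
    }
    state: dict = {}
    for stage in STAGES:
        t0 = time.time()
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            outputs = _STAGE_FN[stage](config, state, stage_dir, resume)
        except ThrombotraceError as e:
            raise ThrombotraceError(
                f"pipeline stage '{stage}' failed: {e}; artifacts in {stage_dir}"
            ) from e
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {
                    str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)
                },
                "wall_s": round(time.time() - t0, 3),
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _stage_phantom(cfg: PipelineConfig, state, stage_dir: Path, resume):
    phantom = make_lobed_phantom(
        a0=cfg.phantom_a0_um,
        b0=cfg.phantom_b0_um,
        c0=cfg.phantom_c0_um,
        n_lobes=cfg.phantom_n_lobes,
        lobe_amplitude=cfg.phantom_lobe_amplitude_um,
        growth_rates=cfg.growth_rate_per_s,
        kind=cfg.growth_kind,
        seed=cfg.seed,
    )
    sched = AcquisitionSchedule(
        slice_thickness_um=cfg.slice_thickness_um,
        pixel_size_um=cfg.pixel_size_um,
        width_px=cfg.width_px,
        height_px=cfg.height_px,
        scan_s=cfg.scan_s,
        transfer_s=cfg.transfer_s,
        n_slices=cfg.n_slices,
        n_stacks=cfg.n_stacks,
    )
    state["phantom"] = phantom
    state["schedule"] = sched
    existing = sorted(stage_dir.glob("stack_*.tif"))
    if resume and len(existing) == cfg.n_stacks:
        state["stacks"] = tio.read_stacks(stage_dir)
        return list(stage_dir.iterdir())
    stacks = acquire_zstacks(phantom, sched)
    state["stacks"] = stacks
    tio.write_stacks(stacks, stage_dir)
    return list(stage_dir.iterdir())


def _stage_reconstruct(cfg, state, stage_dir: Path, resume):
    from .reconstruct import build_surface_from_stack

    stacks = state["stacks"]
    rows = []
    for st in stacks:
        surf = build_surface_from_stack(st, threshold=cfg.threshold)
        m = surface_metrics(surf)
        m["stack"] = st.index
        m["t_mid_s"] = 0.5 * (st.t_start + st.t_end)
        rows.append(m)
        tio.write_surface(surf, stage_dir / f"direct_{st.index:04d}.ply")
    pd.DataFrame(rows).to_csv(stage_dir / "metrics.csv", index=False)
    return list(stage_dir.iterdir())


def _stage_timecorrect(cfg, state, stage_dir: Path, resume):
    stacks = state["stacks"]
    sched = state["schedule"]
    rows = []
    for tag, m in (("t1", cfg.stack_t1), ("t2", cfg.stack_t2)):
        t_star = sched.slice_time_s(m, 0) + sched.scan_s / 2.0
        surf, inst = time_corrected_surface(
            stacks, t_star, threshold=cfg.threshold, increment_s=cfg.increment_s
        )
        state[f"surface_{tag}"] = surf
        met = surface_metrics(surf)
        rows.append(
            {
                "t_star_s": t_star,
                "dt_sample_span_s": inst.dt_sample_span_s,
                **met,
            }
        )
        tio.write_surface(surf, stage_dir / f"corrected_{tag}.ply")
    pd.DataFrame(rows).to_csv(stage_dir / "corrected_log.csv", index=False)
    return list(stage_dir.iterdir())


def _stage_growth(cfg, state, stage_dir: Path, resume):
    g = growth_mod.growth_map(state["surface_t1"], state["surface_t2"])
    state["growth_map"] = g
    stats = growth_mod.growth_stats(g)
    surf = growth_mod.growth_surface(g)
    tio.write_surface(surf, stage_dir / "growth.ply")
    verts = surf.vertices
    pd.DataFrame(
        {
            "x_um": verts[:, 0],
            "y_um": verts[:, 1],
            "z_um": verts[:, 2],
            "growth_um": surf.scalars["growth_um"],
            "label": surf.scalars["growth_label"].astype(int),
        }
    ).to_csv(stage_dir / "growth_vertices.csv", index=False)
    (stage_dir / "growth_stats.json").write_text(json.dumps(stats, indent=1))
    return list(stage_dir.iterdir())


def _stage_flow(cfg, state, stage_dir: Path, resume):
    geom = ChannelGeometry(
        width_mm=cfg.channel_width_mm,
        height_mm=cfg.channel_height_mm,
        length_mm=cfg.domain_length_um * 1e-3,
        flow_ml_min=cfg.channel_flow_ml_min,
        viscosity_cP=cfg.viscosity_cP,
    )
    surf = state["surface_t1"].copy()
    # centre the thrombus in the desk-scale channel subsection
    lo, hi = surf.mesh.bounds
    shift = np.array(
        [
            0.45 * cfg.domain_length_um - 0.5 * (lo[0] + hi[0]),
            0.5 * geom.width_mm * 1e3 - 0.5 * (lo[1] + hi[1]),
            0.0,
        ]
    )
    surf.mesh.apply_translation(shift)
    state["obstacle"] = surf
    state["geom"] = geom
    fieldobj = solve_steady_flow(
        geom,
        obstacle=surf,
        shape=tuple(cfg.grid),
        domain_length_um=cfg.domain_length_um,
        tol=cfg.solver_tol,
    )
    shear = compute_shear_field(fieldobj)
    state["flow"] = fieldobj
    state["shear"] = shear
    tio.write_field(fieldobj, stage_dir / "field.vtk", shear)
    report = {
        "converged": fieldobj.converged,
        "steps": len(fieldobj.residuals),
        "final_residual": fieldobj.residuals[-1],
        "nominal_wall_shear_s": nominal_wall_shear(geom),
        "max_gamma_s": float(shear.gamma.max()),
    }
    (stage_dir / "convergence.json").write_text(json.dumps(report, indent=1))
    return list(stage_dir.iterdir())


def _stage_trace(cfg, state, stage_dir: Path, resume):
    surf = state["obstacle"]
    tracer = state["flow"].tracer_field(state["shear"])
    seeds, valid = seed_surface(
        surf, cfg.seed_offset_um, tracer_field=tracer
    )
    rng = np.random.default_rng(cfg.seed)
    if len(seeds) > cfg.max_seeds:
        keep = rng.choice(len(seeds), size=cfg.max_seeds, replace=False)
        seeds = [seeds[i] for i in sorted(keep)]
    tir = thrombus_interaction_region(surf)
    summaries = {}
    path_rows = []
    for sd in seeds:
        path = trace_backward(tracer, sd)
        if len(path.t_s) < 2:
            continue
        summaries[sd.vertex_index] = summarize_pathline(
            path, window_s=cfg.window_s, tir_um=tir
        )
        for t, pos, g in zip(path.t_s, path.positions_um, path.gamma_s):
            path_rows.append(
                {
                    "vertex": sd.vertex_index,
                    "t_s": t,
                    "x_um": pos[0],
                    "y_um": pos[1],
                    "z_um": pos[2],
                    "gamma_s": g,
                }
            )
    gmap = state.get("growth_map")
    growth_channel = None
    if gmap is not None:
        growth_channel = np.nan_to_num(gmap.distance_um, nan=0.0)
    shear_map = map_summaries(surf, summaries, growth_um=growth_channel)
    tio.write_surface(shear_map.surface, stage_dir / "shear_map.ply")
    verts = shear_map.surface.vertices
    df = pd.DataFrame(
        {
            "vertex": np.arange(len(verts)),
            "x_um": verts[:, 0],
            "y_um": verts[:, 1],
            "z_um": verts[:, 2],
            "gamma_adhesion_s": shear_map.surface.scalars["gamma_adhesion"],
            "gamma_peak_s": shear_map.surface.scalars["gamma_peak"],
            "gamma_mean_s": shear_map.surface.scalars["gamma_mean"],
            "missing": shear_map.missing.astype(int),
        }
    )
    if growth_channel is not None:
        df["growth_um"] = growth_channel
    df.to_csv(stage_dir / "vertex_summaries.csv", index=False)
    pd.DataFrame(path_rows).to_csv(stage_dir / "pathlines.csv", index=False)
    return list(stage_dir.iterdir())


_STAGE_FN = {
    "phantom": _stage_phantom,
    "reconstruct": _stage_reconstruct,
    "timecorrect": _stage_timecorrect,
    "growth": _stage_growth,
    "flow": _stage_flow,
    "trace": _stage_trace,
}
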