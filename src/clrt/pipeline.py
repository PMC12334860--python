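"""End-to-end planning pipeline.

Executes the full workflow on a density grid and structure set:

1. sample focal target points in the PTV,
2. compute each point's feasible angular approach region,
3. assign diversified beam directions per point,
4. assemble the dose-influence matrix and optimize beam weights,
5. accumulate the final dose and evaluate DVHs and plan indices.

Stage timings and beam counts are logged to stderr; the run is fully
deterministic for a fixed config (including its seed).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from .config import PlanningConfig
from .evaluate import DVHCurve, PlanIndices, compute_dvh, plan_indices
from .grid import StructureSet, VoxelGrid
from .lens import Beam
from .optimize import Plan, assemble_dij, optimize_weights
from .planning import (
    UnreachableTargetError,
    assign_directions,
    compute_approach_region,
    sample_target_points,
)

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("clrt")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is attached to the message."""


def _referenced_labels(config: PlanningConfig) -> set[str]:
    labels = {o.structure for o in config.objectives}
    labels |= {c.structure for c in config.constraints}
    return labels


def _resolve_structures(config: PlanningConfig, structures: StructureSet) -> dict:
    """Validate referenced labels; derive NORMAL = BODY minus PTV on demand."""
    masks = dict(structures.masks)
    if "NORMAL" in _referenced_labels(config) and "NORMAL" not in masks:
        masks["NORMAL"] = masks["BODY"] & ~masks["PTV"]
    missing = _referenced_labels(config) - set(masks)
    if missing:
        raise PipelineError(f"[config] objectives/constraints reference missing structures {sorted(missing)}")
    return masks


def run_pipeline(
    config: PlanningConfig,
    density: VoxelGrid,
    structures: StructureSet,
    out_dir: str | Path | None = None,
    verbose: bool = False,
) -> tuple[Plan, PlanIndices, dict[str, DVHCurve]]:
    """Run the full planning workflow; optionally write all artifacts.

    Returns the optimized plan, the plan-quality indices, and one DVH curve
    per structure.  Any stage failure raises :class:`PipelineError` with the
    stage name attached.
    """
    masks = _resolve_structures(config, structures)
    lens = config.lens_spec()
    samp = config.sampling
    body = structures["BODY"]
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"[{name}] {exc}") from exc
                log.info("stage %-12s %.2f s", name, timings[name])
                return False

        return _Stage()

    with stage("sample"):
        points = sample_target_points(
            structures["PTV"], density, lens.fwhm_lateral, samp.spacing_factor
        )
        log.info("sampled %d target points", len(points))

    beams: list[Beam] = []
    depths: list[float] = []
    with stage("directions"):
        for pt in points:
            region = compute_approach_region(pt, density, body, lens, samp.n_candidates)
            if region.n_feasible == 0:
                raise UnreachableTargetError(
                    f"target point {pt.id} at {pt.position} unreachable within "
                    f"{lens.max_depth} mm water-equivalent depth"
                )
            for u in assign_directions(region, samp.n_segments, samp.seed + pt.id):
                beams.append(Beam.aimed(pt.position, u))
            if verbose:
                d = region.depth[region.feasible]
                depths.extend(d.tolist())
                log.info(
                    "point %3d: %3d/%3d feasible, depth %.1f-%.1f mm",
                    pt.id, region.n_feasible, samp.n_candidates, d.min(), d.max(),
                )
        log.info("assigned %d beams over %d target points", len(beams), len(points))

    with stage("dij"):
        dij = assemble_dij(beams, lens, density, body)

    with stage("optimize"):
        plan = optimize_weights(
            dij,
            config.objective_specs(),
            masks,
            constraints=config.constraint_specs(),
            max_iter=config.optimizer.max_iter,
            tol=config.optimizer.tol,
            seed=samp.seed,
            prescription_gy=config.prescription_gy,
            fractions=config.fractions,
        )
        log.info(
            "objective %.4g -> %.4g in %d iterations",
            plan.trace[0], plan.trace[-1], len(plan.trace) - 1,
        )

    with stage("evaluate"):
        indices = plan_indices(plan.dose, structures["PTV"], config.prescription_gy)
        bin_width = 1e-3 * config.prescription_gy
        dvhs = {
            label: compute_dvh(plan.dose, mask, bin_width, structure=label)
            for label, mask in masks.items()
        }

    if out_dir is not None:
        from . import io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_nrrd(plan.dose, out / "dose.nrrd")
        io.save_plan(plan, out / "plan.json")
        io.save_dvhs(dvhs, out / "dvh.csv")
        _write_report(indices, out / "indices.txt")
    return plan, indices, dvhs


def _write_report(indices: PlanIndices, path: Path) -> None:
    lines = [
        f"CI   {indices.CI:.4f}",
        f"TCI  {indices.TCI:.4f}",
        f"CN   {indices.CN:.4f}",
        f"GI   {indices.GI:.1f} %/cm",
        f"V100      {indices.V100:.4f} cc",
        f"V100_PTV  {indices.V100_PTV:.4f} cc",
        f"V_PTV     {indices.V_PTV:.4f} cc",
        f"R100_eff  {indices.R100_eff:.4f} cm",
        f"R50_eff   {indices.R50_eff:.4f} cm",
    ]
    path.write_text("\n".join(lines) + "\n")
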