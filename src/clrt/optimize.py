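"""Inverse optimization of beam weights.

The linear dose model is ``d_i = sum_j D_ij w_j`` with a sparse
dose-influence matrix ``D`` (Gy per unit weight, voxels × beams).  Plan
quality is scored by per-structure one-sided quadratic deviations from a
prescribed dose ``d_hat``::

    f_under = (1/N_S) * sum_{i in S} [d_i < d_hat] (d_i - d_hat)^2
    f_over  = (1/N_S) * sum_{i in S} [d_i > d_hat] (d_i - d_hat)^2

combined into a penalty-weighted sum ``f(w) = sum_n p_n f_n`` and minimized
over ``w >= 0`` with a bound-constrained quasi-Newton method (L-BFGS-B) and
analytic gradients.  Hard max/mean-dose constraints are enforced by quadratic
penalty terms on an escalating fixed multiplier schedule, with remaining
violations logged on the plan.

Voxels at exactly the prescription contribute nothing from either side
(the Heaviside gate is taken as 0 at 0), so the objective is continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt
from scipy import sparse

from .grid import VoxelGrid
from .lens import Beam, LensSpec
from .dose import beam_dose

__all__ = [
    "DoseInfluence",
    "ObjectiveSpec",
    "ConstraintSpec",
    "Plan",
    "assemble_dij",
    "objective_value",
    "objective_gradient",
    "optimize_weights",
    "accumulate_dose",
]

#: entries below this fraction of a column's maximum are dropped to zero
SPARSITY_FLOOR = 1e-6


@dataclass
class DoseInfluence:
    """Sparse dose-influence matrix D (voxels × beams, Gy per unit weight)."""

    matrix: sparse.csc_matrix
    beams: list[Beam]
    grid: VoxelGrid  # geometry reference (values unused)

    @property
    def n_beams(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ObjectiveSpec:
    """One-sided quadratic dose objective on a structure."""

    structure: str
    kind: str  # "squared_underdose" | "squared_overdose"
    dose_gy: float
    penalty: float

    def __post_init__(self) -> None:
        if self.kind not in ("squared_underdose", "squared_overdose"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.dose_gy <= 0:
            raise ValueError("prescribed dose must be positive")
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")


@dataclass(frozen=True)
class ConstraintSpec:
    """Hard max- or mean-dose bound on a structure (enforced by penalty)."""

    structure: str
    kind: str  # "max_dose" | "mean_dose"
    lower_gy: float = -np.inf
    upper_gy: float = np.inf

    def __post_init__(self) -> None:
        if self.kind not in ("max_dose", "mean_dose"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.lower_gy > self.upper_gy:
            raise ValueError("constraint lower bound exceeds upper bound")


@dataclass
class Plan:
    """An optimized plan: weighted beams, final dose, and the objective trace."""

    beams: list[Beam]
    weights: np.ndarray
    dose: VoxelGrid
    trace: list[float]
    prescription_gy: float
    fractions: int = 1
    constraint_violations: dict = field(default_factory=dict)


def assemble_dij(
    beams: list[Beam], lens: LensSpec, density: VoxelGrid, body: np.ndarray
) -> DoseInfluence:
    """Assemble the dose-influence matrix, one beam-dose column per beam.

    Entries below ``SPARSITY_FLOOR`` of each column's maximum are dropped.
    """
    if not beams:
        raise ValueError("need at least one beam")
    cols = []
    for b in beams:
        col = beam_dose(lens, b, density, body).values.ravel()
        floor = SPARSITY_FLOOR * col.max() if col.max() > 0 else 0.0
        col = np.where(col >= floor, col, 0.0)
        cols.append(sparse.csc_matrix(col[:, None]))
    matrix = sparse.hstack(cols, format="csc")
    return DoseInfluence(matrix=matrix, beams=list(beams), grid=density)


def _structure_indices(structures, label: str) -> np.ndarray:
    if hasattr(structures, "masks"):
        masks = structures.masks
    else:
        masks = structures
    if label not in masks:
        raise KeyError(f"unknown structure label {label!r}; have {sorted(masks)}")
    return np.flatnonzero(np.asarray(masks[label]).ravel())


def _one_sided(diff: np.ndarray, kind: str) -> np.ndarray:
    # strict inequality: exactly-at-prescription voxels contribute nothing
    if kind == "squared_underdose":
        return np.where(diff < 0, diff, 0.0)
    return np.where(diff > 0, diff, 0.0)


def objective_value(
    w: np.ndarray, dij: DoseInfluence, objectives: list[ObjectiveSpec], structures
) -> float:
    """Penalty-weighted sum of one-sided quadratic deviations at weights ``w``."""
    w = np.asarray(w, dtype=float)
    d = dij.matrix @ w
    total = 0.0
    for obj in objectives:
        idx = _structure_indices(structures, obj.structure)
        dev = _one_sided(d[idx] - obj.dose_gy, obj.kind)
        total += obj.penalty * float(dev @ dev) / idx.size
    return total


def objective_gradient(
    w: np.ndarray, dij: DoseInfluence, objectives: list[ObjectiveSpec], structures
) -> np.ndarray:
    """Analytic gradient of :func:`objective_value` with respect to ``w``."""
    w = np.asarray(w, dtype=float)
    d = dij.matrix @ w
    g_dose = np.zeros(dij.n_voxels)
    for obj in objectives:
        idx = _structure_indices(structures, obj.structure)
        dev = _one_sided(d[idx] - obj.dose_gy, obj.kind)
        g_dose[idx] += 2.0 * obj.penalty * dev / idx.size
    return dij.matrix.T @ g_dose


def _constraint_penalty_and_grad(w, dij, constraints, structures, multiplier):
    """Quadratic penalty for violated max/mean-dose bounds, plus its gradient."""
    if not constraints:
        return 0.0, np.zeros(dij.n_beams)
    d = dij.matrix @ w
    value = 0.0
    g_dose = np.zeros(dij.n_voxels)
    g_w = np.zeros(dij.n_beams)
    for con in constraints:
        idx = _structure_indices(structures, con.structure)
        if con.kind == "max_dose":
            over = np.maximum(d[idx] - con.upper_gy, 0.0)
            under = np.maximum(con.lower_gy - d[idx], 0.0)
            value += multiplier * float(over @ over + under @ under) / idx.size
            g_dose[idx] += 2.0 * multiplier * (over - under) / idx.size
        else:  # mean_dose
            mean = float(d[idx].mean())
            viol = max(mean - con.upper_gy, 0.0) - max(con.lower_gy - mean, 0.0)
            value += multiplier * viol**2
            if viol != 0.0:
                g_dose[idx] += 2.0 * multiplier * viol / idx.size
    g_w = dij.matrix.T @ g_dose
    return value, g_w


def constraint_violations(
    w: np.ndarray, dij: DoseInfluence, constraints: list[ConstraintSpec], structures
) -> dict:
    """Achieved max/mean dose vs. bounds, keyed by constraint."""
    d = dij.matrix @ np.asarray(w, dtype=float)
    report = {}
    for con in constraints:
        idx = _structure_indices(structures, con.structure)
        achieved = float(d[idx].max()) if con.kind == "max_dose" else float(d[idx].mean())
        viol = max(achieved - con.upper_gy, 0.0) + max(con.lower_gy - achieved, 0.0)
        report[f"{con.kind}:{con.structure}"] = {
            "achieved_gy": achieved,
            "lower_gy": con.lower_gy,
            "upper_gy": con.upper_gy,
            "violation_gy": viol,
        }
    return report


def optimize_weights(
    dij: DoseInfluence,
    objectives: list[ObjectiveSpec],
    structures,
    constraints: list[ConstraintSpec] | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    prescription_gy: float | None = None,
    fractions: int = 1,
) -> Plan:
    """Minimize the weighted objective over non-negative beam weights.

    Starts from uniform weights scaled so the mean dose of the first
    PTV-targeting objective's structure equals its prescription; runs
    L-BFGS-B under ``w >= 0``.  Constraints are folded in as quadratic
    penalties on an escalating multiplier schedule (three stages,
    warm-started); residual violations are reported on the plan.
    The objective trace records ``f`` at the accepted iterates and is
    non-increasing after the first entry (within ``tol``).
    """
    constraints = constraints or []
    active = [o for o in objectives if o.penalty > 0]
    if not active:
        raise ValueError("degenerate problem: all objective penalties are zero")

    ptv_obj = next((o for o in objectives if o.structure == "PTV"), active[0])
    idx = _structure_indices(structures, ptv_obj.structure)
    ones = np.ones(dij.n_beams)
    mean_unit = float((dij.matrix @ ones)[idx].mean())
    scale = ptv_obj.dose_gy / mean_unit if mean_unit > 0 else 1.0
    w0 = scale * ones

    prescription = prescription_gy if prescription_gy is not None else ptv_obj.dose_gy

    multipliers = [10.0, 100.0, 1000.0] if constraints else [0.0]
    trace = [objective_value(w0, dij, active, structures)]
    w = w0
    if max_iter > 0:
        for mult in multipliers:
            def fun(x, _m=mult):
                v = objective_value(x, dij, active, structures)
                cv, _ = _constraint_penalty_and_grad(x, dij, constraints, structures, _m)
                return v + cv

            def jac(x, _m=mult):
                g = objective_gradient(x, dij, active, structures)
                _, cg = _constraint_penalty_and_grad(x, dij, constraints, structures, _m)
                return g + cg

            stage_trace = []
            res = sciopt.minimize(
                fun,
                w,
                jac=jac,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * dij.n_beams,
                callback=lambda x: stage_trace.append(
                    objective_value(x, dij, active, structures)
                ),
                options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
            )
            w = np.maximum(res.x, 0.0)
            trace.extend(stage_trace)

    dose = accumulate_dose(dij, w)
    return Plan(
        beams=[Beam(b.target, b.direction, float(wj)) for b, wj in zip(dij.beams, w)],
        weights=w,
        dose=dose,
        trace=trace,
        prescription_gy=prescription,
        fractions=fractions,
        constraint_violations=constraint_violations(w, dij, constraints, structures),
    )


def accumulate_dose(dij: DoseInfluence, w: np.ndarray) -> VoxelGrid:
    """Final dose ``d = D w`` mapped back onto the grid (exact, linear in w)."""
    w = np.asarray(w, dtype=float)
    if w.shape != (dij.n_beams,):
        raise ValueError(f"weights shape {w.shape} != ({dij.n_beams},)")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    d = dij.matrix @ w
    return dij.grid.like(d.reshape(dij.grid.dims))
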