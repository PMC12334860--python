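import numpy as np
import pytest
from scipy import sparse

import clrt
from clrt.optimize import DoseInfluence


def toy_dij(matrix, dims=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n_vox, n_beams = matrix.shape
    if dims is None:
        dims = (n_vox, 1, 1)
    grid = clrt.VoxelGrid(np.zeros(dims), spacing=(1, 1, 1))
    beams = [clrt.Beam((0, 0, 0), (0, 0, 1.0)) for _ in range(n_beams)]
    return DoseInfluence(matrix=sparse.csc_matrix(matrix), beams=beams, grid=grid)


def masks_for(n_vox, sel=None):
    m = np.zeros((n_vox, 1, 1), bool)
    m[sel if sel is not None else slice(None)] = True
    return {"S": m}


def random_instance(rng, n_vox=100, n_beams=5):
    D = rng.uniform(0, 2, (n_vox, n_beams)) * (rng.uniform(size=(n_vox, n_beams)) < 0.5)
    dij = toy_dij(D)
    half = n_vox // 2
    masks = {"S": np.zeros((n_vox, 1, 1), bool), "T": np.zeros((n_vox, 1, 1), bool)}
    masks["S"][:half] = True
    masks["T"][half:] = True
    objectives = [
        clrt.ObjectiveSpec("S", "squared_underdose", rng.uniform(5, 15), rng.uniform(0.1, 10)),
        clrt.ObjectiveSpec("S", "squared_overdose", rng.uniform(5, 15), rng.uniform(0.1, 10)),
        clrt.ObjectiveSpec("T", "squared_overdose", rng.uniform(1, 5), rng.uniform(0.1, 10)),
    ]
    w = rng.uniform(0, 3, n_beams)
    return dij, masks, objectives, w


# -- objective value ---------------------------------------------------------

def test_objective_zero_at_prescription():
    dij = toy_dij(np.eye(4))
    masks = masks_for(4)
    objs = [clrt.ObjectiveSpec("S", "squared_underdose", 10.0, 1.0),
            clrt.ObjectiveSpec("S", "squared_overdose", 10.0, 1.0)]
    w = np.full(4, 10.0)
    assert clrt.objective_value(w, dij, objs, masks) == 0.0


def test_underdose_hand_value():
    dij = toy_dij([[1.0]])
    masks = masks_for(1)
    objs = [clrt.ObjectiveSpec("S", "squared_underdose", 10.0, 1.0)]
    assert clrt.objective_value(np.array([8.0]), dij, objs, masks) == pytest.approx(4.0)


def test_overdose_inactive_below_prescription():
    dij = toy_dij([[1.0]])
    masks = masks_for(1)
    objs = [clrt.ObjectiveSpec("S", "squared_overdose", 10.0, 1.0)]
    assert clrt.objective_value(np.array([8.0]), dij, objs, masks) == 0.0


def test_boundary_voxel_contributes_nothing_either_side():
    dij = toy_dij([[1.0]])
    masks = masks_for(1)
    for kind in ("squared_underdose", "squared_overdose"):
        objs = [clrt.ObjectiveSpec("S", kind, 10.0, 3.0)]
        assert clrt.objective_value(np.array([10.0]), dij, objs, masks) == 0.0


def test_unknown_structure_label_rejected():
    dij = toy_dij([[1.0]])
    with pytest.raises(KeyError, match="unknown structure"):
        clrt.objective_value(np.array([1.0]), dij,
                             [clrt.ObjectiveSpec("NOPE", "squared_overdose", 1.0, 1.0)],
                             masks_for(1))


# -- gradient ----------------------------------------------------------------

def test_gradient_zero_at_prescription():
    dij = toy_dij(np.eye(3))
    masks = masks_for(3)
    objs = [clrt.ObjectiveSpec("S", "squared_underdose", 5.0, 2.0),
            clrt.ObjectiveSpec("S", "squared_overdose", 5.0, 2.0)]
    g = clrt.objective_gradient(np.full(3, 5.0), dij, objs, masks)
    np.testing.assert_allclose(g, 0.0, atol=1e-15)


def test_gradient_hand_value():
    # single beam, single voxel, D=1, w=8, underdose at 10: df/dw = 2(8-10) = -4
    dij = toy_dij([[1.0]])
    masks = masks_for(1)
    objs = [clrt.ObjectiveSpec("S", "squared_underdose", 10.0, 1.0)]
    g = clrt.objective_gradient(np.array([8.0]), dij, objs, masks)
    assert g[0] == pytest.approx(-4.0)


def test_gradient_matches_finite_differences_on_random_instances():
    """Central finite differences agree with the analytic gradient to 1e-5
    relative error over 100 random problem instances."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        dij, masks, objectives, w = random_instance(rng, n_vox=100, n_beams=5)
        g = clrt.objective_gradient(w, dij, objectives, masks)
        h = 1e-6
        fd = np.empty_like(g)
        for j in range(len(w)):
            e = np.zeros_like(w)
            e[j] = h
            fd[j] = (clrt.objective_value(w + e, dij, objectives, masks)
                     - clrt.objective_value(w - e, dij, objectives, masks)) / (2 * h)
        scale = max(np.max(np.abs(fd)), 1.0)
        np.testing.assert_allclose(g, fd, atol=1e-5 * scale)


# -- optimizer ---------------------------------------------------------------

def test_single_beam_closed_form_recovery():
    """One beam, one voxel, D=2 Gy/weight, prescription 10 Gy: w* = 5."""
    dij = toy_dij([[2.0]])
    masks = {"PTV": np.ones((1, 1, 1), bool)}
    objs = [clrt.ObjectiveSpec("PTV", "squared_underdose", 10.0, 1.0),
            clrt.ObjectiveSpec("PTV", "squared_overdose", 10.0, 1.0)]
    plan = clrt.optimize_weights(dij, objs, masks, max_iter=200, tol=1e-12)
    assert plan.weights[0] == pytest.approx(5.0, abs=1e-5)


def test_identical_columns_reach_closed_form_objective():
    dij = toy_dij(np.array([[2.0, 2.0]]))
    masks = {"PTV": np.ones((1, 1, 1), bool)}
    objs = [clrt.ObjectiveSpec("PTV", "squared_underdose", 10.0, 1.0),
            clrt.ObjectiveSpec("PTV", "squared_overdose", 10.0, 1.0)]
    plan = clrt.optimize_weights(dij, objs, masks, max_iter=200, tol=1e-12)
    # degenerate split: only the sum is determined; f must hit the optimum 0
    assert plan.trace[-1] == pytest.approx(0.0, abs=1e-10)
    assert 2.0 * plan.weights.sum() == pytest.approx(10.0, abs=1e-4)


def test_max_iter_zero_returns_initial_weights():
    dij = toy_dij(np.array([[1.0, 3.0], [2.0, 1.0]]))
    masks = {"PTV": np.ones((2, 1, 1), bool)}
    objs = [clrt.ObjectiveSpec("PTV", "squared_underdose", 10.0, 1.0)]
    plan = clrt.optimize_weights(dij, objs, masks, max_iter=0)
    assert len(plan.trace) == 1
    # initial weights: uniform, scaled so mean PTV dose equals the prescription
    d = dij.matrix @ plan.weights
    assert d.mean() == pytest.approx(10.0)


def test_all_zero_penalties_rejected():
    dij = toy_dij([[1.0]])
    objs = [clrt.ObjectiveSpec("PTV", "squared_underdose", 10.0, 0.0)]
    with pytest.raises(ValueError, match="degenerate"):
        clrt.optimize_weights(dij, objs, {"PTV": np.ones((1, 1, 1), bool)})


def test_objective_trace_monotone_nonincreasing():
    rng = np.random.default_rng(5)
    for _ in range(5):
        dij, masks, objectives, _ = random_instance(rng, n_vox=60, n_beams=8)
        masks["PTV"] = masks["S"]
        plan = clrt.optimize_weights(dij, objectives, masks, max_iter=300, tol=1e-9)
        trace = np.array(plan.trace)
        assert len(trace) > 2
        assert np.all(np.diff(trace[1:]) <= 1e-9 * np.maximum(trace[1:-1], 1.0))


def test_constraint_penalty_caps_max_dose():
    # two voxels, one beam; constrain the second voxel's dose below 4 Gy
    dij = toy_dij(np.array([[1.0], [1.0]]))
    masks = {"PTV": np.zeros((2, 1, 1), bool), "OAR": np.zeros((2, 1, 1), bool)}
    masks["PTV"][0] = True
    masks["OAR"][1] = True
    objs = [clrt.ObjectiveSpec("PTV", "squared_underdose", 10.0, 1.0)]
    cons = [clrt.ConstraintSpec("OAR", "max_dose", upper_gy=4.0)]
    plan = clrt.optimize_weights(dij, objs, masks, constraints=cons, max_iter=500, tol=1e-12)
    rep = plan.constraint_violations["max_dose:OAR"]
    assert rep["achieved_gy"] < 6.0  # pulled far below the unconstrained 10 Gy
    assert rep["violation_gy"] == pytest.approx(rep["achieved_gy"] - 4.0, abs=1e-9)


# -- dose accumulation and matrix assembly -----------------------------------

def test_accumulate_hand_matrix_vector_product():
    dij = toy_dij(np.array([[1.0, 2.0], [3.0, 4.0]]))
    d = clrt.accumulate_dose(dij, np.array([1.0, 2.0]))
    np.testing.assert_allclose(d.values.ravel(), [5.0, 11.0])


def test_accumulate_zero_weights_zero_dose():
    dij = toy_dij(np.array([[1.0, 2.0], [3.0, 4.0]]))
    assert np.all(clrt.accumulate_dose(dij, np.zeros(2)).values == 0.0)


def test_accumulate_rejects_dimension_mismatch_and_negative_weights():
    dij = toy_dij(np.array([[1.0, 2.0]]))
    with pytest.raises(ValueError):
        clrt.accumulate_dose(dij, np.ones(3))
    with pytest.raises(ValueError):
        clrt.accumulate_dose(dij, np.array([1.0, -1.0]))


def test_scaling_covariance():
    """Scaling D by c and w by 1/c leaves the accumulated dose invariant."""
    rng = np.random.default_rng(8)
    D = rng.uniform(0, 2, (30, 4))
    w = rng.uniform(0, 3, 4)
    c = 7.3
    d1 = clrt.accumulate_dose(toy_dij(D), w).values
    d2 = clrt.accumulate_dose(toy_dij(c * D), w / c).values
    np.testing.assert_allclose(d1, d2, rtol=1e-12)


def test_assemble_dij_superposition(water_box_2mm, lens_a):
    """D @ 1 equals the sum of the individual beam dose fields."""
    density, structs = water_box_2mm
    body = structs["BODY"]
    center = np.asarray(density.origin) + (np.asarray(density.dims) - 1) / 2.0 * np.asarray(density.spacing)
    beams = [clrt.Beam.aimed(center, u) for u in
             [(0, 0, 1), (0, 1, 0), (np.sqrt(0.5), 0, np.sqrt(0.5))]]
    dij = clrt.assemble_dij(beams, lens_a, density, body)
    total = sum(clrt.beam_dose(lens_a, b, density, body).values for b in beams)
    accumulated = clrt.accumulate_dose(dij, np.ones(3)).values
    # sparsity floor drops entries below 1e-6 of each column max
    np.testing.assert_allclose(accumulated, total, atol=3e-6 * total.max())


def test_assemble_dij_identical_beams_identical_columns(water_box_2mm, lens_b):
    density, structs = water_box_2mm
    center = np.asarray(density.origin) + (np.asarray(density.dims) - 1) / 2.0 * np.asarray(density.spacing)
    b = clrt.Beam.aimed(center, (0, 0, 1))
    dij = clrt.assemble_dij([b, b], lens_b, density, structs["BODY"])
    cols = dij.matrix.toarray()
    np.testing.assert_array_equal(cols[:, 0], cols[:, 1])


def test_assemble_dij_requires_beams(water_box_2mm, lens_a):
    density, structs = water_box_2mm
    with pytest.raises(ValueError):
        clrt.assemble_dij([], lens_a, density, structs["BODY"])
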