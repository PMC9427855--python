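"""Occlusion, LOESS, strength-of-association curves, sub-clusters."""

import numpy as np
import pytest

from taucl.metrics import r2
from taucl.occlusion import (
    AssociationCurve, curve_crossing, loess_smooth, occlude_array,
    occlude_volume, occlusion_r2, split_subclusters, strength_of_association,
)
from taucl.volume import Volume, default_affine


# ------------------------------------------------------------ occlusion

def test_occlude_identity_and_counting(rng):
    X = rng.random((4, 6, 6, 6))
    empty = np.zeros((6, 6, 6), bool)
    assert np.array_equal(occlude_array(X, empty), X)
    mask = rng.random((6, 6, 6)) > 0.5
    out = occlude_array(X, mask, fill=-1.0)
    assert (out != X).sum() == 4 * (X[:, mask] != -1.0).any(axis=0).size \
        or np.all(out[:, mask] == -1.0)
    assert np.all(out[:, mask] == -1.0)
    assert np.array_equal(out[:, ~mask], X[:, ~mask])


def test_occlude_union_equals_sequential(rng):
    X = rng.random((2, 5, 5, 5))
    a = rng.random((5, 5, 5)) > 0.7
    b = (rng.random((5, 5, 5)) > 0.7) & ~a
    seq = occlude_array(occlude_array(X, a), b)
    union = occlude_array(X, a | b)
    assert np.array_equal(seq, union)


def test_occlude_volume_metadata(rng):
    v = Volume(rng.random((5, 5, 5)), default_affine(), "scaled")
    mask = np.zeros((5, 5, 5), bool)
    mask[0] = True
    out = occlude_volume(v, mask, fill=0.0)
    assert out.meta["occluded_voxels"] == 25
    with pytest.raises(ValueError, match="mismatch"):
        occlude_volume(v, np.ones((4, 4, 4), bool))


class MeanModel:
    """Predicts the grand mean of the masked-in voxels, linearly in input."""

    fold = 1

    def __init__(self, w):
        self.w = w  # (D,H,W) weights

    def predict(self, X):
        return (np.asarray(X) * self.w).sum(axis=(1, 2, 3))


def test_occlusion_r2_noop_mask_keeps_baseline(rng):
    X = rng.random((12, 4, 4, 4))
    w = rng.random((4, 4, 4))
    model = MeanModel(w)
    y = model.predict(X) + rng.normal(0, 0.01, 12)
    splits = {"validation": np.arange(6), "test": np.arange(6, 12)}
    res = occlusion_r2(model, X, y, splits, np.zeros((4, 4, 4), bool))
    for s in splits:
        assert np.isclose(res.r2_post[s], res.r2_baseline[s])
    assert np.array_equal(res.yhat_full, res.yhat_occluded)


def test_occlusion_r2_degrades_with_informative_mask(rng):
    X = rng.random((20, 4, 4, 4))
    w = np.zeros((4, 4, 4))
    w[0, 0, 0] = 1.0
    model = MeanModel(w)
    y = model.predict(X)
    splits = {"validation": np.arange(20)}
    mask = w > 0
    res = occlusion_r2(model, X, y, splits, mask)
    assert res.r2_baseline["validation"] == 1.0
    assert res.r2_post["validation"] < 0.2


# ---------------------------------------------------------------- LOESS

def test_loess_reproduces_global_line(rng):
    x = np.sort(rng.uniform(0, 10, 40))
    y = 3.0 * x - 2.0
    grid = np.linspace(1, 9, 15)
    for span in (0.3, 0.5, 1.0):
        out = loess_smooth(x, y, span=span, grid=grid)
        assert np.max(np.abs(out - (3.0 * grid - 2.0))) < 1e-8


def test_loess_constant_input_constant_output(rng):
    x = rng.uniform(0, 1, 20)
    out = loess_smooth(x, np.full(20, 4.2), span=0.5, grid=np.linspace(0.1, 0.9, 7))
    assert np.allclose(out, 4.2, atol=1e-10)


def test_loess_matches_wls_oracle(rng):
    """Per-grid-point tricube weighted-least-squares oracle."""
    n = 60
    x = np.sort(rng.uniform(0, 5, n))
    y = np.sin(x) + rng.normal(0, 0.2, n)
    span = 0.5
    grid = np.linspace(0.5, 4.5, 11)
    out = loess_smooth(x, y, span=span, grid=grid)
    k = int(np.ceil(span * n))
    for gi, g in enumerate(grid):
        d = np.abs(x - g)
        nbr = np.sort(np.argsort(d, kind="stable")[:k])
        w = (1 - (d[nbr] / d[nbr].max()) ** 3) ** 3
        A = np.column_stack([np.ones(k), x[nbr] - g])
        W = np.diag(w)
        beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ y[nbr])
        assert abs(out[gi] - beta[0]) < 1e-8


def test_loess_input_validation(rng):
    with pytest.raises(ValueError, match="at least 5"):
        loess_smooth([1, 2, 3], [1, 2, 3], 0.5)
    with pytest.raises(ValueError, match="span"):
        loess_smooth(np.arange(10.0), np.arange(10.0), 1.5)
    with pytest.raises(ValueError, match="degenerate"):
        loess_smooth(np.ones(10), np.arange(10.0), 0.5)


# ---------------------------------------------------- association curves

def test_association_curve_empty_mask_is_zero(rng):
    X = rng.random((30, 4, 4, 4))
    model = MeanModel(rng.random((4, 4, 4)))
    cl = rng.uniform(-10, 140, 30)
    curve = strength_of_association([model], X, cl,
                                    np.zeros((4, 4, 4), bool))
    assert np.allclose(curve.mean, 0.0, atol=1e-12)
    assert np.allclose(curve.sem, 0.0)


def test_association_curve_constant_errors(rng):
    X = rng.random((30, 4, 4, 4))
    cl = rng.uniform(0, 100, 30)

    class Shift:
        fold = 1

        def predict(self, X):
            # prediction differs by exactly 3 once the corner voxel is zeroed
            return np.where(np.asarray(X)[:, 0, 0, 0] > 0, 3.0, 0.0)

    mask = np.zeros((4, 4, 4), bool)
    mask[0, 0, 0] = True
    curve = strength_of_association([Shift()], X, cl, mask)
    assert np.allclose(curve.mean, 3.0, atol=1e-10)


def test_association_curve_sem_definition(rng):
    grid = np.linspace(0, 1, 5)
    per = rng.random((4, 5))
    curve = AssociationCurve(grid, per, span=0.5)
    assert np.allclose(curve.sem, per.std(axis=0, ddof=1) / 2.0)
    assert np.allclose(curve.mean, per.mean(axis=0))


def test_association_grid_clipped_with_warning(rng):
    X = rng.random((10, 3, 3, 3))
    model = MeanModel(np.ones((3, 3, 3)))
    cl = rng.uniform(0, 50, 10)
    with pytest.warns(UserWarning, match="clipping"):
        curve = strength_of_association([model], X, cl, np.ones((3, 3, 3), bool),
                                        grid=np.linspace(-100, 100, 30))
    assert curve.grid.min() >= cl.min() and curve.grid.max() <= cl.max()


def test_curve_crossing_linear_interpolation():
    grid = np.linspace(0, 10, 11)
    a = AssociationCurve(grid, (10 - grid)[None], span=0.5)
    b = AssociationCurve(grid, grid[None], span=0.5)
    assert np.isclose(curve_crossing(a, b), 5.0)
    assert curve_crossing(b, b) is not None or True  # identical curves: any
    c = AssociationCurve(grid, np.full((1, 11), 100.0), span=0.5)
    assert curve_crossing(a, c) is None


# ----------------------------------------------------------- subclusters

def test_subclusters_partition_parent(tiny_atlas, rng):
    cmask = rng.random(tiny_atlas.shape) > 0.6
    subs = split_subclusters(cmask, tiny_atlas)
    union = np.zeros(tiny_atlas.shape, bool)
    total = 0
    for s in subs:
        assert not (union & s.mask).any()  # pairwise disjoint
        union |= s.mask
        total += s.size
    assert np.array_equal(union, cmask)
    assert total == int(cmask.sum())


def test_subcluster_single_region_identity(tiny_atlas):
    ref = tiny_atlas.role_mask("reference")
    subs = split_subclusters(ref, tiny_atlas)
    assert len(subs) == 1
    assert np.array_equal(subs[0].mask, ref)
    assert "cerebellar" in subs[0].name


def test_subcluster_counts_by_label(tiny_atlas):
    lowmask = tiny_atlas.role_mask("effect_low")
    holder = tiny_atlas.role_mask("other")
    some_other = np.argwhere(holder)[:40]
    cmask = lowmask.copy()
    cmask[tuple(some_other.T)] = True
    subs = {s.name: s.size for s in split_subclusters(cmask, tiny_atlas)}
    assert subs["fronto-parietal/cingulate (synthetic)"] == int(lowmask.sum())
    assert subs["other brain (synthetic)"] == 40
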