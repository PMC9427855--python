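"""Voxel-wise GLM, permutation FWE, clustering, consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taucl.glm import (
    DesignMatrix, cluster_consistency, design_from_cohort, dice,
    fit_voxelwise_glm, fwe_threshold, scale_extent, threshold_and_cluster,
)
from taucl.volume import Volume, default_affine


def random_design(n, rng):
    X = np.column_stack([np.ones(n), rng.normal(size=n),
                         rng.normal(70, 8, n), rng.integers(0, 2, n)])
    return DesignMatrix(X, ["intercept", "cl", "age", "sex"],
                        np.array([0.0, 1.0, 0.0, 0.0]))


# ------------------------------------------------------------------ GLM

def test_design_from_cohort_and_rank_check():
    cohort = pd.DataFrame({"cl": [0, 10, 20, 40, 80.0],
                           "age": [60, 65, 70, 75, 80.0],
                           "sex": ["F", "M", "F", "M", "F"]})
    d = design_from_cohort(cohort)
    assert d.columns == ["intercept", "cl", "age", "sex"]
    assert d.X[:, 3].tolist() == [1, 0, 1, 0, 1]
    bad = DesignMatrix.__new__(DesignMatrix)
    with pytest.raises(ValueError, match="collinear"):
        DesignMatrix(np.column_stack([np.ones(5), np.ones(5)]),
                     ["a", "b"], np.array([0.0, 1.0]))


def test_glm_exact_fit_voxel_flagged_infinite(rng):
    design = random_design(8, rng)
    Y = design.X[:, 1:2].copy()  # dependent identically the CL column
    fit = fit_voxelwise_glm(Y, design)
    assert np.isclose(fit.beta[1, 0], 1.0)
    assert np.isinf(fit.tvalues[0])


def test_glm_matches_pseudoinverse_oracle(rng):
    """Independent normal-equations oracle per voxel (5 subjects x 3 voxels)."""
    design = random_design(5, rng)
    Y = rng.normal(size=(5, 3))
    fit = fit_voxelwise_glm(Y, design)
    X, c = design.X, design.contrast
    for v in range(3):
        beta = np.linalg.pinv(X) @ Y[:, v]
        resid = Y[:, v] - X @ beta
        s2 = resid @ resid / (5 - 4)
        t = (c @ beta) / np.sqrt(s2 * c @ np.linalg.inv(X.T @ X) @ c)
        assert np.allclose(fit.beta[:, v], beta, atol=1e-8)
        assert np.isclose(fit.tvalues[v], t, atol=1e-8)


def test_glm_null_t_follows_student_t(rng):
    """Under independence, voxel t-values follow Student-t(df)."""
    design = random_design(20, rng)
    Y = rng.normal(size=(20, 10000))
    fit = fit_voxelwise_glm(Y, design)
    p = stats.kstest(fit.tvalues, "t", args=(fit.df,)).pvalue
    assert p > 0.01


def test_glm_constant_shift_moves_only_intercept(rng):
    design = random_design(12, rng)
    Y = rng.normal(size=(12, 4))
    a = fit_voxelwise_glm(Y, design)
    b = fit_voxelwise_glm(Y + 5.0, design)
    assert np.allclose(a.beta[1:], b.beta[1:], atol=1e-10)
    assert np.allclose(b.beta[0] - a.beta[0], 5.0, atol=1e-10)
    assert np.allclose(a.tvalues, b.tvalues, atol=1e-10)


# ------------------------------------------------------------------ FWE

def test_fwe_alpha_one_gives_minimum_of_null(rng):
    design = random_design(15, rng)
    Y = rng.normal(size=(15, 50))
    thr, null = fwe_threshold(Y, design, alpha=1.0, n_perm=100, seed=0,
                              return_null=True)
    assert thr == null.min()


def test_fwe_threshold_monotone_in_alpha(rng):
    design = random_design(15, rng)
    Y = rng.normal(size=(15, 50))
    thrs = [fwe_threshold(Y, design, alpha=a, n_perm=150, seed=3)
            for a in (0.01, 0.05, 0.2, 1.0)]
    assert all(a >= b for a, b in zip(thrs, thrs[1:]))


def test_fwe_threshold_reproducible(rng):
    design = random_design(15, rng)
    Y = rng.normal(size=(15, 50))
    assert fwe_threshold(Y, design, n_perm=150, seed=9) == \
        fwe_threshold(Y, design, n_perm=150, seed=9)


def test_fwe_small_n_enumerates_exhaustively(rng):
    design = DesignMatrix(np.column_stack([np.ones(5), rng.normal(size=5)]),
                          ["intercept", "cl"], np.array([0.0, 1.0]))
    Y = rng.normal(size=(5, 10))
    with pytest.warns(UserWarning, match="exhaustively"):
        fwe_threshold(Y, design, n_perm=150, seed=0)


# ----------------------------------------------------------- clustering

def tmap_from(data, voxel=1.0):
    return Volume(np.asarray(data, float), default_affine(voxel), "tstat")


def test_extent_rule_rejects_199_voxel_blob():
    # one connected component of 199 suprathreshold voxels: below the
    # 200-voxel extent it must be discarded entirely
    flat = np.zeros(20 * 20 * 20)
    flat[:199] = 10.0
    data = flat.reshape(20, 20, 20)  # first 199 raster voxels are connected
    cs = threshold_and_cluster(tmap_from(data), 5.0, min_extent=200)
    assert len(cs) == 0
    assert len(threshold_and_cluster(tmap_from(data), 5.0, min_extent=199)) == 1


def test_cluster_empty_when_nothing_suprathreshold():
    cs = threshold_and_cluster(tmap_from(np.zeros((8, 8, 8))), 3.0,
                               min_extent=1)
    assert len(cs) == 0 and cs.mask().sum() == 0


def _flood_fill(binary, start, connectivity=26):
    """Brute-force BFS flood fill oracle."""
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    if connectivity == 6:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    seen = {start}
    queue = [start]
    while queue:
        x, y, z = queue.pop()
        for dx, dy, dz in offsets:
            p = (x + dx, y + dy, z + dz)
            if p in seen:
                continue
            if all(0 <= c < s for c, s in zip(p, binary.shape)) and binary[p]:
                seen.add(p)
                queue.append(p)
    return seen


def test_two_blobs_match_flood_fill_oracle(rng):
    data = np.zeros((20, 22, 20))
    blob1 = [tuple(v) for v in np.argwhere(np.ones((10, 10, 3)))][:300]
    blob2 = [(x + 14, y + 12, z + 10) for x, y, z in
             np.argwhere(np.ones((5, 10, 5)))][:250]
    for v in blob1:
        data[v] = 8.0
    for v in blob2:
        data[v] = 6.0
    cs = threshold_and_cluster(tmap_from(data), 5.0, min_extent=10,
                               connectivity=26)
    assert [c.size for c in cs] == [300, 250]
    oracle1 = _flood_fill(data > 5.0, blob1[0])
    assert {tuple(v) for v in cs.clusters[0].voxels} == oracle1
    assert cs.clusters[0].peak_t == 8.0
    lab = cs.label_map()
    assert set(np.unique(lab)) == {0, 1, 2}


def test_two_sided_clustering_keeps_negative_blobs():
    data = np.zeros((10, 10, 10))
    data[2:5, 2:5, 2:5] = -7.0
    pos = threshold_and_cluster(tmap_from(data), 5.0, min_extent=5)
    two = threshold_and_cluster(tmap_from(data), 5.0, min_extent=5,
                                tail="two-sided")
    assert len(pos) == 0 and len(two) == 1
    assert two.clusters[0].peak_t == -7.0


def test_scale_extent_volume_preserving():
    assert scale_extent(200, 1.0) == 200
    assert scale_extent(200, 2.0) == 25  # 200 mm^3 at 8 mm^3 voxels
    assert scale_extent(200, (1.0, 2.0, 1.0)) == 100


# ---------------------------------------------------------- consistency

def test_dice_examples():
    a = np.zeros((10, 10, 1), bool)
    b = np.zeros((10, 10, 1), bool)
    a[:10, :10] = True
    assert dice(a, a) == 1.0
    assert dice(a, b) == 0.0
    a2 = np.zeros(200, bool)
    b2 = np.zeros(200, bool)
    a2[:100] = True
    b2[50:150] = True
    assert dice(a2, b2) == 0.5
    assert dice(b, b) == 1.0  # two empty masks


def test_cluster_consistency_matrix_and_consensus():
    m1 = np.zeros((6, 6, 6), bool)
    m2 = np.zeros((6, 6, 6), bool)
    m1[:3], m2[1:4] = True, True
    D, consensus = cluster_consistency([m1, m2])
    assert D.shape == (2, 2) and np.allclose(np.diag(D), 1.0)
    assert consensus.max() == 2 and consensus.sum() == m1.sum() + m2.sum()
    with pytest.raises(ValueError):
        cluster_consistency([m1])
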