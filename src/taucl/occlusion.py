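"""Occlusion analysis: cluster importance and the strength-of-association curve.

A cluster's unique contribution to the CNN's Centiloid mapping is measured
by zeroing ("occluding") its voxels in the input volumes, re-predicting,
and quantifying (a) the drop in out-of-sample R^2 per data split and (b)
the *strength of association*: the LOESS-smoothed absolute difference
between predictions on full and occluded inputs as a function of measured
Centiloid, averaged across cross-validation instances with its standard
error of the mean.  Clusters can be decomposed into anatomical sub-clusters
by intersecting them with an atlas, each analysed the same way.

The occlusion fill value defaults to 0 — the minimum of the [0,1]-scaled
input, i.e. "absent signal"; a mean-fill alternative is available for
sensitivity analysis.  LOESS uses tricube weights and local linear fits
over the span-fraction nearest neighbours (default span 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .glm import Cluster
from .metrics import r2
from .volume import Atlas, Volume, check_same_grid

__all__ = [
    "occlude_volume", "occlude_array", "OcclusionResult", "occlusion_r2",
    "loess_smooth", "AssociationCurve", "strength_of_association",
    "split_subclusters", "curve_crossing",
]


def occlude_array(X: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Copy of ``X`` with masked voxels set to ``fill``.

    ``X`` may be a single volume (D, H, W) or a batch (n, D, H, W).
    """
    X = np.asarray(X)
    mask = np.asarray(mask) > 0
    if X.shape[-3:] != mask.shape:
        raise ValueError(f"mask shape {mask.shape} != volume grid {X.shape[-3:]}")
    out = X.copy()
    out[..., mask] = fill
    return out


def occlude_volume(v: Volume, mask, fill: float = 0.0) -> Volume:
    """Volume variant of :func:`occlude_array` (metadata preserved)."""
    m = mask.mask(v.data.shape) if isinstance(mask, Cluster) else np.asarray(mask)
    check_same_grid(v, m, "volume and occlusion mask")
    out = v.with_data(occlude_array(v.data, m, fill))
    out.meta["occluded_voxels"] = int((np.asarray(m) > 0).sum())
    out.meta["occlusion_fill"] = fill
    return out


@dataclass
class OcclusionResult:
    """Per-split R^2 before/after occluding one cluster."""

    cluster_id: int | str
    r2_baseline: dict[str, float]
    r2_post: dict[str, float]
    yhat_full: np.ndarray
    yhat_occluded: np.ndarray
    n_occluded_voxels: int = 0
    fill: float = 0.0

    def delta(self, split: str) -> float:
        return self.r2_post[split] - self.r2_baseline[split]


def occlusion_r2(instance, X: np.ndarray, y, splits: dict, cluster_mask,
                 cluster_id="cluster", fill: float = 0.0) -> OcclusionResult:
    """Re-predict with one cluster occluded and compare R^2 per split.

    ``splits`` maps split name -> integer index array into ``X``/``y``.
    The network weights are untouched; only the input changes.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    mask = cluster_mask.mask(X.shape[1:]) if isinstance(cluster_mask, Cluster) \
        else np.asarray(cluster_mask) > 0
    yhat_full = instance.predict(X)
    yhat_occ = instance.predict(occlude_array(X, mask, fill))
    base = {s: r2(y[idx], yhat_full[np.asarray(idx, int)]) for s, idx in splits.items()}
    post = {s: r2(y[idx], yhat_occ[np.asarray(idx, int)]) for s, idx in splits.items()}
    return OcclusionResult(cluster_id, base, post, yhat_full, yhat_occ,
                           n_occluded_voxels=int(mask.sum()), fill=fill)


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

def loess_smooth(x, y, span: float = 0.5, grid=None) -> np.ndarray:
    """Local linear regression with tricube weights (classic LOESS, degree 1).

    At each grid point the span-fraction nearest neighbours are fit by
    weighted least squares with tricube weights on normalised distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = x.size
    if n < 5:
        raise ValueError("loess_smooth needs at least 5 points")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    grid = x if grid is None else np.asarray(grid, dtype=float)

    k = max(2, int(np.ceil(span * n)))
    out = np.empty(grid.size)
    for g_i, g in enumerate(grid):
        d = np.abs(x - g)
        nbr = np.argpartition(d, k - 1)[:k]
        dmax = d[nbr].max()
        if dmax == 0:  # all neighbours coincide with g
            out[g_i] = y[nbr].mean()
            continue
        w = (1.0 - (d[nbr] / dmax) ** 3) ** 3
        if w.sum() <= 0:
            out[g_i] = y[nbr].mean()
            continue
        # weighted linear fit in (x - g); intercept is the value at g
        xc = x[nbr] - g
        sw, swx = w.sum(), (w * xc).sum()
        swxx, swy, swxy = (w * xc * xc).sum(), (w * y[nbr]).sum(), (w * xc * y[nbr]).sum()
        det = sw * swxx - swx * swx
        if det <= 1e-300 * max(sw * swxx, 1.0):
            out[g_i] = swy / sw
        else:
            out[g_i] = (swxx * swy - swx * swxy) / det
    return out


# ---------------------------------------------------------------------------
# strength of association
# ---------------------------------------------------------------------------

@dataclass
class AssociationCurve:
    """Strength-of-association values on a CL grid, across instances."""

    grid: np.ndarray            # (G,) strictly increasing Centiloid values
    per_instance: np.ndarray    # (K, G)
    span: float
    label: str = ""
    folds: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.per_instance = np.atleast_2d(np.asarray(self.per_instance, dtype=float))
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("CL grid must be strictly increasing")
        if self.per_instance.shape[1] != self.grid.size:
            raise ValueError("per-instance curves do not match the grid")

    @property
    def mean(self) -> np.ndarray:
        return self.per_instance.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        """Standard error of the mean across instances (ddof=1; 0 for K=1)."""
        K = self.per_instance.shape[0]
        if K == 1:
            return np.zeros(self.grid.size)
        return self.per_instance.std(axis=0, ddof=1) / np.sqrt(K)


def strength_of_association(instances, X: np.ndarray, cl, cluster_mask,
                            span: float = 0.5, grid=None, fill: float = 0.0,
                            label: str = "") -> AssociationCurve:
    """Strength-of-association curve of one cluster across the CL continuum.

    For every instance, the absolute prediction difference
    ``|yhat_full - yhat_occluded|`` is computed for all subjects (splits
    pooled) and LOESS-smoothed against measured CL on a common grid
    (default: 100 points over the observed CL range).  The curve is
    summarised by the cross-instance mean and SEM.
    """
    if not instances:
        raise ValueError("need at least one trained instance")
    X = np.asarray(X)
    cl = np.asarray(cl, dtype=float)
    mask = cluster_mask.mask(X.shape[1:]) if isinstance(cluster_mask, Cluster) \
        else np.asarray(cluster_mask) > 0

    lo, hi = float(cl.min()), float(cl.max())
    if grid is None:
        grid = np.linspace(lo, hi, 100)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < lo or grid.max() > hi:
            warnings.warn("CL grid extends beyond the observed range; "
                          "clipping (no extrapolation)")
            grid = grid[(grid >= lo) & (grid <= hi)]

    Xocc = occlude_array(X, mask, fill)
    curves = []
    for inst in instances:
        err = np.abs(inst.predict(X) - inst.predict(Xocc))
        curves.append(loess_smooth(cl, err, span=span, grid=grid))
    return AssociationCurve(grid, np.asarray(curves), span, label=label,
                            folds=tuple(getattr(i, "fold", 0) for i in instances),
                            meta={"fill": fill, "n_voxels": int(mask.sum()),
                                  "n_subjects": int(cl.size)})


def curve_crossing(a: AssociationCurve, b: AssociationCurve) -> float | None:
    """CL where curve ``a`` hands dominance to curve ``b``.

    Finds sign changes of mean(a) - mean(b) on the common grid (linearly
    interpolated); prefers crossings where ``a`` goes from above to below
    (the planted low-CL -> high-CL handover) and returns the last such
    crossing, falling back to the last crossing of any direction.  None if
    the curves never cross.
    """
    if a.grid.size != b.grid.size or not np.allclose(a.grid, b.grid):
        raise ValueError("curves must share a grid")
    d = a.mean - b.mean
    crossings, down = [], []
    for i in range(d.size - 1):
        if d[i] == 0.0:
            crossings.append(float(a.grid[i]))
            continue
        if d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            x = float(a.grid[i] + frac * (a.grid[i + 1] - a.grid[i]))
            crossings.append(x)
            if d[i] > 0:
                down.append(x)
    if down:
        return down[-1]
    return crossings[-1] if crossings else None


# ---------------------------------------------------------------------------
# sub-clusters
# ---------------------------------------------------------------------------

@dataclass
class SubCluster:
    name: str
    label: int
    mask: np.ndarray

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def split_subclusters(cluster, atlas: Atlas) -> list[SubCluster]:
    """Partition a cluster by atlas region.

    Every nonempty intersection with an atlas label becomes a sub-cluster
    named after the region; voxels with background label 0 form a residual
    sub-cluster.  The sub-cluster masks partition the parent exactly.
    """
    cmask = cluster.mask(atlas.shape) if isinstance(cluster, Cluster) \
        else np.asarray(cluster) > 0
    check_same_grid(cmask, atlas, "cluster and atlas")
    out = []
    for lab in np.unique(atlas.labels[cmask]):
        sub = cmask & (atlas.labels == lab)
        name = atlas.name_map.get(int(lab), "background") if lab != 0 else "background"
        out.append(SubCluster(name=name, label=int(lab), mask=sub))
    return out
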