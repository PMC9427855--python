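"""Fit metrics and cross-validation fold planning.

RMSE and out-of-sample R^2 are the two metrics used throughout: R^2 is
1 - SS_res/SS_tot with SS_tot taken around the mean of the *evaluation*
split's measured values, so it may be negative when predictions are worse
than that constant baseline (post-occlusion test-set values genuinely go
negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("rmse: y and yhat must be equal-length, nonempty")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(y, yhat) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot (may be negative).

    SS_tot is computed around the mean of ``y`` itself (the evaluation
    split), not a training mean.  Zero variance in ``y`` leaves R^2
    undefined: a warning is issued and NaN returned.
    """
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("r2: y and yhat must be equal-length, nonempty")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("r2 undefined: zero variance in measured values")
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def select_best_instance(instances):
    """Best cross-validation instance by mean of validation and test RMSE.

    Ties break deterministically toward the lowest fold id.
    """
    if not instances:
        raise ValueError("select_best_instance: empty instance list")
    for inst in instances:
        if inst.rmse_val is None or inst.rmse_test is None:
            raise ValueError(f"instance (fold {inst.fold}) lacks validation/test RMSE")
    return min(instances, key=lambda i: ((i.rmse_val + i.rmse_test) / 2.0, i.fold))


@dataclass
class FoldPlan:
    """K-fold partition of the non-test cohort plus a fixed hold-out test set.

    Each fold holds out one validation block; the remaining non-test
    subjects train.  Blocks are disjoint and jointly cover the non-test
    cohort.
    """

    K: int
    folds: list[dict]  # each: {"fold": int (1-based), "train": [...], "validation": [...]}
    test: list[str]

    def fold_ids(self, fold: int) -> dict:
        return next(f for f in self.folds if f["fold"] == fold)


def make_folds(cohort: pd.DataFrame, K: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded K-fold plan over the non-test subjects of a cohort table.

    Subjects whose ``split`` is ``test`` form the fixed hold-out set; the
    rest are shuffled and cut into K near-equal validation blocks.
    """
    test_ids = cohort.loc[cohort["split"] == "test", "id"].tolist()
    pool = cohort.loc[cohort["split"] != "test", "id"].to_numpy()
    if K < 1 or K > len(pool):
        raise ValueError(f"K={K} invalid for {len(pool)} non-test subjects")
    rng = np.random.default_rng(seed)
    order = pool[rng.permutation(len(pool))]
    blocks = np.array_split(order, K)
    folds = [{"fold": k + 1,
              "validation": list(blocks[k]),
              "train": [s for j, b in enumerate(blocks) if j != k for s in b]}
             for k in range(K)]
    return FoldPlan(K=K, folds=folds, test=test_ids)
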