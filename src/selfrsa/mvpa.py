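"""Classifier-based importance MVPA.

Items are split per participant into high/middle/low importance bins
(thresholds chosen on the self-importance distribution and re-applied to
the friend-importance ratings).  A self-importance ROI is defined for
each participant by a leave-one-participant-out group analysis (peak
search within a 30 mm sphere around the full-group peak; extraction from
a 3-voxel-radius sphere).  A linear SVM (cost 1) discriminates
self-task from other-task category patterns under leave-one-pair-out
cross-validation, with a label-permutation null and Bonferroni
correction over the three importance levels.  A run-pair consistency
analysis (15 pairs per condition, Fisher-z) feeds a 2 x 3
repeated-measures ANOVA.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .groupinfer import GroupTestSpec, signflip_cluster_test
from .iohub import MaskVolume
from .searchlight import sphere_offsets

logger = logging.getLogger("selfrsa.mvpa")

LEVELS = ("high", "middle", "low")


@dataclass
class ImportanceBins:
    """Per-participant thresholds (t1 < t2 on the 1..7 scale) and the
    resulting item-level assignments for both importance dimensions."""

    t1: int
    t2: int
    self_levels: pd.Series     # item_id -> high|middle|low
    friend_levels: pd.Series
    degenerate: bool = False

    def sizes(self, which: str = "self") -> dict:
        lv = self.self_levels if which == "self" else self.friend_levels
        return {k: int((lv == k).sum()) for k in LEVELS}


def _bin_by_thresholds(ratings: pd.Series, t1: int, t2: int) -> pd.Series:
    out = pd.Series("middle", index=ratings.index)
    out[ratings <= t1] = "low"
    out[ratings > t2] = "high"
    return out


def tertile_bins(importance: pd.Series, friend_importance: pd.Series) -> ImportanceBins:
    """Split items into three bins of roughly equal size.

    Thresholds (t1, t2) are chosen on the *self*-importance distribution
    to minimize the maximum pairwise bin-size difference, ties broken
    toward lower thresholds; the identical thresholds are then applied to
    the friend ratings (the same criterion for both conditions).
    """
    importance = pd.Series(importance)
    friend_importance = pd.Series(friend_importance)
    degenerate = importance.nunique() < 3
    if degenerate:
        logger.warning("fewer than 3 distinct importance ratings; "
                       "best-effort split")
    best = None
    for t1, t2 in itertools.combinations(range(1, 7), 2):
        sizes = _bin_by_thresholds(importance, t1, t2).value_counts()
        counts = [int(sizes.get(k, 0)) for k in LEVELS]
        spread = max(counts) - min(counts)
        key = (spread, t1, t2)      # tie-break toward lower thresholds
        if best is None or key < best[0]:
            best = (key, t1, t2)
    _, t1, t2 = best
    return ImportanceBins(
        t1, t2,
        _bin_by_thresholds(importance, t1, t2),
        _bin_by_thresholds(friend_importance, t1, t2),
        degenerate=degenerate,
    )


@dataclass
class RoiSpec:
    center: tuple                   # voxel indices
    voxel_indices: np.ndarray       # (k, 3) in-mask ROI voxels
    sphere_radius_vox: float = 3.0
    search_radius_mm: float = 30.0
    fallback: bool = False


def _sphere_voxels(center, radius_vox, mask: MaskVolume) -> np.ndarray:
    off = sphere_offsets(radius_vox)
    vox = np.asarray(center) + off
    shape = np.array(mask.shape)
    ok = ((vox >= 0) & (vox < shape)).all(axis=1)
    vox = vox[ok]
    return vox[mask.data[tuple(vox.T)]]


def lopo_roi(
    leftout_index: int,
    all_betas: list,
    mask: MaskVolume,
    group_peak_vox: tuple,
    spec: GroupTestSpec,
    search_radius_mm: float = 30.0,
    sphere_radius_vox: float = 3.0,
) -> RoiSpec:
    """Leave-one-participant-out ROI definition.

    The group test is re-run on all maps but the left-out participant's;
    the ROI center is the peak-t in-mask voxel within ``search_radius_mm``
    (mm space, via the affine) of the full-group peak — restricted to
    supra-threshold voxels when any exist in the search sphere, otherwise
    falling back to the plain search-sphere peak (logged).
    """
    remaining = [m for i, m in enumerate(all_betas) if i != leftout_index]
    if len(remaining) < 3:
        raise ValueError("need at least 3 remaining participants")
    result = signflip_cluster_test(remaining, spec, mask)

    coords = mask.coords()
    mm = (np.c_[coords, np.ones(len(coords))] @ mask.affine.T)[:, :3]
    peak_mm = (mask.affine @ np.array([*group_peak_vox, 1.0]))[:3]
    near = np.linalg.norm(mm - peak_mm, axis=1) <= search_radius_mm
    t_near = result.t_volume[tuple(coords[near].T)]
    supra = t_near > result.t_threshold
    fallback = not supra.any()
    if fallback:
        logger.info("lopo_roi: no supra-threshold voxel within %g mm; "
                    "using search-sphere peak", search_radius_mm)
        cand = t_near
    else:
        cand = np.where(supra, t_near, -np.inf)
    cand = np.where(np.isfinite(cand), cand, -np.inf)
    center = tuple(coords[near][int(np.argmax(cand))])
    roi_vox = _sphere_voxels(center, sphere_radius_vox, mask)
    return RoiSpec(center, roi_vox, sphere_radius_vox, search_radius_mm,
                   fallback)


def extract_roi(volume_or_flatmaps, roi: RoiSpec, mask: MaskVolume) -> np.ndarray:
    """Pull ROI voxel values out of a 3D volume."""
    vol = np.asarray(volume_or_flatmaps)
    return vol[tuple(roi.voxel_indices.T)]


def svm_train_predict(train_x, train_y, test_x, cost: float = 1.0):
    """Linear maximum-margin predictions (cost parameter c, default 1).

    Ties on the decision boundary go to the positive class (the
    lexicographically larger label), deterministically.
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) != 2:
        raise ValueError("training data must contain exactly two classes")
    clf = SVC(kernel="linear", C=cost)
    clf.fit(np.asarray(train_x, dtype=float), train_y)
    scores = clf.decision_function(np.asarray(test_x, dtype=float))
    return np.where(scores >= 0, clf.classes_[1], clf.classes_[0])


@dataclass
class CVResult:
    level: str
    fold_accuracies: np.ndarray
    mean_accuracy_pct: float
    p_perm: float | None = None
    significant_bonferroni: bool | None = None
    cost: float = 1.0


def leave_one_pair_out_cv(self_patterns: np.ndarray,
                          other_patterns: np.ndarray,
                          level: str = "",
                          cost: float = 1.0,
                          scale_features: bool = False) -> CVResult:
    """Leave-one-pair-out linear-SVM cross-validation.

    ``self_patterns`` and ``other_patterns`` are (n_runs, n_features)
    category patterns; run k of one task is paired with run k of the
    other (acquisition order).  Each fold trains on the remaining 5 pairs
    (10 samples) and tests on the held-out pair; the mean of the 6 fold
    accuracies is reported in percent.  Features are raw ROI t-values by
    default; ``scale_features`` z-scores each feature within the training
    set (applied to the test set with training statistics).
    """
    a = np.asarray(self_patterns, dtype=float)
    b = np.asarray(other_patterns, dtype=float)
    if a.shape != b.shape:
        raise ValueError("self and other runs must match in shape")
    n_runs = a.shape[0]
    accs = np.empty(n_runs)
    for k in range(n_runs):
        tr = [r for r in range(n_runs) if r != k]
        train_x = np.vstack([a[tr], b[tr]])
        train_y = np.array(["self"] * len(tr) + ["other"] * len(tr))
        test_x = np.vstack([a[[k]], b[[k]]])
        test_y = np.array(["self", "other"])
        if scale_features:
            mu, sd = train_x.mean(axis=0), train_x.std(axis=0)
            sd[sd == 0] = 1.0
            train_x = (train_x - mu) / sd
            test_x = (test_x - mu) / sd
        pred = svm_train_predict(train_x, train_y, test_x, cost=cost)
        accs[k] = (pred == test_y).mean()
    return CVResult(level, accs, float(accs.mean() * 100.0), cost=cost)


def permutation_pvalue(self_patterns: np.ndarray,
                       other_patterns: np.ndarray,
                       observed_acc_pct: float,
                       n_perm: int = 1000,
                       seed: int = 0,
                       cost: float = 1.0,
                       n_comparisons: int = 3,
                       alpha: float = 0.05) -> tuple:
    """Label-permutation p for a CV accuracy, Bonferroni decision.

    Within each training fold the class labels are shuffled (the CV
    structure itself is fixed); one-tailed
    p = (1 + #{null acc >= observed}) / (1 + n_perm), significant when
    p < alpha / n_comparisons.
    """
    if n_perm < 20:
        raise ValueError("n_perm too small for a meaningful null")
    a = np.asarray(self_patterns, dtype=float)
    b = np.asarray(other_patterns, dtype=float)
    n_runs = a.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p_idx in range(n_perm):
        accs = np.empty(n_runs)
        for k in range(n_runs):
            tr = [r for r in range(n_runs) if r != k]
            train_x = np.vstack([a[tr], b[tr]])
            train_y = np.array(["self"] * len(tr) + ["other"] * len(tr))
            rng.shuffle(train_y)  # permuting a balanced multiset keeps 2 classes
            test_x = np.vstack([a[[k]], b[[k]]])
            test_y = np.array(["self", "other"])
            pred = svm_train_predict(train_x, train_y, test_x, cost=cost)
            accs[k] = (pred == test_y).mean()
        null[p_idx] = accs.mean() * 100.0
    p = (1.0 + (null >= observed_acc_pct).sum()) / (1.0 + n_perm)
    return float(p), bool(p < alpha / n_comparisons)


# --------------------------------------------------------------------------
# run-pair consistency and repeated-measures ANOVA


CLIP_R = 1.0 - 1e-7


def within_condition_consistency(condition_runs: dict) -> pd.DataFrame:
    """Mean Fisher-z run-pair correlation per condition for one participant.

    ``condition_runs`` maps (task, level) to an (n_runs, n_features)
    array; all 15 run pairs (6 choose 2) are correlated, Fisher-z
    transformed, and averaged.  Returns a tidy frame with columns task,
    level, mean_z, n_pairs.
    """
    rows = []
    for (task, level), runs in condition_runs.items():
        runs = np.asarray(runs, dtype=float)
        n_runs = runs.shape[0]
        zs = []
        for i, j in itertools.combinations(range(n_runs), 2):
            if runs[i].std() == 0 or runs[j].std() == 0:
                raise ValueError(
                    f"constant pattern in run {i} or {j} of {(task, level)}")
            r = np.corrcoef(runs[i], runs[j])[0, 1]
            zs.append(np.arctanh(np.clip(r, -CLIP_R, CLIP_R)))
        rows.append({"task": task, "level": level,
                     "mean_z": float(np.mean(zs)), "n_pairs": len(zs)})
    return pd.DataFrame(rows)


def consistency_anova(table: pd.DataFrame) -> pd.DataFrame:
    """2 x 3 repeated-measures ANOVA (task x importance level) on the
    participant-level mean Fisher-z consistencies.

    ``table`` columns: participant_id, task, level, mean_z.  Returns F,
    df and p for the two main effects and the interaction.
    """
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(table, depvar="mean_z", subject="participant_id",
                  within=["task", "level"]).fit()
    out = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df_num",
                 "Den DF": "df_den", "Pr > F": "p"})
    out.index = [ix.replace(":", " x ") for ix in out.index]
    return out
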