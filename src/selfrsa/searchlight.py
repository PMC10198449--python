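"""Spherical-searchlight neural RSMs, per-searchlight RSA regression, and
collinearity diagnostics.

For each in-mask center voxel, the searchlight is the set of in-mask
voxels within the given radius (3 voxels in the reference configuration,
at most 123 voxels).  Pairwise Pearson correlations of the item patterns
over those voxels form the neural RSM; its Fisher-z lower-triangle
vector is regressed on the standardized model-RSM predictors and each
coefficient is written to the center voxel of its beta map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iohub import MaskVolume
from .modelrsm import PredictorSet
from .synthgen import PatternSet

logger = logging.getLogger("selfrsa.searchlight")

CLIP_R = 1.0 - 1e-7


@dataclass
class SearchlightSpec:
    radius: float = 3.0          # voxel units
    min_voxels: int = 10

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.min_voxels < 2:
            raise ValueError("min_voxels must be >= 2")


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets (dx, dy, dz) with squared norm <= radius^2,
    including the origin.  Radius 3 gives the familiar 123 offsets."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = int(np.floor(radius))
    grid = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(grid, grid, grid, indexing="ij")
    off = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    return off[(off**2).sum(axis=1) <= radius**2]


def neural_rsm(patterns: np.ndarray, clip: float = CLIP_R,
               method: str = "pearson") -> np.ndarray:
    """Fisher-z item x item pattern-correlation matrix for one searchlight.

    ``patterns`` is (n_items, n_voxels).  |r| is clipped at ``clip``
    before atanh so degenerate searchlights stay finite.  Items with
    zero variance across voxels get NaN in their rows/columns (their
    pairs are treated as missing downstream).  The diagonal is set to
    the clipped maximum and is never used.
    """
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2:
        raise ValueError("patterns must be (items, voxels)")
    if method == "spearman":
        x = np.apply_along_axis(
            lambda row: pd.Series(row).rank().to_numpy(), 1, x)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    bad = norms == 0
    safe = np.where(bad, 1.0, norms)
    u = xc / safe[:, None]
    r = u @ u.T
    r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    z[bad, :] = np.nan
    z[:, bad] = np.nan
    np.fill_diagonal(z, np.arctanh(clip))
    return z


def rsa_regression(neural_vec: np.ndarray, predictors: PredictorSet) -> np.ndarray:
    """OLS of the neural pair vector on the model predictors.

    Returns (intercept, beta_1..beta_p).  Pairs with missing neural
    values are dropped listwise; fewer complete pairs than predictors+2
    raises.
    """
    y = np.asarray(neural_vec, dtype=float)
    x = predictors.matrix
    if len(y) != x.shape[0]:
        raise ValueError("neural vector length does not match predictors")
    keep = np.isfinite(y)
    if keep.sum() < x.shape[1] + 2:
        raise ValueError("too few complete pairs for regression")
    design = np.column_stack([np.ones(keep.sum()), x[keep]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design rank-deficient after listwise deletion")
    beta, *_ = np.linalg.lstsq(design, y[keep], rcond=None)
    return beta


def vif(predictors: PredictorSet | np.ndarray) -> np.ndarray:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j) from
    regressing column j on the remaining columns (with intercept).
    Perfect collinearity yields inf."""
    x = predictors.matrix if isinstance(predictors, PredictorSet) \
        else np.asarray(predictors, dtype=float)
    n, p = x.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = np.empty(p)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ beta
        ss_res = float((resid**2).sum())
        ss_tot = float(((x[:, j] - x[:, j].mean())**2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class BetaMaps:
    """Searchlight regression coefficients: one volume per predictor per
    task, NaN wherever the searchlight was invalid."""

    maps: dict               # (task, predictor_label) -> 3D array
    valid: np.ndarray        # 3D boolean validity mask
    mask: MaskVolume
    predictor_labels: list
    tasks: tuple

    @property
    def n_maps(self) -> int:
        return len(self.maps)

    def stack(self, task: str) -> np.ndarray:
        return np.stack([self.maps[(task, lab)] for lab in self.predictor_labels])


def _searchlight_indices(mask: MaskVolume, spec: SearchlightSpec):
    """Per-center flat indices of in-mask searchlight members."""
    coords = mask.coords()
    idx_vol = np.full(mask.shape, -1, dtype=np.int64)
    idx_vol[tuple(coords.T)] = np.arange(len(coords))
    offsets = sphere_offsets(spec.radius)
    shape = np.array(mask.shape)
    for c in coords:
        nb = c + offsets
        ok = ((nb >= 0) & (nb < shape)).all(axis=1)
        members = idx_vol[tuple(nb[ok].T)]
        yield c, members[members >= 0]


def run_searchlight(
    patterns: PatternSet,
    predictors: PredictorSet,
    mask: MaskVolume | None = None,
    spec: SearchlightSpec | None = None,
    tasks=None,
    method: str = "pearson",
) -> BetaMaps:
    """Searchlight RSA over every in-mask voxel, independently per task.

    Patterns are run-averaged per task before the neural RSMs are
    computed (the run-pooled RSA path).  Centers whose searchlight has
    fewer than ``spec.min_voxels`` in-mask voxels are left NaN.
    """
    if spec is None:
        spec = SearchlightSpec()
    if mask is None:
        mask = patterns.mask
    if mask.shape != patterns.mask.shape:
        raise ValueError("mask grid does not match patterns")
    if tasks is None:
        tasks = patterns.tasks
    n_items = patterns.data.shape[2]
    expected_pairs = n_items * (n_items - 1) // 2
    if predictors.n_pairs != expected_pairs:
        raise ValueError("predictor pair count does not match item count")

    tri = np.tril_indices(n_items, k=-1)
    design = np.column_stack([np.ones(expected_pairs), predictors.matrix])
    pinv = np.linalg.pinv(design)
    labels = predictors.labels

    maps = {(task, lab): np.full(mask.shape, np.nan)
            for task in tasks for lab in labels}
    valid = np.zeros(mask.shape, dtype=bool)
    task_patterns = {task: patterns.run_mean(task) for task in tasks}

    n_skipped = 0
    for center, members in _searchlight_indices(mask, spec):
        if len(members) < spec.min_voxels:
            n_skipped += 1
            continue
        cx, cy, cz = center
        valid[cx, cy, cz] = True
        for task in tasks:
            z = neural_rsm(task_patterns[task][:, members], method=method)
            y = z[tri]
            if np.isfinite(y).all():
                beta = pinv @ y          # fast path: shared design
            else:
                try:
                    beta = rsa_regression(y, predictors)
                except ValueError:
                    valid[cx, cy, cz] = False
                    n_skipped += 1
                    break
            for k, lab in enumerate(labels):
                maps[(task, lab)][cx, cy, cz] = beta[k + 1]
    if n_skipped:
        logger.info("run_searchlight: %d centers skipped (below min voxel "
                    "count or degenerate)", n_skipped)
    return BetaMaps(maps, valid, mask, labels, tuple(tasks))
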