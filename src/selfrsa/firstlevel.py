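"""Event-related GLM: canonical HRF, design construction with parametric
modulators (serially orthogonalized, as SPM does), OLS fitting, t-maps.

The default fit is plain OLS (no prewhitening); an AR(1) whitening flag
is available.  Session effects enter as per-run intercept columns and
six motion parameters can be appended as nuisance regressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iohub import MaskVolume, VolumeGrid
from .synthgen import PatternSet

logger = logging.getLogger("selfrsa.firstlevel")


@dataclass
class HRFSpec:
    """Canonical double-gamma HRF (SPM parameterization).

    Peak at ``peak_delay`` s, undershoot at ``undershoot_delay`` s, both
    with unit dispersion; the undershoot is scaled by ``ratio``.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 1.0 / 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.length_s < 32.0:
            raise ValueError("kernel length must cover >= 32 s")


def canonical_hrf(spec: HRFSpec | None = None, step: float = 0.1) -> np.ndarray:
    """Difference-of-gamma-density kernel sampled every ``step`` s.

    Zero at t=0 (gamma shapes > 1), single positive lobe followed by one
    undershoot, peak normalized to 1.
    """
    if spec is None:
        spec = HRFSpec()
    t = np.arange(0.0, spec.length_s + step / 2, step)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - spec.ratio * under
    return h / np.abs(h).max()


@dataclass
class DesignMatrix:
    matrix: pd.DataFrame     # scans x regressors
    tr: float
    rank: int = field(init=False)
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        x = self.matrix.to_numpy(dtype=float)
        if (np.abs(x).sum(axis=0) == 0).any():
            raise ValueError("design contains an all-zero column")
        self.rank = int(np.linalg.matrix_rank(x))

    @property
    def names(self) -> list:
        return list(self.matrix.columns)


def _boxcar_convolved(onsets, durations, heights, n_scans, tr, hrf_kernel,
                      dt):
    """High-resolution boxcar (scaled per event) convolved with the HRF and
    sampled at scan times."""
    n_hi = int(np.ceil(n_scans * tr / dt)) + len(hrf_kernel)
    x = np.zeros(n_hi)
    for onset, dur, h in zip(onsets, durations, heights):
        a = int(round(onset / dt))
        b = max(a + 1, int(round((onset + dur) / dt)))
        x[a:b] += h
    conv = np.convolve(x, hrf_kernel)[:n_hi]
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    return conv[scan_idx]


def _gram_schmidt(col, earlier):
    """Residualize ``col`` against the columns in ``earlier``."""
    if earlier:
        e = np.column_stack(earlier)
        beta, *_ = np.linalg.lstsq(e, col, rcond=None)
        col = col - e @ beta
    return col


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    modulators: dict | None = None,
    orthogonalize: bool = True,
    nuisance: pd.DataFrame | None = None,
    hrf_spec: HRFSpec | None = None,
    item_wise: bool = False,
    add_intercept: bool = True,
    dt: float = 0.1,
) -> DesignMatrix:
    """Build a scan x regressor design from an event table.

    Condition regressors are boxcars (event duration) convolved with the
    canonical HRF.  ``modulators`` maps a condition to (values, labels)
    where ``values`` is an (n_events_of_condition x m) array in declared
    order: each modulator is mean-centered, multiplied into the boxcar,
    convolved, then — when ``orthogonalize`` — serially residualized
    against the condition regressor and all earlier modulators.
    ``item_wise=True`` builds one regressor per (task, item) instead of
    one per task.  Constant modulators become zero columns after
    centering and are dropped with a warning.
    """
    if hrf_spec is None:
        hrf_spec = HRFSpec()
    kernel = canonical_hrf(hrf_spec, step=dt)
    end = (events["onset_s"] + events["duration_s"]).max()
    if end > n_scans * tr:
        raise ValueError("events extend beyond the run duration")

    cols: dict = {}
    dropped: list = []
    if item_wise:
        for (task, item), grp in events.groupby(["task", "item_id"], sort=True):
            cols[f"item_{item}" if events["task"].nunique() == 1
                 else f"{task}_item_{item}"] = _boxcar_convolved(
                grp["onset_s"].to_numpy(), grp["duration_s"].to_numpy(),
                np.ones(len(grp)), n_scans, tr, kernel, dt)
    else:
        for task, grp in events.groupby("task", sort=True):
            onsets = grp["onset_s"].to_numpy()
            durs = grp["duration_s"].to_numpy()
            base = _boxcar_convolved(onsets, durs, np.ones(len(grp)),
                                     n_scans, tr, kernel, dt)
            cols[str(task)] = base
            if modulators and task in modulators:
                values, labels = modulators[task]
                values = np.atleast_2d(np.asarray(values, dtype=float))
                if values.shape[0] != len(grp):
                    raise ValueError(
                        f"modulator rows ({values.shape[0]}) != events of "
                        f"'{task}' ({len(grp)})")
                if not np.isfinite(values).all():
                    raise ValueError("modulator values must be finite")
                earlier = [base]
                for m, label in enumerate(labels):
                    centered = values[:, m] - values[:, m].mean()
                    if np.all(centered == 0):
                        logger.warning("dropping constant modulator '%s'", label)
                        dropped.append(f"{task}:{label}")
                        continue
                    col = _boxcar_convolved(onsets, durs, centered,
                                            n_scans, tr, kernel, dt)
                    if orthogonalize:
                        col = _gram_schmidt(col, earlier)
                    if np.abs(col).max() < 1e-12:
                        logger.warning("dropping collinear modulator '%s'", label)
                        dropped.append(f"{task}:{label}")
                        continue
                    cols[f"{task}_x_{label}"] = col
                    earlier.append(col)

    if nuisance is not None:
        for name in nuisance.columns:
            cols[f"nuis_{name}"] = nuisance[name].to_numpy(dtype=float)
    if add_intercept:
        cols["intercept"] = np.ones(n_scans)
    dm = DesignMatrix(pd.DataFrame(cols), tr=tr)
    dm.dropped = dropped
    return dm


@dataclass
class GLMResult:
    beta: np.ndarray        # regressors x voxels
    t: np.ndarray           # regressors x voxels
    sigma2: np.ndarray      # residual variance per voxel
    df: int
    names: list
    mask: MaskVolume

    def beta_volume(self, name: str) -> np.ndarray:
        return self._to_volume(self.beta[self.names.index(name)])

    def t_volume(self, name: str) -> np.ndarray:
        return self._to_volume(self.t[self.names.index(name)])

    def _to_volume(self, flat: np.ndarray) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask.data] = flat
        return vol


def _ar1_whiten(y: np.ndarray, x: np.ndarray) -> tuple:
    """Single-pass Cochrane–Orcutt AR(1) whitening (pooled phi estimate)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    num = (resid[1:] * resid[:-1]).sum()
    den = (resid[:-1] ** 2).sum()
    phi = float(num / den) if den > 0 else 0.0
    yw = y[1:] - phi * y[:-1]
    xw = x[1:] - phi * x[:-1]
    return yw, xw


def fit_glm(series, design: DesignMatrix, mask: MaskVolume,
            whiten_ar1: bool = False) -> GLMResult:
    """Per-voxel OLS on masked voxels.

    ``series`` is a 4D :class:`VolumeGrid` (x, y, z, t) or an already
    masked (scans x voxels) array.  Rank-deficient designs are fitted via
    the pseudo-inverse with a warning; t = beta / SE(beta) with
    df = scans - rank.
    """
    x = design.matrix.to_numpy(dtype=float)
    if isinstance(series, VolumeGrid):
        if series.data.ndim != 4:
            raise ValueError("series must be 4D")
        y = series.data[mask.data].T  # scans x voxels
    else:
        y = np.asarray(series, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError(
            f"series has {y.shape[0]} scans but design has {x.shape[0]} rows")
    if whiten_ar1:
        y, x = _ar1_whiten(y, x)

    n, p = x.shape
    rank = int(np.linalg.matrix_rank(x))
    if rank < p:
        logger.warning("rank-deficient design (rank %d < %d columns); "
                       "using pseudo-inverse", rank, p)
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    df = n - rank
    sigma2 = (resid**2).sum(axis=0) / df
    # Var(beta_j) = sigma2 * [pinv pinv^T]_jj  (reduces to (X'X)^-1 when full rank)
    var_scale = np.einsum("ij,ij->i", pinv, pinv)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / np.sqrt(var_scale[:, None] * sigma2[None, :])
    return GLMResult(beta, t, sigma2, df, design.names, mask)


def itemwise_tmaps(
    runs: list,
    mask: MaskVolume,
    path: str = "rsa",
    tr: float = 2.5,
    nuisance: dict | None = None,
    hrf_spec: HRFSpec | None = None,
) -> PatternSet:
    """Item-wise t-maps from per-run time series.

    ``runs`` is a list of (series, events) with single-task runs; every
    item must occur in every run of its task.  ``path="rsa"`` pools runs:
    one concatenated GLM with a regressor per (task, item) spanning all
    runs, per-run intercepts as session effects, optional per-run motion
    nuisance — one t-map per item per task.  ``path="mvpa"`` fits each
    run separately — one t-map per item per task per run.  Output is a
    :class:`PatternSet` with shape (tasks, runs_or_1, items, voxels).
    """
    if path not in ("rsa", "mvpa"):
        raise ValueError("path must be 'rsa' or 'mvpa'")
    by_task: dict = {}
    for series, events in runs:
        task = events["task"].iloc[0]
        if events["task"].nunique() != 1:
            raise ValueError("each run must contain a single task")
        by_task.setdefault(task, []).append((series, events))
    tasks = sorted(by_task)
    item_ids = np.sort(runs[0][1]["item_id"].unique())
    for series, events in runs:
        if not np.array_equal(np.sort(events["item_id"].unique()), item_ids):
            raise ValueError("every item must occur in every run")

    n_items = len(item_ids)
    n_runs = len(by_task[tasks[0]])
    out_runs = n_runs if path == "mvpa" else 1
    data = np.zeros((len(tasks), out_runs, n_items, mask.n_voxels))

    for t_idx, task in enumerate(tasks):
        task_runs = by_task[task]
        if path == "mvpa":
            for r_idx, (series, events) in enumerate(task_runs):
                n_scans = series.data.shape[3] if isinstance(series, VolumeGrid) \
                    else series.shape[0]
                design = build_design(events, tr, n_scans, item_wise=True,
                                      hrf_spec=hrf_spec)
                res = fit_glm(series, design, mask)
                for i_idx, item in enumerate(item_ids):
                    data[t_idx, r_idx, i_idx] = res.t[
                        res.names.index(f"item_{item}")]
        else:
            blocks_y, blocks_x, run_lens = [], [], []
            for series, events in task_runs:
                n_scans = series.data.shape[3] if isinstance(series, VolumeGrid) \
                    else series.shape[0]
                design = build_design(events, tr, n_scans, item_wise=True,
                                      hrf_spec=hrf_spec, add_intercept=False)
                y = series.data[mask.data].T if isinstance(series, VolumeGrid) \
                    else np.asarray(series, dtype=float)
                blocks_y.append(y)
                blocks_x.append(design.matrix[
                    [f"item_{i}" for i in item_ids]].to_numpy())
                run_lens.append(n_scans)
            y = np.vstack(blocks_y)
            x_items = np.vstack(blocks_x)
            session = np.zeros((sum(run_lens), len(run_lens)))
            pos = 0
            for r, ln in enumerate(run_lens):
                session[pos:pos + ln, r] = 1.0
                pos += ln
            cols = {f"item_{i}": x_items[:, k] for k, i in enumerate(item_ids)}
            for r in range(len(run_lens)):
                cols[f"session_{r + 1}"] = session[:, r]
            if nuisance and task in nuisance:
                mo = np.asarray(nuisance[task], dtype=float)
                for m in range(mo.shape[1]):
                    cols[f"motion_{m + 1}"] = mo[:, m]
            design = DesignMatrix(pd.DataFrame(cols), tr=tr)
            res = fit_glm(y, design, mask)
            for i_idx, item in enumerate(item_ids):
                data[t_idx, 0, i_idx] = res.t[res.names.index(f"item_{item}")]

    return PatternSet(0, tuple(tasks), item_ids, data, mask)
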