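"""Synthetic ratings, item activation patterns, and BOLD-like time series.

The generator emulates the data layout of a two-task self-reference
experiment: each participant rates a candidate pool of items on several
7-point dimensions, performs 6 runs per task in the scanner, and every
item yields one activation pattern per run per task.  A designated ROI
carries representational geometry driven by one chosen rating dimension
("the encoding dimension"), in one task only, so the whole downstream
pipeline can be checked against a known ground truth.

Ratings come from a latent-Gaussian copula cut at equal-probability
cutpoints, giving uniform 7-point marginals.  Because coarse
discretization attenuates correlation, the latent correlation is
calibrated (via the bivariate normal orthant probabilities) so that the
*discrete* ratings hit the requested Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .iohub import MaskVolume, VolumeGrid, isotropic_affine

RATING_LEVELS = 7
#: cutpoints Phi^-1(k/7), k = 1..6: equal-probability bins on the latent scale
_CUTPOINTS = stats.norm.ppf(np.arange(1, RATING_LEVELS) / RATING_LEVELS)

DIMENSIONS_EXP1 = (
    "self_descriptiveness",
    "self_importance",
    "valence",
    "familiarity",
    "autobiographical_memory",
)
DIMENSIONS_EXP2 = (
    "self_descriptiveness",
    "self_importance",
    "friend_descriptiveness",
    "friend_importance",
    "valence",
    "familiarity",
    "autobiographical_memory",
)
#: metadata-derived model dimensions appended after the rated ones
META_DIMENSIONS = ("word_length", "self_provided")


def default_corr_targets(dimensions) -> np.ndarray:
    """Moderately correlated rating structure.

    Descriptiveness and importance of the same target tend to correlate
    strongly (0.5 here); evaluative dimensions (valence) correlate weakly
    with both; familiarity and autobiographical memory share episodic
    content (0.3); everything else is near-independent (0.1).
    """
    dims = list(dimensions)
    p = len(dims)
    corr = np.full((p, p), 0.1)
    np.fill_diagonal(corr, 1.0)

    def put(a, b, v):
        if a in dims and b in dims:
            i, j = dims.index(a), dims.index(b)
            corr[i, j] = corr[j, i] = v

    put("self_descriptiveness", "self_importance", 0.5)
    put("friend_descriptiveness", "friend_importance", 0.5)
    put("self_descriptiveness", "valence", 0.3)
    put("self_importance", "valence", 0.3)
    put("familiarity", "autobiographical_memory", 0.3)
    # eigen-clip in case hand-set entries break PSD
    w, v = np.linalg.eigh(corr)
    if w.min() < 0:
        w = np.clip(w, 1e-6, None)
        corr = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


# --------------------------------------------------------------------------
# copula calibration


def discretize_latent(z: np.ndarray) -> np.ndarray:
    """Map latent standard-normal draws to ratings 1..7 via fixed cutpoints."""
    return 1 + np.searchsorted(_CUTPOINTS, z, side="left").astype(np.int64)


def _discrete_corr_of_latent(rho: float) -> float:
    """Exact Pearson correlation of two 7-level ratings cut from a bivariate
    standard normal with latent correlation ``rho``."""
    if rho in (1.0, -1.0):
        return rho
    p_marg = 1.0 - np.arange(1, RATING_LEVELS) / RATING_LEVELS  # P(Z > c_k)
    cov = 0.0
    bvn = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho], [rho, 1.0]],
                                    allow_singular=True)
    for j, cj in enumerate(_CUTPOINTS):
        for k, ck in enumerate(_CUTPOINTS):
            joint = 1.0 - stats.norm.cdf(cj) - stats.norm.cdf(ck) \
                + bvn.cdf([cj, ck])
            cov += joint - p_marg[j] * p_marg[k]
    var = (RATING_LEVELS**2 - 1) / 12.0  # variance of uniform {1..7}
    return float(cov / var)


_CALIB_GRID: tuple | None = None


def _calibration_grid() -> tuple:
    global _CALIB_GRID
    if _CALIB_GRID is None:
        rho = np.linspace(-0.999, 0.999, 81)
        r = np.array([_discrete_corr_of_latent(x) for x in rho])
        _CALIB_GRID = (r, rho)
    return _CALIB_GRID


def latent_corr_for_target(target_r: float) -> float:
    """Latent Gaussian correlation whose discretized ratings have Pearson
    correlation ``target_r``."""
    if abs(target_r) >= 1.0:
        return float(np.sign(target_r))
    r_grid, rho_grid = _calibration_grid()
    return float(np.interp(target_r, r_grid, rho_grid))


@dataclass
class RatingTable:
    """Long-format ratings plus per-item metadata.

    ``ratings`` columns: participant_id, item_id, dimension, rating.
    ``items`` columns: item_id, char_count, self_provided.
    """

    ratings: pd.DataFrame
    items: pd.DataFrame

    @property
    def participants(self) -> list:
        return sorted(self.ratings["participant_id"].unique())

    @property
    def dimensions(self) -> list:
        return list(pd.unique(self.ratings["dimension"]))

    def wide(self, participant_id) -> pd.DataFrame:
        """Items x dimensions table for one participant, including the
        metadata columns word_length (= char_count) and self_provided."""
        sub = self.ratings[self.ratings["participant_id"] == participant_id]
        w = sub.pivot(index="item_id", columns="dimension", values="rating")
        w = w[self.dimensions]
        meta = self.items.set_index("item_id")
        w["word_length"] = meta.loc[w.index, "char_count"]
        w["self_provided"] = meta.loc[w.index, "self_provided"]
        return w

    def subset_items(self, item_ids) -> "RatingTable":
        item_ids = list(item_ids)
        return RatingTable(
            self.ratings[self.ratings["item_id"].isin(item_ids)].copy(),
            self.items[self.items["item_id"].isin(item_ids)].copy(),
        )


def generate_ratings(
    n_participants: int,
    n_items: int,
    dimensions=DIMENSIONS_EXP1,
    dimension_corr_targets: np.ndarray | None = None,
    seed: int = 0,
    char_count_range: tuple = (2, 12),
    p_self_provided: float = 0.5,
) -> RatingTable:
    """Draw a rating table with controlled inter-dimension correlations.

    ``dimension_corr_targets`` is the target Pearson correlation matrix of
    the *discrete* 7-point ratings (symmetric, unit diagonal, PSD); the
    latent Gaussian correlations are calibrated to compensate for the
    attenuation introduced by discretization.
    """
    dims = list(dimensions)
    p = len(dims)
    if dimension_corr_targets is None:
        dimension_corr_targets = np.eye(p)
    target = np.asarray(dimension_corr_targets, dtype=float)
    if target.shape != (p, p):
        raise ValueError(f"target matrix must be {p}x{p}")
    if not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("target correlation matrix must be symmetric")
    if not np.allclose(np.diag(target), 1.0):
        raise ValueError("target correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(target).min() < -1e-8:
        raise ValueError("target correlation matrix must be positive semi-definite")

    latent = np.eye(p)
    for i in range(p):
        for j in range(i):
            latent[i, j] = latent[j, i] = latent_corr_for_target(target[i, j])
    w = np.linalg.eigvalsh(latent)
    if w.min() < 0:  # calibration can nudge a borderline matrix off PSD
        ww, vv = np.linalg.eigh(latent)
        latent = vv @ np.diag(np.clip(ww, 1e-8, None)) @ vv.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
    chol = np.linalg.cholesky(latent)

    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, n_participants + 1):
        z = rng.standard_normal((n_items, p)) @ chol.T
        r = discretize_latent(z)
        for d_idx, dim in enumerate(dims):
            rows.append(pd.DataFrame({
                "participant_id": pid,
                "item_id": np.arange(1, n_items + 1),
                "dimension": dim,
                "rating": r[:, d_idx],
            }))
    ratings = pd.concat(rows, ignore_index=True)

    lo, hi = char_count_range
    items = pd.DataFrame({
        "item_id": np.arange(1, n_items + 1),
        "char_count": rng.integers(lo, hi + 1, size=n_items),
        "self_provided": (rng.random(n_items) < p_self_provided).astype(int),
    })
    return RatingTable(ratings, items)


# --------------------------------------------------------------------------
# masks, ROI and ground truth


def ellipsoid_mask(shape=(30, 36, 30), voxel_mm: float = 3.0,
                   semiaxes_frac=(0.38, 0.42, 0.38)) -> MaskVolume:
    """A smooth ellipsoidal blob standing in for an anatomical ROI mask
    (synthetic; desk-scale but with genuine mask-boundary edge cases)."""
    shape = tuple(shape)
    center = (np.array(shape) - 1) / 2.0
    semi = np.array(semiaxes_frac) * np.array(shape)
    idx = np.indices(shape).astype(float)
    d2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return MaskVolume(d2 <= 1.0, isotropic_affine(voxel_mm))


def sphere_roi(mask: MaskVolume, radius_vox: float = 3.0,
               center=None) -> np.ndarray:
    """Boolean ROI: a sphere of ``radius_vox`` voxels inside the mask."""
    if center is None:
        coords = mask.coords()
        center = coords.mean(axis=0).round().astype(int)
    center = np.asarray(center)
    idx = np.indices(mask.shape).astype(float)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    roi = (d2 <= radius_vox**2) & mask.data
    if not roi.any():
        raise ValueError("ROI sphere does not intersect the mask")
    return roi


@dataclass
class GroundTruth:
    """What the pattern generator embedded, for parameter-recovery tests."""

    encoding_dimension: str
    effect: float
    roi: np.ndarray  # 3D boolean, inside the mask
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")
        if not np.asarray(self.roi).any():
            raise ValueError("ground-truth ROI is empty")


@dataclass
class PatternSet:
    """Per-participant activation patterns on the in-mask voxel support.

    ``data`` has shape (n_tasks, n_runs, n_items, n_voxels); voxel order
    follows ``mask.coords()`` (C order).
    """

    participant_id: int
    tasks: tuple
    item_ids: np.ndarray
    data: np.ndarray
    mask: MaskVolume

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("pattern data must be (tasks, runs, items, voxels)")
        if self.data.shape[3] != self.mask.n_voxels:
            raise ValueError("pattern voxel axis does not match mask support")

    @property
    def n_runs(self) -> int:
        return self.data.shape[1]

    def task_index(self, task: str) -> int:
        return self.tasks.index(task)

    def run_mean(self, task: str) -> np.ndarray:
        """Run-averaged patterns (n_items, n_voxels) for one task — the
        RSA-path stand-in for run-pooled item t-maps."""
        return self.data[self.task_index(task)].mean(axis=0)


def _level_prototypes(n_voxels: int, rng: np.random.Generator,
                      width: float = 1.0) -> np.ndarray:
    """One pattern per rating level (7 x n_voxels) whose *exact* pairwise
    correlation is the Gaussian kernel exp(-(dl)^2 / (4 width^2)).

    This is the dense-channel limit of a population of Gaussian tuning
    curves (width in rating levels) tiling the scale: pattern similarity
    decays strictly monotonically with the absolute rating difference, so
    the noiseless neural RSM is a monotone transform of the 7-|d| model
    RSM.  Rows are zero-mean with per-voxel variance 1.
    """
    if n_voxels < RATING_LEVELS + 1:
        raise ValueError("ROI too small for level prototypes "
                         f"(need >= {RATING_LEVELS + 1} voxels)")
    levels = np.arange(1, RATING_LEVELS + 1, dtype=float)
    corr = np.exp(-((levels[:, None] - levels[None, :]) ** 2)
                  / (4.0 * width**2))
    chol = np.linalg.cholesky(corr)
    g = rng.standard_normal((RATING_LEVELS, n_voxels))
    g -= g.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(g.T)        # zero-mean orthonormal basis rows
    u = q[:, :RATING_LEVELS].T
    return (chol @ u) * np.sqrt(n_voxels)


def generate_item_patterns(
    ratings: RatingTable,
    mask: MaskVolume,
    truth: GroundTruth,
    noise_sd: float = 1.0,
    n_runs: int = 6,
    tasks: tuple = ("self", "word"),
    signal_task: str = "self",
    participant_id: int | None = None,
    seed: int | None = None,
) -> PatternSet:
    """Per-item patterns in which, for the signal-bearing task only, ROI
    voxels respond to the encoding dimension through Gaussian tuning
    curves; everywhere else (and in the control task) pure noise.

    ROI voxels respond through rating-level prototype patterns with an
    exact Gaussian-kernel correlation structure (see
    :func:`_level_prototypes`): pattern similarity inside the ROI decays
    strictly with the absolute rating difference on the encoding
    dimension, matching the 7-|d| model-RSM geometry, and only for
    ``signal_task`` (the task dependence the pipeline is meant to
    detect).  ``effect`` is the per-voxel signal-to-noise amplitude
    ratio.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if participant_id is None:
        participant_id = ratings.participants[0]
    if truth.encoding_dimension not in ratings.dimensions:
        raise ValueError(
            f"encoding dimension '{truth.encoding_dimension}' absent from ratings")
    roi = np.asarray(truth.roi, dtype=bool)
    if (roi & ~mask.data).any():
        raise ValueError("ground-truth ROI extends outside the mask")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    wide = ratings.wide(participant_id)
    item_ids = wide.index.to_numpy()
    r_enc = wide[truth.encoding_dimension].to_numpy(dtype=float)

    coords = mask.coords()
    flat_roi = roi[tuple(coords.T)]          # ROI flags in voxel order
    n_vox = len(coords)
    n_items = len(item_ids)

    data = rng.normal(0.0, noise_sd, size=(len(tasks), n_runs, n_items, n_vox)) \
        if noise_sd > 0 else np.zeros((len(tasks), n_runs, n_items, n_vox))
    if truth.effect > 0:
        # fixed per-participant level prototypes; item pattern = prototype
        # of its rating level on the encoding dimension
        prototypes = _level_prototypes(int(flat_roi.sum()), rng)
        levels = np.clip(np.round(r_enc).astype(int), 1, RATING_LEVELS)
        signal = truth.effect * prototypes[levels - 1]       # items x roi vox
        t_sig = tasks.index(signal_task)
        data[t_sig, :, :, flat_roi] += signal.T[:, None, :]  # over runs
    return PatternSet(participant_id, tuple(tasks), item_ids, data, mask)


def generate_cohort(
    n_participants: int,
    mask: MaskVolume,
    encoding_dimension: str = "self_importance",
    effect: float = 1.0,
    noise_sd: float = 1.0,
    n_items: int = 40,
    n_runs: int = 6,
    tasks: tuple = ("self", "word"),
    dimensions=DIMENSIONS_EXP1,
    corr_targets: np.ndarray | None = None,
    roi: np.ndarray | None = None,
    seed: int = 0,
) -> tuple:
    """Ratings plus one PatternSet per participant, sharing a ground truth."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s % (2**31)) for s in ss.generate_state(n_participants + 1)]
    if corr_targets is None:
        corr_targets = default_corr_targets(dimensions)
    ratings = generate_ratings(n_participants, n_items, dimensions,
                               corr_targets, seed=seeds[0])
    if roi is None:
        roi = sphere_roi(mask, radius_vox=3.0)
    truth = GroundTruth(encoding_dimension, effect, roi, seed=seed)
    cohort = [
        generate_item_patterns(ratings, mask, truth, noise_sd=noise_sd,
                               n_runs=n_runs, tasks=tasks,
                               participant_id=pid, seed=seeds[pid])
        for pid in range(1, n_participants + 1)
    ]
    return ratings, cohort, truth


# --------------------------------------------------------------------------
# BOLD-like time series


def sample_iti(rng: np.random.Generator, n: int,
               low: float = 3.0, high: float = 7.0) -> np.ndarray:
    """Inter-trial intervals, uniform on [low, high] s (mean 5 s default)."""
    return rng.uniform(low, high, size=n)


def make_events(item_ids, task: str, run: int, rng: np.random.Generator,
                duration_s: float = 1.5, start_s: float = 10.0) -> pd.DataFrame:
    """Randomized trial order, one trial per item, uniform ITIs."""
    order = rng.permutation(np.asarray(item_ids))
    itis = sample_iti(rng, len(order))
    onsets = start_s + np.concatenate(
        [[0.0], np.cumsum(duration_s + itis[:-1])])
    return pd.DataFrame({
        "onset_s": onsets,
        "duration_s": duration_s,
        "task": task,
        "item_id": order,
        "run": run,
    })


def generate_timeseries(
    patterns: PatternSet,
    tr: float = 2.5,
    ar_phi: float = 0.3,
    noise_sd: float = 1.0,
    hrf_spec=None,
    seed: int = 0,
    tail_s: float = 32.0,
) -> tuple:
    """4D BOLD-like series per (task, run) plus the matching event table.

    Each voxel time course is the HRF-convolved item design weighted by
    the item amplitudes of that run's pattern, plus stationary AR(1)
    noise (marginal SD ``noise_sd``, lag-1 autocorrelation ``ar_phi``).
    """
    from .firstlevel import HRFSpec, build_design  # avoid import cycle

    if hrf_spec is None:
        hrf_spec = HRFSpec()
    rng = np.random.default_rng(seed)
    mask = patterns.mask
    coords = mask.coords()
    series: dict = {}
    all_events = []
    for t_idx, task in enumerate(patterns.tasks):
        for run in range(1, patterns.n_runs + 1):
            ev = make_events(patterns.item_ids, task, run, rng)
            end = float(ev["onset_s"].iloc[-1] + ev["duration_s"].iloc[-1])
            n_scans = int(np.ceil((end + tail_s) / tr))
            design = build_design(ev, tr=tr, n_scans=n_scans,
                                  item_wise=True, hrf_spec=hrf_spec,
                                  add_intercept=False)
            amp = patterns.data[t_idx, run - 1]           # items x voxels
            cols = [f"item_{i}" for i in patterns.item_ids]
            clean = design.matrix[cols].to_numpy() @ amp  # scans x voxels
            if noise_sd > 0:
                innov = rng.normal(
                    0.0, noise_sd * np.sqrt(1 - ar_phi**2),
                    size=clean.shape)
                innov[0] /= np.sqrt(1 - ar_phi**2)  # stationary start
                noise = sp_signal.lfilter([1.0], [1.0, -ar_phi], innov, axis=0)
            else:
                noise = 0.0
            vol4d = np.zeros(mask.shape + (n_scans,))
            vol4d[tuple(coords.T)] = (clean + noise).T
            series[(task, run)] = VolumeGrid(vol4d, mask.affine)
            all_events.append(ev)
    return series, pd.concat(all_events, ignore_index=True)
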