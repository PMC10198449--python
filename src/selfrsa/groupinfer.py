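"""Group-level inference on beta maps: NaN-aware Gaussian smoothing, a
one-sample sign-flip permutation test with cluster-extent FWE correction
within a mask, cluster-overlap statistics, and a participant-bootstrap
power analysis.

The sign-flip test assumes a symmetric null per participant map: under
H0 each map may be multiplied by a random sign.  Candidate clusters are
connected components of voxels whose one-sample t exceeds the Student-t
quantile at the cluster-forming p; the null distribution of the maximum
cluster extent across flips yields the corrected p
(1 + #{null max >= extent}) / (1 + n_permutations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .iohub import MaskVolume, VolumeGrid

logger = logging.getLogger("selfrsa.groupinfer")

#: scipy binary structures for 6 / 18 / 26 neighbor connectivity
_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class GroupTestSpec:
    n_permutations: int = 5000
    voxel_p: float = 0.005          # 0.001 is the whole-brain convention
    cluster_alpha: float = 0.05
    smooth_fwhm_mm: float = 4.0
    connectivity: int = 18
    seed: int = 0
    one_sided: bool = True
    exhaustive: bool = False        # enumerate all 2^n flips (small n only)

    def __post_init__(self) -> None:
        if not (0 < self.voxel_p < 1 and 0 < self.cluster_alpha < 1):
            raise ValueError("p thresholds must lie in (0, 1)")
        if self.n_permutations < 100 and not self.exhaustive:
            raise ValueError("need at least 100 permutations")
        if self.connectivity not in _CONNECTIVITY:
            raise ValueError("connectivity must be 6, 18 or 26")


def smooth_volume(vol: VolumeGrid, fwhm_mm: float,
                  mask: MaskVolume | None = None) -> VolumeGrid:
    """NaN-aware Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2))
    per axis in mm; values are renormalized by the smoothed validity mask
    so constants are preserved and NaN voxels do not bleed in.
    fwhm_mm = 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    data = np.asarray(vol.data, dtype=float)
    valid = np.isfinite(data)
    if mask is not None:
        valid &= mask.data
    if not valid.any():
        raise ValueError("volume has no valid voxels to smooth")
    if fwhm_mm == 0:
        out = np.where(valid, data, np.nan)
        return VolumeGrid(out, vol.affine)
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / s for s in vol.voxel_size]
    filled = np.where(valid, data, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox)
    den = ndimage.gaussian_filter(valid.astype(float), sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return VolumeGrid(out, vol.affine)


def one_sample_t(x: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0 (participants x voxels)."""
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return m / (sd / np.sqrt(n))


def label_clusters(supra: np.ndarray, connectivity: int = 18) -> tuple:
    """Connected components of a boolean volume; returns (labels, sizes)."""
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(supra, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


@dataclass
class GroupResult:
    t_volume: np.ndarray
    t_threshold: float
    clusters: pd.DataFrame       # peak mm, peak t/Z, extent, p_fwe
    null_max_extent: np.ndarray
    spec: GroupTestSpec
    labels: np.ndarray = field(repr=False, default=None)

    @property
    def any_significant(self) -> bool:
        return bool((self.clusters["p_fwe"] < self.spec.cluster_alpha).any()) \
            if len(self.clusters) else False

    def significant_mask(self) -> np.ndarray:
        out = np.zeros(self.t_volume.shape, dtype=bool)
        for _, row in self.clusters.iterrows():
            if row["p_fwe"] < self.spec.cluster_alpha:
                out |= self.labels == row["cluster_id"]
        return out


def _flip_matrix(n: int, spec: GroupTestSpec) -> np.ndarray:
    # for small samples all 2^n sign assignments are enumerated (the null is
    # then exact); random flips otherwise
    if spec.exhaustive or n < 10 or 2**n <= spec.n_permutations:
        if n > 20:
            raise ValueError("exhaustive flips impractical for n > 20")
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        return 1.0 - 2.0 * bits
    rng = np.random.default_rng(spec.seed)
    return rng.choice([-1.0, 1.0], size=(spec.n_permutations, n))


def signflip_cluster_test(maps, spec: GroupTestSpec,
                          mask: MaskVolume) -> GroupResult:
    """One-sample sign-flip permutation test with cluster-extent FWE.

    ``maps`` is a list of per-participant 3D arrays (or a stacked 4D
    array, participants first) on the mask grid.  Voxels that are
    non-finite for any participant, or have zero variance, are excluded
    (logged).  One-sided (positive) by default.
    """
    x4 = np.stack([m.data if isinstance(m, VolumeGrid) else np.asarray(m)
                   for m in maps]).astype(float)
    n = x4.shape[0]
    if n < 4:
        raise ValueError("need at least 4 participants for a sign-flip test")
    if x4.shape[1:] != mask.shape:
        raise ValueError("maps and mask grids differ")

    coords = mask.coords()
    x = x4[(slice(None),) + tuple(coords.T)]      # n x V
    good = np.isfinite(x).all(axis=0) & (x.std(axis=0) > 0)
    if not good.all():
        logger.info("excluding %d in-mask voxels (non-finite or zero variance)",
                    int((~good).sum()))
    x = x[:, good]
    coords = coords[good]
    if x.shape[1] == 0:
        raise ValueError("no valid voxels in mask")

    df = n - 1
    tcrit = float(stats.t.ppf(1.0 - spec.voxel_p, df))

    # sign-flipped t for all permutations at once: the per-voxel sum of
    # squares is flip-invariant, so only the flipped mean varies
    flips = _flip_matrix(n, spec)
    ssq = (x**2).sum(axis=0)
    means = (flips @ x) / n                                   # perms x V
    var = (ssq[None, :] - n * means**2) / df
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_all = means / np.sqrt(var / n)

    def max_extent(tvec: np.ndarray) -> int:
        supra = np.zeros(mask.shape, dtype=bool)
        sel = tvec > tcrit if spec.one_sided else np.abs(tvec) > tcrit
        supra[tuple(coords[sel].T)] = True
        _, sizes = label_clusters(supra, spec.connectivity)
        return int(sizes.max()) if len(sizes) else 0

    null_max = np.fromiter((max_extent(t_all[k]) for k in range(len(flips))),
                           dtype=np.int64, count=len(flips))

    t_obs = one_sample_t(x)
    supra = np.zeros(mask.shape, dtype=bool)
    sel = t_obs > tcrit if spec.one_sided else np.abs(t_obs) > tcrit
    supra[tuple(coords[sel].T)] = True
    labels, sizes = label_clusters(supra, spec.connectivity)

    t_vol = np.full(mask.shape, np.nan)
    t_vol[tuple(coords.T)] = t_obs
    affine = mask.affine
    rows = []
    n_perm = len(flips)
    for cid, size in enumerate(sizes, start=1):
        in_cluster = labels == cid
        tc = np.where(in_cluster, t_vol, -np.inf)
        peak = np.unravel_index(np.nanargmax(tc), t_vol.shape)
        peak_mm = (affine @ np.array([*peak, 1.0]))[:3]
        peak_t = float(t_vol[peak])
        p_fwe = (1.0 + (null_max >= size).sum()) / (1.0 + n_perm)
        rows.append({
            "cluster_id": cid,
            "x_mm": peak_mm[0], "y_mm": peak_mm[1], "z_mm": peak_mm[2],
            "peak_t": peak_t,
            "peak_z": float(stats.norm.isf(stats.t.sf(peak_t, df))),
            "extent_voxels": int(size),
            "p_fwe": float(p_fwe),
        })
    clusters = pd.DataFrame(
        rows, columns=["cluster_id", "x_mm", "y_mm", "z_mm", "peak_t",
                       "peak_z", "extent_voxels", "p_fwe"])
    if len(clusters):
        clusters = clusters.sort_values("extent_voxels", ascending=False,
                                        ignore_index=True)
    return GroupResult(t_vol, tcrit, clusters, null_max, spec, labels)


@dataclass
class OverlapStats:
    intersection: int
    union: int

    @property
    def jaccard(self) -> float:
        return self.intersection / self.union


def overlap_stats(a: np.ndarray, b: np.ndarray) -> OverlapStats:
    """Voxel-set intersection, union and Jaccard index of two binary maps."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("both maps are empty")
    return OverlapStats(int((a & b).sum()), union)


@dataclass
class PowerEstimate:
    n_target: int
    n_boot: int
    power: float
    seed: int


def bootstrap_power(pilot_maps, n_target: int, n_boot: int,
                    spec: GroupTestSpec, mask: MaskVolume,
                    seed: int = 0) -> PowerEstimate:
    """Participant-bootstrap power: resample ``n_target`` pilot maps with
    replacement, run the sign-flip cluster test, and report the fraction
    of replicates with any FWE-significant in-mask cluster."""
    pilot = [m.data if isinstance(m, VolumeGrid) else np.asarray(m)
             for m in pilot_maps]
    if len(pilot) < 2:
        raise ValueError("need more than one pilot participant")
    if n_boot < 10:
        raise ValueError("n_boot too small for a stable estimate")
    rng = np.random.default_rng(seed)
    hits = 0
    for b in range(n_boot):
        idx = rng.integers(0, len(pilot), size=n_target)
        rep_spec = GroupTestSpec(
            n_permutations=spec.n_permutations, voxel_p=spec.voxel_p,
            cluster_alpha=spec.cluster_alpha,
            smooth_fwhm_mm=spec.smooth_fwhm_mm,
            connectivity=spec.connectivity,
            seed=int(rng.integers(0, 2**31)), one_sided=spec.one_sided)
        res = signflip_cluster_test([pilot[i] for i in idx], rep_spec, mask)
        hits += int(res.any_significant)
    return PowerEstimate(n_target, n_boot, hits / n_boot, seed)
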