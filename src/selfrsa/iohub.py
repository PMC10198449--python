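"""Volume and table I/O, run configuration, and the stage-chaining pipeline.

Volumes are held as :class:`VolumeGrid` (data + affine) and masks as
:class:`MaskVolume`.  All files are NIfTI-1/2 via nibabel; tables are
CSV/TSV via pandas.  Voxel indices are 0-based throughout; millimetre
coordinates are obtained through the affine.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("selfrsa")

DEFAULT_SEED = 20230517


class VolumeError(ValueError):
    """Raised for malformed or mismatched volume inputs."""


@dataclass
class VolumeGrid:
    """A scalar lattice with its voxel-to-mm affine.

    ``data`` may be 3D (one map) or 4D (a time series); ``affine`` is the
    4x4 voxel->mm transform of the spatial axes.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeError(f"affine must be 4x4, got {self.affine.shape}")
        if self.data.ndim not in (3, 4):
            raise VolumeError(f"volume data must be 3D or 4D, got {self.data.ndim}D")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size(self) -> tuple:
        """Voxel edge lengths in mm, from the norms of the affine columns."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (n x 3) to mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (homog @ self.affine.T)[:, :3]


@dataclass
class MaskVolume:
    """Binary inclusion mask on the same grid as the volumes it gates."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeError(f"mask must be 3D, got {self.data.ndim}D")
        if not self.data.any():
            raise VolumeError("mask contains no included voxels")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def coords(self) -> np.ndarray:
        """In-mask voxel indices as an (n, 3) int array (C order)."""
        return np.array(np.nonzero(self.data)).T

    def as_grid(self) -> VolumeGrid:
        return VolumeGrid(self.data.astype(np.uint8), self.affine)


def isotropic_affine(voxel_mm: float, origin: tuple = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Affine for an axis-aligned isotropic grid."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    aff[:3, 3] = origin
    return aff


def read_volume(path, expect_ndim: int = 3) -> VolumeGrid:
    """Load a NIfTI volume, preserving NaNs.

    Raises :class:`VolumeError` when the on-disk dimensionality does not
    match ``expect_ndim`` (e.g. a 4D series passed to a 3D reader).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data) if data.ndim > expect_ndim else data
    if data.ndim != expect_ndim:
        raise VolumeError(
            f"{path.name}: expected {expect_ndim}D volume, got {data.ndim}D"
        )
    return VolumeGrid(data, img.affine)


def write_volume(vol: VolumeGrid, path) -> None:
    """Write a volume as NIfTI; round-trips data, affine and NaN pattern."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    nib.save(img, str(path))


def read_mask(path) -> MaskVolume:
    vol = read_volume(path, expect_ndim=3)
    return MaskVolume(vol.data > 0, vol.affine)


def write_mask(mask: MaskVolume, path) -> None:
    write_volume(mask.as_grid(), path)


def read_events(path) -> pd.DataFrame:
    """Read a TSV event table (onset_s, duration_s, task, item_id[, run])."""
    events = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "task", "item_id"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return events


def write_events(events: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, sep="\t", index=False)


def read_ratings(path) -> pd.DataFrame:
    """Read a long-format ratings CSV (participant_id, item_id, dimension, rating)."""
    ratings = pd.read_csv(path)
    required = {"participant_id", "item_id", "dimension", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"rating table missing columns: {sorted(missing)}")
    return ratings


@dataclass
class RunConfig:
    """Parameters for one pipeline run.  Every random stage has its own seed
    derived deterministically from ``seed``."""

    seed: int = DEFAULT_SEED
    out_dir: str = "selfrsa_out"
    experiment: int = 1                 # 1: self/word (7 predictors), 2: self/other (9)
    n_participants: int = 8
    n_items: int = 40
    n_runs: int = 6
    n_candidate_items: int = 80
    grid_shape: tuple = (18, 20, 18)
    voxel_mm: float = 3.0
    effect: float = 1.0
    noise_sd: float = 1.0
    searchlight_radius: float = 3.0
    min_searchlight_voxels: int = 10
    smooth_fwhm_mm: float = 4.0
    n_permutations: int = 500
    voxel_p: float = 0.005
    cluster_alpha: float = 0.05
    mvpa_n_permutations: int = 200
    power_n_target: int = 12
    power_n_boot: int = 50
    run_glm_demo: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        for name in ("voxel_p", "cluster_alpha", "effect", "noise_sd",
                     "searchlight_radius", "smooth_fwhm_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.voxel_p < 1 and 0 < self.cluster_alpha < 1):
            raise ValueError("p thresholds must lie in (0, 1)")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        tag = zlib.crc32(stage.encode()) % (2**31)
        return int(np.random.SeedSequence([self.seed, tag])
                   .generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order and return a report of produced artifacts.

    Stages: simulate -> select-stimuli -> glm -> rsa -> group -> mvpa ->
    power.  Every output path listed in the report exists on return; the
    run log records seeds and parameter values.
    """
    from . import pipeline  # local import: stages pull in every module

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(logfile=out / "run.log")
    logger.info("run_pipeline config: %s", json.dumps(config.to_dict()))

    report: dict = {"config": config.to_dict(), "artifacts": {}}
    state: dict = {}
    stages = [
        ("simulate", pipeline.stage_simulate),
        ("select-stimuli", pipeline.stage_select_stimuli),
        ("glm", pipeline.stage_glm),
        ("rsa", pipeline.stage_rsa),
        ("group", pipeline.stage_group),
        ("mvpa", pipeline.stage_mvpa),
        ("power", pipeline.stage_power),
    ]
    for name, fn in stages:
        logger.info("stage %s: start (seed=%d)", name, config.stage_seed(name))
        try:
            artifacts = fn(config, state, out)
        except Exception as exc:  # abort with stage name and cause
            raise PipelineError(name, exc) from exc
        report["artifacts"][name] = artifacts
        logger.info("stage %s: done", name)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
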