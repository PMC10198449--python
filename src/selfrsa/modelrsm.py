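"""Model representational similarity matrices and the RSA predictor set.

One model RSM per dimension: for 7-point ratings similarity is
7 - |a - b|; for word length it is maxlen - |a - b| (maxlen taken within
the participant's final item set); for the binary self-provided flag it
is 1 when both items share provenance and 0 otherwise.  Each RSM's
strictly-lower-triangle vector, z-scored, is one column of the
regression design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import META_DIMENSIONS, RATING_LEVELS, RatingTable

logger = logging.getLogger("selfrsa.modelrsm")

KINDS = ("rating7", "length", "binary")


def rating_similarity(a, b):
    """7 minus the absolute rating difference; inputs on the 1..7 scale."""
    a, b = np.asarray(a), np.asarray(b)
    if ((a < 1) | (a > RATING_LEVELS) | (b < 1) | (b > RATING_LEVELS)).any():
        raise ValueError("ratings must lie in 1..7")
    return RATING_LEVELS - np.abs(a - b)


def length_similarity(a, b, maxlen):
    """maxlen minus the absolute character-count difference."""
    a, b = np.asarray(a), np.asarray(b)
    if ((a < 1) | (a > maxlen) | (b < 1) | (b > maxlen)).any():
        raise ValueError("character counts must lie in 1..maxlen")
    return maxlen - np.abs(a - b)


def source_similarity(a, b):
    """1 when both items have the same provenance (both self-provided or
    both experimenter-provided), else 0."""
    a, b = np.asarray(a), np.asarray(b)
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("provenance flags must be binary")
    return (a == b).astype(int)


@dataclass
class ModelRSM:
    values: np.ndarray
    dimension: str
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown RSM kind '{self.kind}'")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("RSM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("RSM must be symmetric")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]


def build_model_rsm(values, kind: str, dimension: str = "",
                    maxlen: int | None = None) -> ModelRSM:
    """All pairwise similarities of one per-item value sequence."""
    v = np.asarray(values)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("need a 1D sequence of at least 3 item values")
    if kind == "rating7":
        mat = rating_similarity(v[:, None], v[None, :])
    elif kind == "length":
        if maxlen is None:
            maxlen = int(v.max())
        mat = length_similarity(v[:, None], v[None, :], maxlen)
    elif kind == "binary":
        mat = source_similarity(v[:, None], v[None, :])
    else:
        raise ValueError(f"unknown RSM kind '{kind}'")
    return ModelRSM(mat.astype(float), dimension, kind)


def vectorize_lower(rsm) -> np.ndarray:
    """Strictly-lower-triangle entries, row-major, length n(n-1)/2.

    The diagonal is excluded; asymmetry beyond 1e-10 is rejected.
    """
    mat = rsm.values if isinstance(rsm, ModelRSM) else np.asarray(rsm, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("matrix must be square")
    delta = mat - mat.T
    np.fill_diagonal(delta, 0.0)
    if np.nanmax(np.abs(delta)) > 1e-10:
        raise ValueError("matrix asymmetric beyond 1e-10")
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def pair_index(n: int) -> pd.DataFrame:
    """(item_i, item_j) positions matching :func:`vectorize_lower` order."""
    i, j = np.tril_indices(n, k=-1)
    return pd.DataFrame({"item_i": i, "item_j": j})


@dataclass
class PredictorSet:
    """Standardized lower-triangle vectors, one column per model RSM."""

    matrix: np.ndarray       # n_pairs x n_predictors, each column z-scored
    labels: list
    dropped: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("predictor matrix/label mismatch")

    @property
    def n_pairs(self) -> int:
        return self.matrix.shape[0]


def standardize_predictors(rsms) -> PredictorSet:
    """z-score each RSM's pair vector; zero-variance predictors (e.g. all
    items self-provided) are dropped with a log entry."""
    cols, labels, dropped = [], [], []
    for rsm in rsms:
        vec = vectorize_lower(rsm)
        sd = vec.std()
        if sd == 0:
            logger.warning("dropping zero-variance predictor '%s'", rsm.dimension)
            dropped.append(rsm.dimension)
            continue
        cols.append((vec - vec.mean()) / sd)
        labels.append(rsm.dimension)
    if not cols:
        raise ValueError("no predictor with nonzero variance")
    return PredictorSet(np.column_stack(cols), labels, dropped)


def model_rsms_for_participant(
    ratings: RatingTable,
    participant_id,
    dimensions=None,
    standardize_ratings_first: bool = False,
) -> list:
    """Model RSMs for one participant: one rating7 RSM per rated dimension
    plus the word-length and provenance RSMs from item metadata.

    ``standardize_ratings_first`` applies the alternative reading in which
    raw ratings are z-scored before similarity is computed (similarity is
    then the negative absolute z difference); default is to z-score the
    pair vectors instead (see :func:`standardize_predictors`).
    """
    wide = ratings.wide(participant_id)
    if dimensions is None:
        dimensions = [c for c in wide.columns if c not in META_DIMENSIONS]
    rsms = []
    for dim in dimensions:
        vals = wide[dim].to_numpy()
        if standardize_ratings_first:
            z = (vals - vals.mean()) / vals.std() if vals.std() > 0 \
                else np.zeros_like(vals, dtype=float)
            mat = -np.abs(z[:, None] - z[None, :])
            rsms.append(ModelRSM(mat, dim, "rating7"))
        else:
            rsms.append(build_model_rsm(vals, "rating7", dim))
    maxlen = int(wide["word_length"].max())
    rsms.append(build_model_rsm(wide["word_length"].to_numpy(), "length",
                                "word_length", maxlen=maxlen))
    rsms.append(build_model_rsm(wide["self_provided"].to_numpy(), "binary",
                                "self_provided"))
    return rsms
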