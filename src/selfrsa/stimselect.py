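"""Stimulus-set decorrelation and behavioral consistency QC.

The stimulus optimizer draws random k-item subsets of the candidate pool
and keeps the subset whose largest cross-dimension correlation magnitude
(``r_highest``) is smallest — optionally subject to a cap on one
designated pair of dimensions (used when two dimensions, e.g.
descriptiveness and importance, are strongly correlated for a
participant and only need to be kept below a ceiling rather than
minimized).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("selfrsa.stimselect")


def dimension_correlations(wide: pd.DataFrame, dimensions=None) -> pd.DataFrame:
    """Pearson correlation matrix across rating dimensions for a set of items.

    ``wide`` is items x dimensions (numeric; binary flags coded 0/1).  A
    zero-variance dimension within the subset yields NaN in its row and
    column (undefined, never silently 0).
    """
    if dimensions is not None:
        wide = wide[list(dimensions)]
    if len(wide) < 3:
        raise ValueError("need at least 3 items to correlate dimensions")
    x = wide.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=wide.columns, columns=wide.columns)


def r_highest(corr: pd.DataFrame | np.ndarray, exclude_pairs=(),
              absolute: bool = True) -> float:
    """Largest off-diagonal correlation over non-excluded dimension pairs.

    By default the magnitude |r| is used (collinearity is sign-agnostic);
    ``absolute=False`` gives the signed maximum instead.
    """
    if isinstance(corr, pd.DataFrame):
        labels = list(corr.columns)
        mat = corr.to_numpy(dtype=float)
    else:
        mat = np.asarray(corr, dtype=float)
        labels = list(range(mat.shape[0]))
    excl = {frozenset(p) for p in exclude_pairs}
    best = None
    for i, j in itertools.combinations(range(len(labels)), 2):
        if frozenset((labels[i], labels[j])) in excl:
            continue
        v = abs(mat[i, j]) if absolute else mat[i, j]
        if not np.isnan(v) and (best is None or v > best):
            best = v
    if best is None:
        raise ValueError("all dimension pairs excluded or undefined")
    return float(best)


@dataclass
class SelectionResult:
    chosen_items: list
    r_highest: float
    constrained_pair: tuple | None = None
    constrained_value: float | None = None
    feasible: bool = True
    iterations: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "chosen_items": [int(i) for i in self.chosen_items],
            "r_highest": self.r_highest,
            "constrained_pair": list(self.constrained_pair)
            if self.constrained_pair else None,
            "constrained_value": self.constrained_value,
            "feasible": self.feasible,
            "iterations": self.iterations,
            "seed": self.seed,
        }


def _subset_objective(wide, idx, dims, cap_pair, cap_threshold, absolute):
    corr = dimension_correlations(wide.iloc[list(idx)], dims)
    if cap_pair is not None:
        cap_val = float(corr.loc[cap_pair[0], cap_pair[1]])
        obj = r_highest(corr, exclude_pairs=[cap_pair], absolute=absolute)
        ok = not np.isnan(cap_val) and cap_val < cap_threshold
        return obj, cap_val, ok
    return r_highest(corr, absolute=absolute), None, True


def select_stimulus_set(
    wide: pd.DataFrame,
    k: int,
    n_iter: int = 100_000,
    dimensions=None,
    cap: tuple | None = None,            # ((dim_a, dim_b), threshold)
    seed: int = 0,
    absolute: bool = True,
    early_stop: float = 0.05,
    exhaustive: bool = False,
) -> SelectionResult:
    """Best-of-``n_iter`` random k-subsets minimizing ``r_highest``.

    With ``cap=((a, b), thr)`` the (a, b) correlation is removed from the
    objective and the search is restricted to subsets with signed
    r(a, b) < thr; if no sampled subset satisfies the cap the result is
    returned with ``feasible=False`` (a reported status, not an error).
    ``exhaustive=True`` enumerates all C(n, k) subsets instead.
    """
    n = len(wide)
    if not 0 < k <= n:
        raise ValueError(f"k must be in 1..{n}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    dims = list(dimensions) if dimensions is not None else list(wide.columns)
    cap_pair, cap_thr = (tuple(cap[0]), float(cap[1])) if cap else (None, None)

    rng = np.random.default_rng(seed)
    if exhaustive:
        candidates = itertools.combinations(range(n), k)
    elif k == n:
        candidates = iter([tuple(range(n))])
    else:
        candidates = (tuple(rng.choice(n, size=k, replace=False))
                      for _ in range(n_iter))

    best = None          # (objective, idx, cap_val)
    best_infeasible = None
    used = 0
    for idx in candidates:
        used += 1
        obj, cap_val, ok = _subset_objective(
            wide, idx, dims, cap_pair, cap_thr, absolute)
        if np.isnan(obj):
            continue
        if ok:
            if best is None or obj < best[0]:
                best = (obj, idx, cap_val)
            if best[0] < early_stop and not exhaustive:
                break
        elif best_infeasible is None or obj < best_infeasible[0]:
            best_infeasible = (obj, idx, cap_val)

    feasible = best is not None
    if not feasible:
        logger.warning("no sampled subset satisfied the cap %s < %s",
                       cap_pair, cap_thr)
        best = best_infeasible
    if best is None:
        raise ValueError("no subset produced a defined objective")
    obj, idx, cap_val = best
    return SelectionResult(
        chosen_items=list(wide.index[list(idx)]),
        r_highest=float(obj),
        constrained_pair=cap_pair,
        constrained_value=cap_val,
        feasible=feasible,
        iterations=used,
        seed=seed,
    )


# --------------------------------------------------------------------------
# behavioral scoring and QC


def proportion_yes(responses) -> float:
    """Proportion of yes (1) responses across the (nominally six) binary
    in-scanner judgments of one item; missing responses shrink the
    denominator (logged)."""
    arr = np.asarray(responses, dtype=float)
    valid = ~np.isnan(arr)
    if valid.sum() == 0:
        raise ValueError("no valid responses for item")
    if valid.sum() < arr.size:
        logger.info("proportion_yes: %d/%d valid responses",
                    int(valid.sum()), arr.size)
    return float(arr[valid].sum() / valid.sum())


def consistency_score(session_a, session_b) -> float:
    """Pearson correlation of one participant's item scores across two
    rating sessions; NaN (flagged) when either vector is constant."""
    a = np.asarray(session_a, dtype=float)
    b = np.asarray(session_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sessions must cover the same items")
    if a.std() == 0 or b.std() == 0:
        logger.warning("consistency undefined: zero-variance session")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class QCReport:
    """Per-participant consistency and exclusion flags."""

    scores: pd.DataFrame  # participant_id, one column per session pair
    group_mean: float = field(init=False)
    group_sd: float = field(init=False)

    def __post_init__(self) -> None:
        vals = self.score_matrix().mean(axis=1)
        self.group_mean = float(vals.mean())
        self.group_sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")

    def score_matrix(self) -> pd.DataFrame:
        return self.scores.set_index("participant_id")


def apply_exclusions(qc: QCReport, rule: str = "sd3",
                     min_r: float = 0.5) -> pd.DataFrame:
    """Exclusion flags under the selectable rule set.

    rule ``"sd3"``: a participant is excluded when the Fisher-z of their
    mean consistency falls 3 or more population SDs below the group mean
    of those z values (population SD: with a sample SD a single outlier
    among n can never reach 3, since max |dev|/sd is (n-1)/sqrt(n)).
    rule ``"min_r"``: excluded when *any* session-pair correlation is
    < ``min_r`` (strictly; a score exactly at the bound is retained).
    """
    mat = qc.score_matrix()
    if rule == "sd3":
        if len(mat) < 3:
            raise ValueError("rule 'sd3' needs at least 3 participants")
        z = np.arctanh(np.clip(mat.to_numpy(dtype=float), -1 + 1e-12, 1 - 1e-12))
        score = z.mean(axis=1)
        cut = score.mean() - 3.0 * score.std(ddof=0)
        excluded = score <= cut + 1e-12
        reason = [f"mean Fisher-z {s:.3f} < {cut:.3f}" if e else ""
                  for s, e in zip(score, excluded)]
    elif rule == "min_r":
        excluded = (mat.to_numpy(dtype=float) < min_r).any(axis=1)
        reason = [f"some session correlation < {min_r}" if e else ""
                  for e in excluded]
    else:
        raise ValueError(f"unknown exclusion rule '{rule}'")
    return pd.DataFrame({
        "participant_id": mat.index,
        "excluded": excluded,
        "reason": reason,
    })
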