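"""Stage implementations chained by :func:`selfrsa.iohub.run_pipeline`.

The pipeline runs entirely on synthetic data with a known ground truth:
simulate ratings and an ROI-bearing pattern cohort, decorrelate the
stimulus set, demonstrate the item-wise GLM on generated time series,
run searchlight RSA, group inference, classifier MVPA, and the bootstrap
power analysis.  Each stage returns a dict of artifact paths/counts that
ends up in the run report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import firstlevel, groupinfer, modelrsm, mvpa, searchlight, stimselect, synthgen
from .iohub import RunConfig, VolumeGrid, write_mask, write_volume

logger = logging.getLogger("selfrsa.pipeline")


def _dimensions(config: RunConfig):
    return synthgen.DIMENSIONS_EXP2 if config.experiment == 2 \
        else synthgen.DIMENSIONS_EXP1


def stage_simulate(config: RunConfig, state: dict, out: Path) -> dict:
    seed = config.stage_seed("simulate")
    dims = _dimensions(config)
    ratings = synthgen.generate_ratings(
        config.n_participants, config.n_candidate_items, dims,
        synthgen.default_corr_targets(dims), seed=seed)
    mask = synthgen.ellipsoid_mask(config.grid_shape, config.voxel_mm)
    roi = synthgen.sphere_roi(mask, radius_vox=3.0)
    truth = synthgen.GroundTruth("self_importance", config.effect, roi,
                                 seed=seed)
    state.update(ratings=ratings, mask=mask, truth=truth)

    ratings_path = out / "ratings.csv"
    ratings.ratings.to_csv(ratings_path, index=False)
    items_path = out / "items.csv"
    ratings.items.to_csv(items_path, index=False)
    mask_path = out / "mask.nii.gz"
    write_mask(mask, mask_path)
    truth_path = out / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"encoding_dimension": truth.encoding_dimension,
                   "effect": truth.effect,
                   "roi_voxels": int(roi.sum()), "seed": seed}, fh, indent=2)
    return {"ratings": str(ratings_path), "items": str(items_path),
            "mask": str(mask_path), "ground_truth": str(truth_path)}


def stage_select_stimuli(config: RunConfig, state: dict, out: Path) -> dict:
    seed = config.stage_seed("select-stimuli")
    ratings: synthgen.RatingTable = state["ratings"]
    chosen: dict = {}
    records = []
    for i, pid in enumerate(ratings.participants):
        wide = ratings.wide(pid)
        res = stimselect.select_stimulus_set(
            wide, k=config.n_items, n_iter=300, seed=seed + i)
        chosen[pid] = res.chosen_items
        records.append({"participant_id": int(pid), **res.to_dict()})
    state["chosen"] = chosen
    path = out / "stimulus_selection.json"
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
    return {"selection": str(path),
            "mean_r_highest": float(np.mean([r["r_highest"] for r in records]))}


def stage_glm(config: RunConfig, state: dict, out: Path) -> dict:
    """Generate per-item patterns for every participant and, for the first
    participant, demonstrate the full time-series route (BOLD simulation
    followed by the item-wise GLM)."""
    seed = config.stage_seed("glm")
    ratings: synthgen.RatingTable = state["ratings"]
    mask = state["mask"]
    truth = state["truth"]
    tasks = ("self", "other") if config.experiment == 2 else ("self", "word")

    cohort = []
    for i, pid in enumerate(ratings.participants):
        sub = ratings.subset_items(state["chosen"][pid])
        cohort.append(synthgen.generate_item_patterns(
            sub, mask, truth, noise_sd=config.noise_sd,
            n_runs=config.n_runs, tasks=tasks,
            participant_id=pid, seed=seed + i))
    state["cohort"] = cohort

    artifacts: dict = {"n_participants": len(cohort)}
    if config.run_glm_demo:
        series, events = synthgen.generate_timeseries(
            cohort[0], seed=seed, noise_sd=config.noise_sd)
        runs = [(series[(task, run)],
                 events[(events["task"] == task) & (events["run"] == run)])
                for task in tasks for run in range(1, config.n_runs + 1)]
        tmaps = firstlevel.itemwise_tmaps(runs, mask, path="rsa")
        n_maps = tmaps.data.shape[0] * tmaps.data.shape[2]
        tvol = np.full(mask.shape, np.nan)
        tvol[mask.data] = tmaps.data[0, 0, 0]
        tmap_path = out / "demo_item_tmap.nii.gz"
        write_volume(VolumeGrid(tvol, mask.affine), tmap_path)
        artifacts.update(n_item_tmaps_participant1=int(n_maps),
                         demo_tmap=str(tmap_path))
    return artifacts


def stage_rsa(config: RunConfig, state: dict, out: Path) -> dict:
    ratings: synthgen.RatingTable = state["ratings"]
    mask = state["mask"]
    spec = searchlight.SearchlightSpec(
        radius=config.searchlight_radius,
        min_voxels=config.min_searchlight_voxels)
    betas: dict = {}
    vif_rows = []
    beta_dir = out / "betas"
    n_files = 0
    for pats in state["cohort"]:
        pid = pats.participant_id
        sub = ratings.subset_items(state["chosen"][pid])
        rsms = modelrsm.model_rsms_for_participant(sub, pid)
        preds = modelrsm.standardize_predictors(rsms)
        bm = searchlight.run_searchlight(pats, preds, mask, spec)
        betas[pid] = bm
        for lab, v in zip(preds.labels, searchlight.vif(preds)):
            vif_rows.append({"participant_id": pid, "predictor": lab,
                             "vif": float(v)})
        for (task, lab), vol in bm.maps.items():
            write_volume(VolumeGrid(vol, mask.affine),
                         beta_dir / f"sub-{pid}_task-{task}_pred-{lab}.nii.gz")
            n_files += 1
    state["betas"] = betas
    vif_path = out / "vif.csv"
    pd.DataFrame(vif_rows).to_csv(vif_path, index=False)
    per_participant = len(next(iter(betas.values())).maps)
    return {"beta_volumes_written": n_files,
            "beta_maps_per_participant": per_participant,
            "vif_table": str(vif_path)}


def _smoothed_maps(state, config, task, predictor):
    mask = state["mask"]
    out = []
    for pid, bm in state["betas"].items():
        vol = VolumeGrid(bm.maps[(task, predictor)], mask.affine)
        out.append(groupinfer.smooth_volume(
            vol, config.smooth_fwhm_mm, mask).data)
    return out


def stage_group(config: RunConfig, state: dict, out: Path) -> dict:
    seed = config.stage_seed("group")
    mask = state["mask"]
    truth = state["truth"]
    spec = groupinfer.GroupTestSpec(
        n_permutations=config.n_permutations, voxel_p=config.voxel_p,
        cluster_alpha=config.cluster_alpha,
        smooth_fwhm_mm=config.smooth_fwhm_mm, seed=seed)
    tasks = next(iter(state["betas"].values())).tasks
    results = {}
    tables = []
    for task in tasks:
        maps = _smoothed_maps(state, config, task, truth.encoding_dimension)
        res = groupinfer.signflip_cluster_test(maps, spec, mask)
        results[task] = res
        tab = res.clusters.copy()
        tab.insert(0, "task", task)
        tables.append(tab)
    state["group"] = results

    signal_task = tasks[0]
    sig = results[signal_task].significant_mask()
    overlap = None
    if sig.any():
        ov = groupinfer.overlap_stats(sig, truth.roi)
        overlap = {"intersection": ov.intersection, "union": ov.union,
                   "jaccard": ov.jaccard}
    cluster_path = out / "group_clusters.csv"
    non_empty = [t for t in tables if len(t)]
    (pd.concat(non_empty, ignore_index=True) if non_empty
     else tables[0]).to_csv(cluster_path, index=False)
    return {"clusters": str(cluster_path),
            "significant_in_signal_task": bool(results[signal_task].any_significant),
            "roi_overlap": overlap}


def stage_mvpa(config: RunConfig, state: dict, out: Path) -> dict:
    seed = config.stage_seed("mvpa")
    mask = state["mask"]
    ratings: synthgen.RatingTable = state["ratings"]
    truth = state["truth"]
    dims = _dimensions(config)
    friend_dim = "friend_importance" if "friend_importance" in dims \
        else "self_importance"
    tasks = next(iter(state["betas"].values())).tasks
    spec = groupinfer.GroupTestSpec(
        n_permutations=max(100, config.n_permutations // 2),
        voxel_p=config.voxel_p, cluster_alpha=config.cluster_alpha,
        smooth_fwhm_mm=config.smooth_fwhm_mm, seed=seed)

    # full-group peak on the self-task encoding-dimension beta maps
    enc = truth.encoding_dimension
    all_maps = _smoothed_maps(state, config, tasks[0], enc)
    full = groupinfer.signflip_cluster_test(all_maps, spec, mask)
    coords = mask.coords()
    t_in = full.t_volume[tuple(coords.T)]
    group_peak = tuple(coords[int(np.nanargmax(t_in))])

    cv_rows, cons_rows = [], []
    for p_idx, pats in enumerate(state["cohort"]):
        pid = pats.participant_id
        wide = ratings.subset_items(state["chosen"][pid]).wide(pid)
        bins = mvpa.tertile_bins(wide["self_importance"], wide[friend_dim])
        roi = mvpa.lopo_roi(p_idx, all_maps, mask, group_peak, spec)
        flat_roi_idx = roi.voxel_indices
        vox_lookup = np.full(mask.shape, -1, dtype=np.int64)
        vox_lookup[mask.data] = np.arange(mask.n_voxels)
        roi_cols = vox_lookup[tuple(flat_roi_idx.T)]

        cond_runs = {}
        for task, lv_series in ((tasks[0], bins.self_levels),
                                (tasks[1], bins.friend_levels)):
            t_idx = pats.task_index(task)
            for level in mvpa.LEVELS:
                items = np.isin(pats.item_ids,
                                lv_series.index[lv_series == level])
                if items.sum() == 0:
                    continue
                cond_runs[(task, level)] = \
                    pats.data[t_idx][:, items][:, :, roi_cols].mean(axis=1)
        for level in mvpa.LEVELS:
            key_a, key_b = (tasks[0], level), (tasks[1], level)
            if key_a not in cond_runs or key_b not in cond_runs:
                continue
            cv = mvpa.leave_one_pair_out_cv(
                cond_runs[key_a], cond_runs[key_b], level=level)
            p, sig = mvpa.permutation_pvalue(
                cond_runs[key_a], cond_runs[key_b], cv.mean_accuracy_pct,
                n_perm=config.mvpa_n_permutations, seed=seed + p_idx)
            cv_rows.append({"participant_id": pid, "comparison": level,
                            "accuracy_pct": cv.mean_accuracy_pct,
                            "p_perm": p, "significant_bonferroni": sig})
        cons = mvpa.within_condition_consistency(cond_runs)
        cons.insert(0, "participant_id", pid)
        cons_rows.append(cons)

    cv_path = out / "mvpa_cv.csv"
    pd.DataFrame(cv_rows).to_csv(cv_path, index=False)
    cons_table = pd.concat(cons_rows, ignore_index=True)
    cons_path = out / "consistency.csv"
    cons_table.to_csv(cons_path, index=False)
    artifacts = {"cv_results": str(cv_path), "consistency": str(cons_path)}
    if cons_table["participant_id"].nunique() >= 3 \
            and cons_table.groupby("participant_id").size().nunique() == 1 \
            and cons_table.groupby("participant_id").size().iloc[0] == 6:
        anova = mvpa.consistency_anova(cons_table)
        anova_path = out / "consistency_anova.csv"
        anova.to_csv(anova_path)
        artifacts["anova"] = str(anova_path)
    return artifacts


def stage_power(config: RunConfig, state: dict, out: Path) -> dict:
    seed = config.stage_seed("power")
    mask = state["mask"]
    truth = state["truth"]
    tasks = next(iter(state["betas"].values())).tasks
    pilot = _smoothed_maps(state, config, tasks[0], truth.encoding_dimension)
    spec = groupinfer.GroupTestSpec(
        n_permutations=max(100, config.n_permutations // 2),
        voxel_p=config.voxel_p, cluster_alpha=config.cluster_alpha,
        smooth_fwhm_mm=config.smooth_fwhm_mm, seed=seed)
    logger.info("bootstrap power with %d permutations per replicate",
                spec.n_permutations)
    est = groupinfer.bootstrap_power(
        pilot, config.power_n_target, config.power_n_boot, spec, mask,
        seed=seed)
    path = out / "power.json"
    with open(path, "w") as fh:
        json.dump({"n_target": est.n_target, "n_boot": est.n_boot,
                   "power": est.power, "seed": est.seed}, fh, indent=2)
    return {"power": str(path), "estimated_power": est.power}
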