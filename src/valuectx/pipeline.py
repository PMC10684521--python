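"""End-to-end orchestration of the analysis stages."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, encoding, io, statespace, synth, tfce

logger = logging.getLogger(__name__)


def assign_ap_subregion(
    contacts: pd.DataFrame, y_threshold: float = 35.0
) -> pd.DataFrame:
    """Split medial/central orbitofrontal contacts at an MNI y boundary.

    A contact is anterior iff its MNI y coordinate is strictly greater
    than ``y_threshold`` (a contact exactly at the boundary is
    posterior); the flag applies to medial and central OFC contacts
    only, all others get an empty label.
    """
    out = contacts.copy()
    ofc = out["roi"].isin(["OFC-medial", "OFC-central"])
    ap = np.where(out["y"] > y_threshold, "anterior", "posterior")
    out["ap"] = np.where(ofc, ap, "")
    return out


def _stage(log: list, name: str, **info) -> None:
    record = {"stage": name, **info}
    log.append(record)
    logger.info("stage %s: %s", name, info)


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Run synth/load -> behavior -> encoding -> TFCE -> state space.

    Deterministic for a fixed config (all permutation seeds derive from
    ``config.seed``); every stage's tidy outputs are written under
    ``config.outdir`` together with a provenance log (config hash,
    seeds, stage records).  A stage failure raises with the stage name;
    outputs already written are kept.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list = []
    root = np.random.SeedSequence(config.seed)
    seed_group, seed_contact, seed_boot = (
        int(s) for s in root.generate_state(3) >> np.uint32(1)
    )
    results: dict = {"config_hash": config.content_hash()}

    try:
        if config.trials_csv:
            trials = io.read_trials(config.trials_csv)
            contacts = io.read_contacts(config.contacts_tsv)
            power, truth = io.load_power(config.power_h5)
            dataset = synth.SynthDataset(
                trials=trials, contacts=contacts, power=power,
                truth=truth if truth is not None else pd.DataFrame(),
                config=None,
            )
        else:
            synth_cfg = synth.SynthConfig(**{"seed": config.seed, **config.synth})
            dataset = synth.generate_dataset(synth_cfg)
        io.write_trials(dataset.trials, outdir / "trials.csv")
        io.write_contacts(dataset.contacts, outdir / "contacts.tsv")
        _stage(log, "data", n_trials=len(dataset.trials),
               n_contacts=len(dataset.contacts))
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc

    try:
        trials = behavior.exclude_rt_outliers(dataset.trials)
        prev = behavior.regress_all_subjects(trials, "previous", lag=1)
        rt_reg = behavior.regress_all_subjects(trials, "rt")
        t_prev, p_prev = behavior.group_ttest(prev["coefficient"].to_numpy())
        prev.to_csv(outdir / "behavior_previous_bid.tsv", sep="\t", index=False)
        rt_reg.to_csv(outdir / "behavior_rt.tsv", sep="\t", index=False)
        results["behavior"] = {
            "group_t_previous": t_prev,
            "group_p_previous": p_prev,
            "n_excluded": int((~trials["valid"]).sum()),
        }
        _stage(log, "behavior", **results["behavior"])
    except Exception as exc:
        raise RuntimeError(f"stage 'behavior' failed: {exc}") from exc

    try:
        band_power = dataset.power[config.band]
        spec = encoding.DesignSpec(variant=config.glm_variant)
        glm = encoding.fit_glm(band_power, trials, dataset.contacts, spec)
        tidy = encoding.result_to_frame(glm, band_power.time)
        tidy.to_csv(outdir / "glm.tsv", sep="\t", index=False)
        results["glm"] = {
            "n_usable_contacts": int(glm.usable.sum()),
            "regressors": glm.names,
        }
        _stage(log, "glm", **results["glm"])
    except Exception as exc:
        raise RuntimeError(f"stage 'glm' failed: {exc}") from exc

    try:
        params = tfce.TFCEParams(
            E=config.tfce_E, H=config.tfce_H, n_levels=config.tfce_n_levels
        )
        clusters = []
        roi_groups = {"all": dataset.contacts["contact"].tolist()}
        for roi, grp in dataset.contacts.groupby("roi"):
            roi_groups[roi] = grp["contact"].tolist()
        cid_row = {c: i for i, c in enumerate(glm.contact_ids)}
        for roi, cids in roi_groups.items():
            rows = [cid_row[c] for c in cids if glm.usable[cid_row[c]]]
            if len(rows) < 4:
                continue
            for reg in ("sv_current", "sv_previous"):
                betas = glm.coef(reg)[rows]
                res = tfce.group_permutation(
                    betas, params, n_perm=config.n_perm_group,
                    seed=seed_group, alpha=config.alpha,
                )
                summ = tfce.summarize_clusters(
                    res.mask, res.tfce, res.max_stats, res.min_stats,
                    band_power.time, regressor=reg,
                )
                summ.insert(0, "roi", roi)
                clusters.append(summ)
        clusters = [c for c in clusters if len(c)]
        cluster_table = (
            pd.concat(clusters, ignore_index=True)
            if clusters
            else pd.DataFrame()
        )
        cluster_table.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        results["tfce"] = {"n_clusters": int(len(cluster_table))}
        _stage(log, "tfce", **results["tfce"])
    except Exception as exc:
        raise RuntimeError(f"stage 'tfce' failed: {exc}") from exc

    try:
        sym = tfce.skewness_symmetry_test(
            glm.coef("sv_current")[glm.usable], n_boot=1000, seed=seed_boot
        )
        results["symmetry"] = {
            "frac_symmetric_timepoints": float(np.mean(sym.symmetric)),
        }
        _stage(log, "symmetry", **results["symmetry"])
    except Exception as exc:
        raise RuntimeError(f"stage 'symmetry' failed: {exc}") from exc

    try:
        pop = statespace.prepare_population(
            band_power, trials, dataset.contacts, smoothing_ms=config.smoothing_ms
        )
        pca_traj = statespace.pca_trajectories(pop)
        D = statespace.denoising_matrix(pop, n_pc=min(config.n_pc, len(pop.contact_ids)))
        axes = statespace.regression_axes(glm, D)
        reg_traj = statespace.project_conditions(pop, axes)
        pca_traj.to_frame(band_power.time).to_csv(
            outdir / "trajectories_pca.tsv", sep="\t", index=False
        )
        reg_traj.to_frame(band_power.time).to_csv(
            outdir / "trajectories_regression.tsv", sep="\t", index=False
        )
        results["statespace"] = {
            "explained_variance_pc12": [
                float(v) for v in pca_traj.explained_variance_ratio[:2]
            ],
            "t_max": [int(i) for i in axes.t_max],
        }
        _stage(log, "statespace", **results["statespace"])
    except Exception as exc:
        raise RuntimeError(f"stage 'statespace' failed: {exc}") from exc

    provenance = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seeds": {
            "group": seed_group,
            "contact": seed_contact,
            "bootstrap": seed_boot,
        },
        "stages": log,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    results["outdir"] = str(outdir)
    return results
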