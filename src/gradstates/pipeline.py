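"""End-to-end orchestration: simulate -> prep -> dFC -> gradients -> stats -> classify.

A run is fully determined by a :class:`RunConfig` (serialisable to YAML) and
its master seed.  Every stage logs one structured line with its parameters and
timing; every output file is listed in the machine-readable report with a
content hash.  When the inputs are simulated, the report also contains
ground-truth-vs-recovered comparisons (state-label agreement, planted-edge and
planted-region recovery).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import classification as clf_mod
from . import dfc_states as dfc
from . import functional_gradients as fg
from . import group_stats as gs
from . import synthetic_cohort as syn
from ._utils import derive_seed
from .signal_prep import bandpass, detrend, load_cohort

logger = logging.getLogger("gradstates.pipeline")


@dataclass
class RunConfig:
    """All pipeline parameters, with the study's stated values as defaults."""

    # cohort
    n_patients: int = 34
    n_controls: int = 32
    T: int = 200
    TR: float = 2.0
    P: int = 90
    n_states: int = 4
    stickiness: float = 0.9
    effect_z_shift: float = 0.5  # 0 -> null cohort
    # optional real-data input (overrides simulation)
    manifest: str | None = None
    timeseries_dir: str | None = None
    # prep
    detrend_order: int = 1
    low_hz: float = 0.01
    high_hz: float = 0.08
    # dFC
    window_length: int = 50
    window_step: int = 1
    k: int | str = "auto"  # "auto" -> SSE-elbow selection over k_range
    k_range: tuple[int, int] = (2, 8)
    n_init: int = 20
    # gradients
    networks: tuple[str, ...] = ("default_mode", "somatomotor")
    n_voxels: int = 150
    n_parcels: int = 400
    density: float = 0.10
    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 10
    n_dispersion_components: int = 2
    gradient_shift: float = 0.15  # latent offset planted per network; 0 -> null
    # stats
    fdr_q: float = 0.05
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    n_perm: int = 1000
    # classification
    n_gradient_features: int = 12
    n_dfc_features: int = 12
    classifiers: tuple[str, ...] = clf_mod.CLASSIFIERS
    cv_schemes: tuple[str, ...] = ("loocv", "5fold")
    # run
    seed: int = 0
    outdir: str = "gradstates_run"
    verbosity: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("k_range", "networks", "classifiers", "cv_schemes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str, t0: float, **params) -> None:
    logger.info("stage=%s elapsed=%.1fs %s", name, time.time() - t0,
                " ".join(f"{k}={v}" for k, v in params.items()))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order, write all artefacts, return the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.getLogger("gradstates").setLevel(config.verbosity)
    config.to_yaml(out / "config.yaml")
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    files: dict[str, str] = {"config.yaml": ""}
    stage = "simulate"
    try:
        # ---- simulate or load -------------------------------------------
        t0 = time.time()
        truth_states = None
        effect_edges: tuple = ()
        if config.manifest:
            subjects, clinical = load_cohort(config.manifest,
                                             config.timeseries_dir or ".", config.TR)
            region_ids = subjects[0].region_ids
        else:
            spec = syn.CohortSpec(
                n_patients=config.n_patients, n_controls=config.n_controls,
                T=config.T, TR=config.TR, P=config.P, n_states=config.n_states,
                stickiness=config.stickiness,
                effect_edges=(None if config.effect_z_shift else ()),
                low_hz=config.low_hz, high_hz=config.high_hz,
                seed=derive_seed(config.seed, 10),
            )
            if config.effect_z_shift and spec.effect_edges is None:
                spec = dataclasses.replace(
                    spec, effect_edges=syn.default_effect_edges(
                        spec, z_shift=config.effect_z_shift))
            cohort = syn.generate_cohort(spec)
            subjects, clinical = cohort.subjects, cohort.clinical
            truth_states = cohort.true_states
            effect_edges = cohort.effect_edges
            region_ids = subjects[0].region_ids
            syn.write_cohort(out / "cohort", cohort)
        groups = np.array([s.group for s in subjects])
        sids = [s.subject_id for s in subjects]
        _stage(stage, t0, n_subjects=len(subjects), simulated=not config.manifest)

        # ---- prep -------------------------------------------------------
        stage, t0 = "prep", time.time()
        prepped = [bandpass(detrend(s, config.detrend_order),
                            config.low_hz, config.high_hz) for s in subjects]
        _stage(stage, t0, detrend=config.detrend_order,
               band=(config.low_hz, config.high_hz))

        # ---- dFC --------------------------------------------------------
        stage, t0 = "dfc", time.time()
        stacks = [dfc.sliding_window_fc(s, config.window_length, config.window_step)
                  for s in prepped]
        enames = dfc.edge_names(region_ids)
        variability = pd.DataFrame([dfc.dfc_variability(st) for st in stacks],
                                   index=sids, columns=enames)
        mean_z = pd.DataFrame([dfc.mean_dfc(st) for st in stacks],
                              index=sids, columns=enames)
        selection = None
        if config.k == "auto":
            selection = dfc.select_k(
                stacks, range(config.k_range[0], config.k_range[1] + 1),
                n_init=config.n_init, seed=derive_seed(config.seed, 20))
            model = selection.models[selection.chosen_k]
            selection.table.to_csv(out / "k_selection.csv", index=False)
            files["k_selection.csv"] = ""
        else:
            model = dfc.fit_states(stacks, int(config.k), n_init=config.n_init,
                                   seed=derive_seed(config.seed, 20))
        dynamics = dfc.state_dynamics(model)
        variability.to_csv(out / "dfc_variability.csv")
        dynamics.to_csv(out / "state_dynamics.csv", index=False)
        files["dfc_variability.csv"] = files["state_dynamics.csv"] = ""
        with open(out / "state_model.json", "w") as fh:
            json.dump({"k": model.k, "sse": model.sse,
                       "centroids": np.round(model.centroids, 6).tolist()}, fh)
        files["state_model.json"] = ""
        report["stages"]["dfc"] = {
            "n_windows": int(stacks[0].n_windows),
            "chosen_k": int(model.k),
            "selection": (selection.table.to_dict("records")
                          if selection is not None else None),
        }
        _stage(stage, t0, W=stacks[0].n_windows, k=model.k)

        # ---- gradients --------------------------------------------------
        stage, t0 = "gradients", time.time()
        grad_scores_parts, cluster_parts, region_label_parts = [], [], []
        dispersion_rows = []
        offset = 0
        for net_idx, net in enumerate(config.networks):
            shift_idx = ()
            gspec = syn.GradientManifoldSpec(
                n_voxels=config.n_voxels, n_parcels=config.n_parcels,
                seed=derive_seed(config.seed, 30, net_idx))
            if config.gradient_shift:
                rlab = gspec.region_labels()
                target_region = (2 * net_idx + 1) % gspec.n_regions
                shift_idx = tuple(int(i) for i in np.flatnonzero(rlab == target_region))
                gspec = dataclasses.replace(
                    gspec, group_shift_regions=((shift_idx, config.gradient_shift),))
            fcs = [syn.simulate_network_voxels(
                gspec, s.group, derive_seed(config.seed, 31, net_idx, i))[0]
                for i, s in enumerate(subjects)]
            template, aligned = fg.align_cohort(
                fcs, config.density, config.alpha, config.diffusion_time,
                config.n_components)
            g1 = np.stack([e.components[:, 0] for e in aligned])
            region_labels = np.array(
                [f"{net}:reg{r}" for r in gspec.region_labels()], dtype=object)
            grad_scores_parts.append(pd.DataFrame(
                g1, index=sids,
                columns=[f"{net}:v{i:03d}" for i in range(gspec.n_voxels)]))
            region_label_parts.append(region_labels)
            for sid, e in zip(sids, aligned):
                disp = fg.gradient_dispersion(e, region_labels,
                                              config.n_dispersion_components)
                for _, row in disp.centroid_distances.iterrows():
                    dispersion_rows.append({
                        "subject_id": sid, "network": net,
                        "region_a": row["region_a"], "region_b": row["region_b"],
                        "distance": row["distance"]})
            report["stages"].setdefault("gradients", {})[net] = {
                "eigenvalues": np.round(template.eigenvalues, 6).tolist(),
                "planted_voxels": list(shift_idx),
                "voxel_offset": offset,
            }
            offset += gspec.n_voxels
        gradient_scores = pd.concat(grad_scores_parts, axis=1)
        region_labels_all = np.concatenate(region_label_parts)
        dispersion = pd.DataFrame(dispersion_rows)
        gradient_scores.to_csv(out / "gradient_scores.csv")
        dispersion.to_csv(out / "gradient_dispersion.csv", index=False)
        files["gradient_scores.csv"] = files["gradient_dispersion.csv"] = ""
        _stage(stage, t0, networks=config.networks)

        # ---- stats ------------------------------------------------------
        stage, t0 = "stats", time.time()
        covs = clinical.set_index("subject_id").loc[sids, ["age", "sex"]]
        edge_stats = gs.adjusted_group_test(mean_z.to_numpy(), groups, covs, enames)
        edge_stats["significant"] = gs.fdr_correct(edge_stats["p"], config.fdr_q)
        sd_stats = gs.adjusted_group_test(variability.to_numpy(), groups, covs, enames)
        sd_stats["significant"] = gs.fdr_correct(sd_stats["p"], config.fdr_q)
        clusters = gs.cluster_correct_permutation(
            gradient_scores.to_numpy(), groups, covs, region_labels_all,
            config.voxel_p, config.cluster_p, config.n_perm,
            derive_seed(config.seed, 40))
        dyn_cols = [c for c in dynamics.columns if c != "subject_id"]
        dyn_stats = gs.adjusted_group_test(
            dynamics[dyn_cols].to_numpy(), groups, covs, dyn_cols)
        dyn_stats["significant"] = gs.fdr_correct(
            dyn_stats["p"].fillna(1.0), config.fdr_q)
        corr = gs.clinical_correlations(
            _cluster_means(gradient_scores, clusters.clusters), clinical)
        edge_stats.to_csv(out / "edge_stats.csv", index=False)
        sd_stats.to_csv(out / "sd_stats.csv", index=False)
        clusters.clusters.to_csv(out / "gradient_clusters.csv", index=False)
        dyn_stats.to_csv(out / "dynamics_stats.csv", index=False)
        corr.to_csv(out / "clinical_correlations.csv", index=False)
        for f in ("edge_stats.csv", "sd_stats.csv", "gradient_clusters.csv",
                  "dynamics_stats.csv", "clinical_correlations.csv"):
            files[f] = ""
        report["stages"]["stats"] = {
            "significant_edges": edge_stats.loc[edge_stats["significant"],
                                                "feature"].tolist(),
            "significant_sd_edges": sd_stats.loc[sd_stats["significant"],
                                                 "feature"].tolist(),
            "significant_clusters": clusters.clusters[
                clusters.clusters["significant"]].to_dict("records"),
            "significant_dynamics": dyn_stats.loc[dyn_stats["significant"],
                                                  "feature"].tolist(),
        }
        _stage(stage, t0, edges=int(edge_stats["significant"].sum()),
               clusters=len(clusters.clusters))

        # ---- classify ---------------------------------------------------
        stage, t0 = "classify", time.time()
        labels = pd.Series(groups, index=pd.Index(sids, name="subject_id"))
        features = clf_mod.assemble_features(
            gradient_scores, clusters.clusters, mean_z, edge_stats, labels,
            config.n_gradient_features, config.n_dfc_features)
        cv_results = clf_mod.evaluate_all(
            features, config.cv_schemes, config.classifiers,
            derive_seed(config.seed, 50))
        ranking = clf_mod.rank_features(features, derive_seed(config.seed, 51))
        ranking.to_csv(out / "feature_ranking.csv", index=False)
        files["feature_ranking.csv"] = ""
        report["stages"]["classification"] = {
            f"{c}|{s}": {k: (round(v, 6) if np.isfinite(v) else None)
                         for k, v in r.metrics.items()}
            for (c, s), r in cv_results.items()
        }
        report["stages"]["classification"]["top_features"] = (
            ranking["feature"].head(5).tolist())
        _stage(stage, t0, n_features=features.data.shape[1])

        # ---- truth comparison -------------------------------------------
        if truth_states is not None:
            true_lab = np.concatenate([
                dfc.window_majority_labels(truth_states[sid], config.window_length,
                                           config.window_step) for sid in sids])
            rec_lab = np.concatenate([model.labels[sid] for sid in sids])
            planted = [enames[_edge_pos(i, j, len(region_ids))]
                       for i, j, _ in effect_edges]
            recovered = set(report["stages"]["stats"]["significant_edges"])
            planted_vox = {
                net: set(report["stages"]["gradients"][net]["planted_voxels"])
                for net in config.networks}
            cluster_hits = {}
            for net in config.networks:
                off = report["stages"]["gradients"][net]["voxel_offset"]
                hits = False
                for rec in report["stages"]["stats"]["significant_clusters"]:
                    idx = set(range(rec["start"] - off,
                                    rec["start"] - off + rec["size"]))
                    if idx & planted_vox[net]:
                        hits = True
                cluster_hits[net] = hits
            report["truth_comparison"] = {
                "state_label_ari": round(float(
                    adjusted_rand_score(true_lab, rec_lab)), 6),
                "planted_edges": planted,
                "planted_edges_recovered": sorted(set(planted) & recovered),
                "edge_recovery_sensitivity": (
                    round(len(set(planted) & recovered) / len(planted), 6)
                    if planted else None),
                "planted_cluster_recovered": cluster_hits,
            }
    except Exception as err:  # noqa: BLE001 - abort with stage context
        report["error"] = {"stage": stage, "message": str(err)}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    # ---- report ---------------------------------------------------------
    for name in list(files):
        files[name] = _sha256(out / name)
    report["files"] = files
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _edge_pos(i: int, j: int, P: int) -> int:
    """Position of edge (i, j) in the strict upper-triangle vectorisation."""
    i, j = min(i, j), max(i, j)
    return i * P - i * (i + 1) // 2 + (j - i - 1)


def _cluster_means(gradient_scores: pd.DataFrame,
                   clusters: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for _, row in clusters.iterrows():
        idx = np.arange(int(row["start"]), int(row["start"]) + int(row["size"]))
        cols[f"cluster{int(row['cluster_id'])}:{row['region']}"] = (
            gradient_scores.iloc[:, idx].mean(axis=1))
    if not cols:
        return pd.DataFrame(index=gradient_scores.index)
    return pd.DataFrame(cols)
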