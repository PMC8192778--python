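"""End-to-end analysis pipeline.

Per circuit (cognitive, motor): tapered sliding-window connectivity per
subject -> group-wise brain-state clustering -> per-subject NII summaries
-> group comparison (raw and confound-adjusted).  If an item table is
supplied, ADI-R factor scores are derived and brain-behavior association /
cross-validated prediction is run within the ASD group.  All randomness is
driven by ``config.seed``; two runs with the same inputs and seed produce
identical outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import factors as factors_mod
from .behavior import specificity_report
from .exceptions import InputError, PipelineStageError
from .inference import confound_adjusted_test, two_sample_test
from .io import PipelineConfig, manifest_frame, read_items, read_manifest, read_network_timeseries
from .nii import COGNITIVE_CIRCUIT, MOTOR_CIRCUIT, compute_subject_features, features_table
from .states import assign_states, fit_group_states, vectorize_connectivity
from .windows import make_taper, sliding_window_connectivity

logger = logging.getLogger("rrbdyn")

CIRCUITS = {"cognitive": COGNITIVE_CIRCUIT, "motor": MOTOR_CIRCUIT}


def _subset_connectivity(wc, networks):
    """Restrict a WindowedConnectivity to the given channels."""
    from .windows import WindowedConnectivity

    idx = [wc.network_names.index(n) for n in networks]
    return WindowedConnectivity(
        subject_id=wc.subject_id, network_names=tuple(networks),
        window_onsets=wc.window_onsets,
        matrices=wc.matrices[np.ix_(np.arange(wc.n_windows), idx, idx)],
        kernel=wc.kernel,
    )


def compute_connectivity(timeseries, config: PipelineConfig):
    """Windowed correlation matrices for every subject (all six networks)."""
    out = []
    for ts in timeseries:
        W = config.window_samples(ts.tr_seconds)
        kernel = make_taper(W, config.window_shape, config.decay_rate)
        out.append(sliding_window_connectivity(ts, kernel, config.window_step))
    return out


def analyze_circuit(conns, groups: pd.Series, circuit_name: str,
                    config: PipelineConfig):
    """States + NII features for one circuit; returns (models, features_df)."""
    circuit = CIRCUITS[circuit_name]
    networks = circuit.networks()
    sub = [_subset_connectivity(wc, networks) for wc in conns]
    by_subject = {wc.subject_id: wc for wc in sub}
    aggregation = (config.cnii_aggregation if circuit_name == "cognitive"
                   else config.mnii_aggregation)
    models, feats = {}, []
    for gi, group in enumerate(("ASD", "TD")):
        ids = groups.index[groups == group]
        gconns = [by_subject[s] for s in ids]
        feat = vectorize_connectivity(gconns, use_fisher_z=config.fisher_z)
        model = fit_group_states(
            feat, k_range=tuple(config.k_range), n_restarts=config.n_restarts,
            seed=(config.seed + 101 * gi + (7 if circuit_name == "motor" else 0)),
            group=group, silhouette_subsample=config.silhouette_subsample)
        models[group] = model
        logger.info("circuit=%s group=%s: k=%d silhouette=%.3f (n=%d windows)",
                    circuit_name, group, model.k, model.silhouette, len(feat))
        for wc in gconns:
            labels = model.labels.loc[wc.subject_id].to_numpy()
            feats.append(compute_subject_features(wc, circuit, labels=labels,
                                                  aggregation=aggregation))
    return models, features_table(feats)


def compare_groups(features: pd.DataFrame, manifest: pd.DataFrame,
                   config: PipelineConfig) -> dict:
    """Raw + adjusted group tests for mean and SD of each circuit's NII."""
    man = manifest.set_index("subject_id")
    out = {}
    for circuit in ("cognitive", "motor"):
        block = features[features["circuit"] == circuit].set_index("subject_id")
        for stat in ("mean_nii", "sd_nii"):
            name = f"{circuit}_{stat}"
            vals = block[stat]
            ok = vals.notna()
            n_dropped = int((~ok).sum())
            if n_dropped:
                logger.info("%s: dropping %d subject(s) with undefined SD",
                            name, n_dropped)
            sub_man = man.loc[vals.index[ok]].reset_index()
            v = vals[ok].to_numpy(dtype=float)
            a = v[(sub_man["group"] == "ASD").to_numpy()]
            b = v[(sub_man["group"] == "TD").to_numpy()]
            unadj = two_sample_test(a, b, feature=name, welch=config.welch)
            adj = confound_adjusted_test(v, sub_man, feature=name)
            out[name] = {"unadjusted": unadj.to_dict(),
                         "adjusted": adj.to_dict(),
                         "n_dropped_missing_sd": n_dropped}
    return out


def behavior_analysis(features: pd.DataFrame, scores: pd.DataFrame,
                      config: PipelineConfig) -> dict:
    """Specificity table of circuit features vs CI/IS/RM in ASD subjects."""
    wide = (features.pivot_table(index="subject_id", columns="circuit",
                                 values=["mean_nii", "sd_nii"]))
    X = pd.DataFrame({
        "cnii_mean": wide[("mean_nii", "cognitive")],
        "cnii_sd": wide[("sd_nii", "cognitive")],
        "mnii_mean": wide[("mean_nii", "motor")],
    })
    common = X.index.intersection(scores.index)
    X = X.loc[common].dropna()
    report = specificity_report(X, scores.loc[X.index],
                                n_permutations=config.n_permutations,
                                cv_folds=config.cv_folds, seed=config.seed)
    return {"n_subjects": int(len(X)),
            "associations": report.to_dict(orient="records")}


def run_pipeline(config: PipelineConfig, manifest_path, timeseries_dir,
                 items_path=None, out_dir="rrbdyn_out") -> dict:
    """Run every stage and write the report files.

    Writes ``nii_features.tsv``, ``state_assignments.tsv``,
    ``group_comparison.json`` and (when items are given)
    ``brain_behavior.json`` plus factor tables to ``out_dir``.  On any
    stage failure the partial outputs are removed and a
    :class:`PipelineStageError` naming the stage is raised.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    stage = "read_inputs"
    try:
        records = read_manifest(manifest_path)
        manifest = manifest_frame(records)
        ts_dir = Path(timeseries_dir)
        timeseries = []
        for rec in records:
            f = ts_dir / f"{rec.subject_id}.tsv"
            if not f.exists():
                f = ts_dir / f"{rec.subject_id}.csv"
            if not f.exists():
                raise InputError(f"no time-series file for {rec.subject_id!r}")
            timeseries.append(read_network_timeseries(f, subject_id=rec.subject_id))
        groups = manifest.set_index("subject_id")["group"]
        logger.info("pipeline: seed=%d, %d subjects (%d ASD / %d TD)",
                    config.seed, len(records), (groups == "ASD").sum(),
                    (groups == "TD").sum())

        stage = "connectivity"
        conns = compute_connectivity(timeseries, config)

        stage = "states_and_features"
        all_feats, state_rows, state_meta = [], [], {}
        for circuit in ("cognitive", "motor"):
            models, feats = analyze_circuit(conns, groups, circuit, config)
            feats.insert(1, "group", feats["subject_id"].map(groups))
            all_feats.append(feats)
            for group, model in models.items():
                state_meta[f"{circuit}_{group}"] = {
                    "k": model.k, "silhouette": model.silhouette,
                    "silhouette_by_k": {int(k): v for k, v in
                                        model.silhouette_by_k.items()},
                    "one_state_flag": bool(model.one_state_flag),
                }
                lab = model.labels.reset_index()
                lab.insert(0, "circuit", circuit)
                lab.insert(1, "group", group)
                state_rows.append(lab)
        features = pd.concat(all_feats, ignore_index=True)
        f_feat = out / "nii_features.tsv"
        features.to_csv(f_feat, sep="\t", index=False)
        written.append(f_feat)
        f_states = out / "state_assignments.tsv"
        pd.concat(state_rows, ignore_index=True).to_csv(f_states, sep="\t",
                                                        index=False)
        written.append(f_states)

        stage = "group_comparison"
        comparison = {"states": state_meta,
                      "features": compare_groups(features, manifest, config)}
        f_cmp = out / "group_comparison.json"
        f_cmp.write_text(json.dumps(comparison, indent=2))
        written.append(f_cmp)

        result = {"out_dir": str(out), "files": [str(p) for p in written],
                  "states": state_meta}
        if items_path is not None:
            stage = "rrb_factors"
            items = read_items(items_path)
            recoded = factors_mod.recode_items(items)
            solution = factors_mod.pca_varimax(recoded)
            f_load = out / "factor_loadings.tsv"
            solution.loadings.to_csv(f_load, sep="\t", index_label="item")
            written.append(f_load)
            f_eig = out / "eigenvalues.tsv"
            pd.Series(solution.eigenvalues, name="eigenvalue").to_csv(
                f_eig, sep="\t", index_label="component")
            written.append(f_eig)
            f_scores = out / "factor_scores.tsv"
            solution.scores.to_csv(f_scores, sep="\t", index_label="subject_id")
            written.append(f_scores)

            stage = "brain_behavior"
            wanted = [c for c in ("CI", "IS", "RM")
                      if c in solution.scores.columns]
            if len(wanted) == 3:
                scores = solution.scores[wanted]
                asd_ids = groups.index[groups == "ASD"]
                scores = scores.loc[scores.index.intersection(asd_ids)]
                behavior = behavior_analysis(
                    features[features["subject_id"].isin(scores.index)],
                    scores, config)
            else:
                behavior = {"skipped": "components did not match CI/IS/RM",
                            "labels": list(solution.component_labels)}
            behavior["factor_solution"] = {
                "n_components": solution.n_components,
                "variance_explained_total": solution.total_variance_explained,
                "component_labels": list(solution.component_labels),
            }
            f_beh = out / "brain_behavior.json"
            f_beh.write_text(json.dumps(behavior, indent=2))
            written.append(f_beh)
        result["files"] = [str(p) for p in written]
        return result
    except Exception as exc:  # noqa: BLE001 - cleanup then re-raise with stage
        for p in written:
            try:
                Path(p).unlink()
            except OSError:
                pass
        raise PipelineStageError(stage, exc) from exc
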