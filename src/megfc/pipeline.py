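"""End-to-end driver: simulate -> preprocess -> connectivity -> NBS -> behavior.

``run_pipeline`` executes the whole analysis on a synthetic cohort defined
by a :class:`~megfc.config.PipelineConfig` and writes a deterministic
results bundle (manifests, QC report, baselined connectivity matrices,
NBS component tables, behavioral correlations, network exports and a run
log). Re-running with the same configuration and seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._version import __version__
from .behavior import correlate_with_behavior, generate_behavior_table, network_strength
from .beamform import (
    compute_lcmv_weights,
    orthogonalize_epochs,
    reconstruct_parcel_timeseries,
)
from .config import PipelineConfig
from .connectivity import ConnectivityMatrix, average_and_baseline, build_adjacency
from .io import (
    export_network,
    generic_node_table,
    load_node_table,
    save_array_store,
    seed_indices,
    write_manifest,
    write_run_log,
)
from .nbs import (
    NBSDesign,
    bonferroni_band_correction,
    matrices_to_edges,
    nbs_permutation_test,
    roi_matrix_to_square,
    roi_pairs,
    whole_brain_pairs,
)
from .paradigm import build_paradigm
from .preprocessing import (
    bandpass_filterbank,
    epoch_trials,
    qc_min_trials,
    reject_motion_trials,
    remove_artifact_components,
)
from .simulate import (
    make_artifact_signals,
    make_leadfield,
    project_to_sensors,
    simulate_subject_timeseries,
)

GROUPS = ("ASD", "TD")
TASK_CONDITIONS = ("familiar", "unfamiliar")


class PipelineError(RuntimeError):
    """A stage failure annotated with stage and subject context."""


@dataclass
class PipelineResult:
    """In-memory summary of one pipeline run."""

    outdir: Path
    included_subjects: list[str]
    nbs_table: pd.DataFrame
    behavior_table: pd.DataFrame
    behavior_correlations: pd.DataFrame
    matrices: dict = field(repr=False, default_factory=dict)
    qc: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        if len(self.nbs_table) == 0:
            return self.nbs_table
        return self.nbs_table[self.nbs_table["significant"]]


def _token(s: str) -> int:
    return zlib.crc32(s.encode("utf8")) & 0x7FFFFFFF


def _subject_ids(config: PipelineConfig) -> list[tuple[str, str]]:
    out = []
    for group in GROUPS:
        for k in range(config.simulation.n_subjects_per_group):
            out.append((f"{group.lower()}{k + 1:02d}", group))
    return out


def _simulate_cohort(config: PipelineConfig):
    """Stage 1: manifests plus parcel-level trial data for every subject."""
    sim = config.simulation
    n_rest_trials = max(1, int(2 * config.paradigm.rest_duration_s // sim.trial_duration_s))
    manifests = []
    data: dict[tuple[str, str], np.ndarray] = {}
    for subject, group in _subject_ids(config):
        rng = np.random.default_rng([config.seed, _token("manifest"), _token(subject)])
        manifest = build_paradigm(
            config.paradigm,
            subject=subject,
            group=group,
            rng=rng,
            response_disagreement_rate=config.response_disagreement_rate,
        )
        music = manifest[~manifest["is_rest"]].copy()
        rows = [music]
        for condition in TASK_CONDITIONS:
            idx = music.index[music["condition_response"] == condition]
            n_trials = len(idx)
            if n_trials == 0:
                continue
            try:
                ts, truth = simulate_subject_timeseries(
                    sim, subject, group, condition, n_trials
                )
            except Exception as err:  # pragma: no cover - defensive
                raise PipelineError(
                    f"simulate stage failed for subject {subject} ({condition}): {err}"
                ) from err
            music.loc[idx, "motion_mm"] = truth.motion_mm
            data[(subject, condition)] = ts.data
        ts_rest, truth_rest = simulate_subject_timeseries(
            sim, subject, group, "rest", n_rest_trials
        )
        data[(subject, "rest")] = ts_rest.data
        rest_rows = pd.DataFrame(
            {
                "subject": subject,
                "group": group,
                "run": 0,
                "trial": [1000 + k for k in range(n_rest_trials)],
                "stimulus": "rest",
                "condition_stimulus": "rest",
                "liking": "n/a",
                "condition_response": "rest",
                "duration_s": sim.trial_duration_s,
                "is_rest": True,
                "motion_mm": truth_rest.motion_mm,
            }
        )
        rows.append(rest_rows)
        manifests.append(pd.concat(rows, ignore_index=True))
    return pd.concat(manifests, ignore_index=True), data


def _sensor_roundtrip(config: PipelineConfig, subject: str, data: dict) -> None:
    """Optional stage 2b: forward-project, ICA-clean and beamform back."""
    sim = config.simulation
    rng = np.random.default_rng([config.seed, _token("forward"), _token(subject)])
    p = sim.n_parcels
    leadfield = make_leadfield(sim.sensor_count, p, rng)
    loadings = 2.0 * rng.standard_normal((sim.sensor_count, sim.artifact_components))
    cleaned: dict[str, np.ndarray] = {}
    for condition in TASK_CONDITIONS + ("rest",):
        key = (subject, condition)
        if key not in data:
            continue
        trials = data[key]
        n_trials, _, n = trials.shape
        refs = make_artifact_signals(n_trials, n, sim.sampling_rate_hz,
                                     sim.artifact_components, rng)
        from .simulate import ParcelTimeSeries

        ts = ParcelTimeSeries(trials, sim.sampling_rate_hz, subject=subject,
                              condition=condition)
        sensors, refs = project_to_sensors(
            ts, leadfield, artifact_loadings=loadings, artifact_signals=refs,
            noise_sd=0.05 * sim.noise_sd, rng=rng,
        )
        sensors, _report = remove_artifact_components(sensors, refs)
        cleaned[condition] = sensors
    flat = np.concatenate(
        [np.moveaxis(v, 0, 1).reshape(v.shape[1], -1) for v in cleaned.values()],
        axis=1,
    )
    cov = np.cov(flat)
    weights = compute_lcmv_weights(leadfield, cov, regularization=0.05)
    for condition, sensors in cleaned.items():
        data[(subject, condition)] = reconstruct_parcel_timeseries(weights, sensors)


def _connectivity_stage(config: PipelineConfig, manifest: pd.DataFrame,
                        data: dict, included: list[str], seeds: list[int]):
    """Stages 3-4: filterbank, epoching, adjacency, baselining.

    Returns {(metric, band, mode): {(subject, group, condition): values}}.
    """
    sim = config.simulation
    fs = sim.sampling_rate_hz
    matrices: dict[tuple[str, str, str], dict[tuple[str, str, str], np.ndarray]] = {}
    groups = dict(manifest.groupby("subject")["group"].first())
    for subject in included:
        group = groups[subject]
        # indices of kept trials per condition, mapped into the simulated arrays
        kept: dict[str, np.ndarray] = {}
        sub_rows = manifest[manifest["subject"] == subject]
        for condition in TASK_CONDITIONS + ("rest",):
            if (subject, condition) not in data:
                continue
            rows = sub_rows[sub_rows["condition_response"] == condition]
            order = np.argsort(rows["trial"].to_numpy())
            kept[condition] = rows.iloc[order]["trial_pos"].to_numpy()
        for band in sim.bands:
            # filter kept trials, epoch to 10 s
            per_cond_epochs: dict[str, list[np.ndarray]] = {}
            for condition, trial_pos in kept.items():
                if len(trial_pos) == 0:
                    continue
                trials = data[(subject, condition)][trial_pos]
                try:
                    filtered = bandpass_filterbank(trials, fs, bands=[band])[band.label]
                except Exception as err:
                    raise PipelineError(
                        f"filter stage failed for subject {subject}: {err}"
                    ) from err
                per_cond_epochs[condition] = [
                    epoch_trials(tr, fs, config.epoch_s) for tr in filtered
                ]
            if "rest" not in per_cond_epochs:
                raise PipelineError(f"subject {subject} has no resting data")
            for metric in config.metrics:
                cond_epochs = per_cond_epochs
                if metric == "aec":
                    # one leakage correction per subject and band, all epochs
                    all_eps = [
                        ep for eps in per_cond_epochs.values() for tr in eps for ep in tr
                    ]
                    stacked = np.stack(all_eps)
                    ortho = orthogonalize_epochs(stacked)
                    cond_epochs = {}
                    k = 0
                    for condition, eps in per_cond_epochs.items():
                        out = []
                        for tr in eps:
                            out.append(ortho[k : k + len(tr)])
                            k += len(tr)
                        cond_epochs[condition] = out
                for mode in config.modes:
                    mode_seeds = seeds if mode == "roi" else None
                    per_cond_mats: dict[str, list[ConnectivityMatrix]] = {}
                    for condition, eps in cond_epochs.items():
                        mats = [
                            build_adjacency(
                                tr, metric, sfreq=fs, trim_s=config.edge_trim_s,
                                mode=mode, seeds=mode_seeds,
                                band=band.label, condition=condition, subject=subject,
                            )
                            for tr in eps
                        ]
                        per_cond_mats[condition] = mats
                    store = matrices.setdefault((metric, band.label, mode), {})
                    for condition in TASK_CONDITIONS:
                        if condition not in per_cond_mats:
                            continue
                        baselined = average_and_baseline(
                            per_cond_mats[condition], per_cond_mats["rest"]
                        )
                        store[(subject, group, condition)] = baselined.values
    return matrices


def _nbs_stage(config: PipelineConfig, matrices: dict, seeds: list[int]) -> pd.DataFrame:
    """Stage 5: within, between and interaction NBS with Bonferroni decisions."""
    p = config.simulation.n_parcels
    rows = []

    def edge_data(store, subject_filter, condition, mode):
        mats = []
        subjects = []
        for (subject, group, cond), values in sorted(store.items()):
            if cond != condition or not subject_filter(group):
                continue
            if mode == "roi":
                values = roi_matrix_to_square(values, seeds, p)
            mats.append(values)
            subjects.append((subject, group))
        return mats, subjects

    def run(analysis, family, metric, band, mode, threshold, direction, a, b, contrast,
            cond_label):
        design = NBSDesign(
            contrast=contrast,
            primary_threshold=threshold,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=int(
                np.random.SeedSequence(
                    [config.seed, _token(analysis), _token(metric), _token(band),
                     _token(mode), _token(direction), int(threshold * 100)]
                ).generate_state(1)[0] % (2**31)
            ),
            direction=direction,
        )
        pairs = roi_pairs(p, seeds) if mode == "roi" else whole_brain_pairs(p)
        results = nbs_permutation_test(a, b, design, pairs, p)
        corr = bonferroni_band_correction(
            [r.p_fwer for r in results], family, config.alpha
        ) if results else {"threshold": config.alpha, "significant": []}
        for rank, r in enumerate(results):
            rows.append(
                {
                    "analysis": analysis,
                    "family": family,
                    "metric": metric,
                    "band": band,
                    "mode": mode,
                    "threshold": threshold,
                    "direction": direction,
                    "condition": cond_label,
                    "component": rank,
                    "n_edges": r.n_edges,
                    "n_nodes": r.n_nodes,
                    "p_fwer": r.p_fwer,
                    "p_threshold": corr["threshold"],
                    "significant": bool(r.p_fwer < corr["threshold"]),
                    "edges": "|".join(f"{i}-{j}" for i, j in r.edges),
                }
            )

    for (metric, band, mode), store in sorted(matrices.items()):
        thresholds = (
            config.aec_thresholds if metric == "aec" else (config.wpli_threshold,)
        )
        for threshold in thresholds:
            # between groups, per condition and direction
            for condition in TASK_CONDITIONS:
                asd, _ = edge_data(store, lambda g: g == "ASD", condition, mode)
                td, _ = edge_data(store, lambda g: g == "TD", condition, mode)
                if len(asd) < 2 or len(td) < 2:
                    continue
                pairs = roi_pairs(p, seeds) if mode == "roi" else whole_brain_pairs(p)
                a = matrices_to_edges(asd, pairs)
                b = matrices_to_edges(td, pairs)
                for direction, label in (("greater", "ASD>TD"), ("less", "TD>ASD")):
                    run(f"between_{condition}_{label}", "between", metric, band, mode,
                        threshold, direction, a, b, "between_groups", condition)
            # within each group, familiar vs unfamiliar (paired)
            for group in GROUPS:
                fam_mats, fam_sub = edge_data(store, lambda g, G=group: g == G,
                                              "familiar", mode)
                unf_mats, unf_sub = edge_data(store, lambda g, G=group: g == G,
                                              "unfamiliar", mode)
                common = sorted(set(s for s, _ in fam_sub) & set(s for s, _ in unf_sub))
                if len(common) < 2:
                    continue
                fam_idx = {s: k for k, (s, _) in enumerate(fam_sub)}
                unf_idx = {s: k for k, (s, _) in enumerate(unf_sub)}
                pairs = roi_pairs(p, seeds) if mode == "roi" else whole_brain_pairs(p)
                a = matrices_to_edges([fam_mats[fam_idx[s]] for s in common], pairs)
                b = matrices_to_edges([unf_mats[unf_idx[s]] for s in common], pairs)
                for direction, label in (("greater", "fam>unf"), ("less", "unf>fam")):
                    run(f"within_{group}_{label}", "within", metric, band, mode,
                        threshold, direction, a, b, "within_group_paired", "familiar-unfamiliar")
        # 2x2 interaction on per-subject condition differences
        diffs = {"ASD": [], "TD": []}
        by_subject: dict[str, dict[str, np.ndarray]] = {}
        for (subject, group, cond), values in sorted(store.items()):
            if mode == "roi":
                values = roi_matrix_to_square(values, seeds, p)
            by_subject.setdefault(subject, {"group": group})[cond] = values
        for subject, entry in sorted(by_subject.items()):
            if "familiar" in entry and "unfamiliar" in entry:
                diffs[entry["group"]].append(entry["familiar"] - entry["unfamiliar"])
        if len(diffs["ASD"]) >= 2 and len(diffs["TD"]) >= 2:
            pairs = roi_pairs(p, seeds) if mode == "roi" else whole_brain_pairs(p)
            a = matrices_to_edges(diffs["ASD"], pairs)
            b = matrices_to_edges(diffs["TD"], pairs)
            run("interaction", "interaction", metric, band, mode,
                config.interaction_f, "greater", a, b, "interaction_2x2",
                "familiarity x group")

    columns = ["analysis", "family", "metric", "band", "mode", "threshold",
               "direction", "condition", "component", "n_edges", "n_nodes",
               "p_fwer", "p_threshold", "significant", "edges"]
    return pd.DataFrame(rows, columns=columns)


def _behavior_stage(config: PipelineConfig, matrices: dict, nbs_table: pd.DataFrame,
                    included: list[str], groups: dict, seeds: list[int]):
    """Stage 6: network strength of significant networks vs behavioral scores."""
    rng = np.random.default_rng([config.seed, _token("behavior")])
    table = generate_behavior_table(included, [groups[s] for s in included], rng)
    rows = []
    sig = nbs_table[nbs_table["significant"] & (nbs_table["family"] == "between")]
    p = config.simulation.n_parcels
    for _, net in sig.iterrows():
        edges = [tuple(map(int, e.split("-"))) for e in net["edges"].split("|") if e]
        store = matrices[(net["metric"], net["band"], net["mode"])]
        strengths = []
        for subject in included:
            key = (subject, groups[subject], net["condition"])
            if key not in store:
                strengths.append(np.nan)
                continue
            values = store[key]
            if net["mode"] == "roi":
                values = roi_matrix_to_square(values, seeds, p)
            strengths.append(network_strength(values, edges))
        strengths = np.asarray(strengths)
        net_id = f"{net['analysis']}_{net['metric']}_{net['band']}_{net['mode']}"
        asd_mask = np.array([groups[s] == "ASD" for s in included])
        for score, mask in (("SCQ", None), ("RBS_R_sameness", None), ("ADOS_css", asd_mask)):
            vals = table[score].to_numpy(dtype=float)
            s = strengths.copy()
            if mask is not None:
                s = np.where(mask, s, np.nan)
            try:
                r, pval, n = correlate_with_behavior(s, vals)
            except ValueError:
                continue
            rows.append({"network": net_id, "score": score, "r": r, "p": pval, "n": n})
    return table, pd.DataFrame(rows, columns=["network", "score", "r", "p", "n"])


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Run the full analysis and write a deterministic results bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    manifest, data = _simulate_cohort(config)
    # remember each row's position within its subject/condition data block
    manifest["trial_pos"] = (
        manifest.groupby(["subject", "condition_response"]).cumcount()
    )
    write_manifest(manifest.drop(columns=["trial_pos"]), outdir / "manifest_full.tsv")

    kept, motion_report = reject_motion_trials(manifest, config.motion_threshold_mm)
    included, count_report = qc_min_trials(kept, config.min_trials)
    # baselining needs at least one surviving resting trial per subject
    rest_counts = kept[kept["is_rest"]].groupby("subject").size()
    no_rest = [s for s in included if rest_counts.get(s, 0) == 0]
    if no_rest:
        included = [s for s in included if s not in no_rest]
        count_report.excluded_subjects.extend(no_rest)
    write_manifest(kept.drop(columns=["trial_pos"]), outdir / "manifest_kept.tsv")
    qc = {
        "kept": motion_report.kept,
        "dropped_motion": motion_report.dropped_motion,
        "condition_counts": count_report.condition_counts,
        "excluded_subjects": count_report.excluded_subjects,
        "included_subjects": included,
    }

    if config.sensor_space:
        for subject in included:
            _sensor_roundtrip(config, subject, data)

    if config.node_table_path:
        node_table = load_node_table(config.node_table_path, canonical=False)
    elif sim.n_parcels == 92:
        node_table = load_node_table()
    else:
        node_table = generic_node_table(sim.n_parcels, n_seeds=min(13, sim.n_parcels // 2))
    if len(node_table) != sim.n_parcels:
        raise PipelineError("node table row count does not match parcel count")
    seeds = seed_indices(node_table)

    matrices = _connectivity_stage(config, kept, data, included, seeds)

    for (metric, band, mode), store in sorted(matrices.items()):
        save_array_store(
            {f"{s}_{c}": v for (s, _g, c), v in store.items()},
            outdir / "matrices" / f"{metric}_{band}_{mode}",
            meta={"metric": metric, "band": band, "mode": mode,
                  "baselined": True, "seeds": seeds if mode == "roi" else None},
        )

    nbs_table = _nbs_stage(config, matrices, seeds)
    nbs_table.to_csv(outdir / "nbs_results.tsv", sep="\t", index=False,
                     float_format="%.6g")

    groups = dict(manifest.groupby("subject")["group"].first())
    behavior_table, correlations = _behavior_stage(
        config, matrices, nbs_table, included, groups, seeds
    )
    behavior_table.to_csv(outdir / "behavior.tsv", sep="\t", index=False,
                          float_format="%.6g")
    correlations.to_csv(outdir / "behavior_correlations.tsv", sep="\t", index=False,
                        float_format="%.6g")

    exports = outdir / "exports"
    sig = nbs_table[nbs_table["significant"]] if len(nbs_table) else nbs_table
    if len(sig):
        exports.mkdir(exist_ok=True)
        for _, net in sig.iterrows():
            edges = [tuple(map(int, e.split("-"))) for e in net["edges"].split("|") if e]
            name = (f"{net['analysis']}_{net['metric']}_{net['band']}_{net['mode']}"
                    f"_t{net['threshold']:g}_c{net['component']}")
            export_network(edges, node_table, exports / name)

    write_run_log(
        outdir / "run_log.json",
        {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "config": config.to_dict(),
            "seed": config.seed,
            "qc": qc,
            "n_significant": int(nbs_table["significant"].sum()) if len(nbs_table) else 0,
        },
    )

    return PipelineResult(
        outdir=outdir,
        included_subjects=included,
        nbs_table=nbs_table,
        behavior_table=behavior_table,
        behavior_correlations=correlations,
        matrices=matrices,
        qc=qc,
    )
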