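"""Pipeline driver: classify windows -> bouts -> events -> features -> analysis.

Each stage reads its upstream products from disk and writes plain CSV/JSON
artifacts with fixed column orders, so a rerun with the same seed and config
is byte-identical.  Every filter step logs (n_before, n_removed, n_after).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity, analysis, classify, features, io, strides, synthetic
from .config import PipelineConfig
from .types import DependencyError, MsgaitError, WalkingBout

log = logging.getLogger("msgait")

STAGES = ("detect_bouts", "extract", "analyze", "classify")


def simulate(config: PipelineConfig, out_dir, n_subjects: int = 38,
             faller_fraction: float = 21 / 38, duration_min: float = 30.0,
             effect_config: dict | None = None, with_lab: bool = True,
             seed: int | None = None) -> dict:
    """Generate a synthetic cohort dataset on disk (home + lab recordings).

    ``duration_min`` is the simulated free-living wear time per subject; the
    study's 48-hour protocol is emulated at shorter durations for tractable
    experiments (the bout mixture, not the total hours, is what downstream
    stages consume).
    """
    seed = config.seed if seed is None else seed
    missing = {"NSI": 2} if n_subjects >= 10 else None
    cohort = synthetic.generate_cohort(n_subjects, faller_fraction,
                                       effect_config=effect_config, seed=seed,
                                       missing_surveys=missing)
    recordings, gts, labs = {}, {}, {}
    child_seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    for prof, ss in zip(cohort, child_seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        chest, thigh, gt = synthetic.generate_subject_recording(
            prof, duration_h=duration_min / 60.0, seed=sub_seed, fs=config.fs_target
        )
        recordings[prof.subject_id] = (chest, thigh)
        gts[prof.subject_id] = gt
        if with_lab:
            labs[prof.subject_id] = synthetic.generate_lab_recording(prof, seed=sub_seed + 1)
    return synthetic.write_dataset(cohort, recordings, gts, out_dir,
                                   lab_recordings=labs if with_lab else None)


def _detect_bouts(config, input_dir, out_dir, classifier=None):
    manifest = io.read_manifest(input_dir)
    rows = []
    for sid in sorted(manifest["subjects"]):
        chest, thigh, _ = io.load_subject(input_dir, sid)
        windows = activity.window_signal(chest, thigh, config.window_s)
        if classifier is None:
            det = activity.SpectralGaitDetector(fs=chest.fs)
            labels, _ = det.classify(windows)
        else:
            labels, _ = activity.classify_windows(classifier, windows)
        bouts = activity.assemble_bouts(labels, config.window_s, subject_id=sid, fs=chest.fs)
        for b in bouts:
            rows.append({"subject_id": sid, "bout_id": b.bout_id, "start_s": b.start_s,
                         "end_s": b.end_s, "duration_s": b.duration_s,
                         "n_windows": int(round(b.duration_s / config.window_s))})
    df = pd.DataFrame(rows, columns=io.BOUT_TABLE_COLUMNS)
    io.write_table(df, Path(out_dir) / "bouts.csv", io.BOUT_TABLE_COLUMNS)
    log.info("detect_bouts: %d bouts across %d subjects", len(df), len(manifest["subjects"]))
    return df


def _extract(config, input_dir, out_dir):
    bout_path = Path(out_dir) / "bouts.csv"
    if not bout_path.exists():
        raise DependencyError("extract requires bouts.csv; run detect_bouts first")
    bout_table = pd.read_csv(bout_path)
    manifest = io.read_manifest(input_dir)

    all_bouts = []
    for sid, grp in bout_table.groupby("subject_id"):
        chest, thigh, _ = io.load_subject(input_dir, sid)
        bouts = [
            WalkingBout(bout_id=int(r.bout_id), subject_id=sid, start_s=r.start_s,
                        end_s=r.end_s, fs=chest.fs)
            for r in grp.itertuples()
        ]
        activity.attach_views(bouts, chest, thigh)
        for b in bouts:
            strides.detect_bout_events(b)
        all_bouts.extend(bouts)

    retained, flog = strides.filter_valid(all_bouts, config.validity_ranges)
    log.info("filter_valid: %s", flog)

    stride_rows, param_rows = [], []
    for b in retained:
        cls = analysis.categorize_bout_duration(b.duration_s, config.duration_class_bounds)
        for i, s in enumerate(b.strides):
            stride_rows.append({"subject_id": b.subject_id, "bout_id": b.bout_id,
                                "stride_idx": i, "fc_s": s.foot_contact_s,
                                "fo_s": s.foot_off_s, "stride_s": s.stride_time_s,
                                "stance_s": s.stance_time_s, "swing_s": s.swing_time_s,
                                "duty_factor": s.duty_factor, "valid_flag": 1})
        try:
            param_rows.append(features.extract_bout_parameters(b, cls))
        except MsgaitError as exc:
            log.warning("bout %s/%s dropped at feature stage: %s", b.subject_id, b.bout_id, exc)

    # lab hallway walk: one long bout per subject, resampled to the home rate
    n_lab = 0
    for sid in sorted(manifest["subjects"]):
        lab = io.load_subject_lab(input_dir, sid)
        if lab is None:
            continue
        chest = io.resample_recording(lab[0], config.fs_target)
        thigh = io.resample_recording(lab[1], config.fs_target)
        b = WalkingBout(bout_id=100000, subject_id=sid, start_s=0.0,
                        end_s=chest.duration_s, fs=config.fs_target, context="lab")
        activity.attach_views(b_list := [b], chest, thigh)
        if not strides.detect_bout_events(b):
            log.warning("lab walk for %s yielded <2 strides", sid)
            continue
        kept, _ = strides.filter_valid(b_list, config.validity_ranges)
        if not kept:
            continue
        try:
            param_rows.append(features.extract_bout_parameters(b, "lab"))
            n_lab += 1
        except MsgaitError as exc:
            log.warning("lab bout for %s dropped: %s", sid, exc)

    stride_df = pd.DataFrame(stride_rows, columns=io.STRIDE_TABLE_COLUMNS)
    param_df = pd.DataFrame(param_rows)
    io.write_table(stride_df, Path(out_dir) / "strides.csv", io.STRIDE_TABLE_COLUMNS)
    io.write_table(param_df, Path(out_dir) / "parameters.csv", io.PARAMETER_TABLE_COLUMNS)
    (Path(out_dir) / "filter_log.json").write_text(json.dumps(flog, indent=1))
    log.info("extract: %d home bouts, %d lab bouts parameterized", len(param_rows) - n_lab, n_lab)
    return param_df


def _analyze(config, input_dir, out_dir):
    param_path = Path(out_dir) / "parameters.csv"
    if not param_path.exists():
        raise DependencyError("analyze requires parameters.csv; run extract first")
    params = pd.read_csv(param_path)
    cohort = io.read_cohort_table(input_dir)
    cohort = analysis.impute_surveys_knn(cohort, k=3)
    io.write_table(cohort, Path(out_dir) / "cohort_imputed.csv")
    tables = analysis.comparison_suite(params, cohort, config)
    for name, df in tables.items():
        io.write_table(df, Path(out_dir) / f"comparisons_{name}.csv",
                       io.COMPARISON_TABLE_COLUMNS)
    return tables


def _classify(config, input_dir, out_dir, families=("LR", "KNN", "tree"),
              selectors=("short", "medium", "long", "all_home", "lab"),
              n_search: int = 0):
    param_path = Path(out_dir) / "parameters.csv"
    if not param_path.exists():
        raise DependencyError("classify requires parameters.csv; run extract first")
    params = pd.read_csv(param_path)
    cohort = io.read_cohort_table(input_dir)
    report = []
    for selector in selectors:
        try:
            X, y, sids = classify.build_feature_matrix(params, selector, cohort)
        except MsgaitError as exc:
            log.warning("selector %s skipped: %s", selector, exc)
            continue
        for family in families:
            try:
                out = classify.loso_feature_classifiers(
                    X, y, sids, model_family=family, pca_variance=config.pca_variance,
                    seed=config.seed, n_search=n_search, feature_set=selector,
                )
            except MsgaitError as exc:
                log.warning("%s/%s skipped: %s", selector, family, exc)
                continue
            report.append({"feature_set": selector, "model": family,
                           "auc_per_input": out.auc_per_input,
                           "auc_subject_median": out.auc_subject_median,
                           "n_inputs": int(len(out.scores)),
                           "per_fold": out.per_fold})
    (Path(out_dir) / "classifier_report.json").write_text(json.dumps(report, indent=1))
    return report


def run_pipeline(config: PipelineConfig, input_dir, out_dir, stages=STAGES,
                 classifier=None) -> dict:
    """Execute the requested stages in pipeline order.

    Stages: detect_bouts, extract, analyze, classify.  A stage requested
    without its upstream products on disk raises DependencyError.  Window
    classification uses the deterministic spectral detector unless a trained
    ``classifier`` is supplied.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise MsgaitError(f"unknown stages {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "detect_bouts":
            results[stage] = _detect_bouts(config, input_dir, out_dir, classifier)
        elif stage == "extract":
            results[stage] = _extract(config, input_dir, out_dir)
        elif stage == "analyze":
            results[stage] = _analyze(config, input_dir, out_dir)
        elif stage == "classify":
            results[stage] = _classify(config, input_dir, out_dir)
    return results
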