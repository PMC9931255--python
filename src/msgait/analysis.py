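"""Bout-duration stratification and group comparison suites.

Walking bouts fall into three duration classes (short <= 8 s, medium
12-28 s, long >= 32 s; durations are 4-s quantized so the gaps cannot
occur).  Per subject and class, each gait parameter is summarized with seven
statistics (mean, median, max, min, SD, 5th and 95th percentile, linear
interpolation for percentiles).  Three Wilcoxon rank-sum suites mirror the
study's analysis: duration vs duration on pooled bout-level values, lab vs
home, and faller vs non-faller on the subject summaries — all two-sided at a
single alpha with no multiplicity correction (a Benjamini-Hochberg option
exists but is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .features import FEATURES_BASE
from .types import ConfigurationError, MsgaitError, SURVEY_FIELDS

SUMMARY_STATS = ("mean", "median", "max", "min", "sd", "p5", "p95")


@dataclass
class GroupComparison:
    comparison_id: str
    unit: str  # "bout" | "subject_summary"
    feature: str
    median_a: float
    median_b: float
    p_value: float
    significant: bool


def categorize_bout_duration(duration_s: float, bounds=None) -> str:
    """Map a 4-s-quantized bout duration to short / medium / long."""
    if bounds is None:
        bounds = PipelineConfig().duration_class_bounds
    if duration_s <= 0:
        raise ConfigurationError("duration must be positive")
    if duration_s <= bounds.short_max_s:
        return "short"
    if bounds.medium_min_s <= duration_s <= bounds.medium_max_s:
        return "medium"
    if duration_s >= bounds.long_min_s:
        return "long"
    raise MsgaitError(
        f"duration {duration_s} s falls between classes; durations must be "
        "multiples of the window length"
    )


def summarize_subject(values, subject_id: str = "", duration_class: str = "") -> dict:
    """Seven summary statistics of one parameter's bout-level values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise MsgaitError(f"no bouts for subject {subject_id} in class {duration_class}")
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "max": float(v.max()),
        "min": float(v.min()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "p5": float(np.percentile(v, 5)),  # linear interpolation
        "p95": float(np.percentile(v, 95)),
    }


def summarize_subjects(param_table: pd.DataFrame, features=None) -> pd.DataFrame:
    """Per subject x duration-class summary table (long format).

    Columns: subject_id, duration_class, feature, then the seven statistics.
    Subjects with no bouts in a class are simply absent from that class.
    """
    features = list(features) if features is not None else FEATURES_BASE
    rows = []
    for (sid, cls), grp in param_table.groupby(["subject_id", "duration_class"]):
        for feat in features:
            if feat not in grp.columns:
                continue
            vals = grp[feat].dropna()
            if vals.empty:
                continue
            row = {"subject_id": sid, "duration_class": cls, "feature": feat}
            row.update(summarize_subject(vals, sid, cls))
            rows.append(row)
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(sample_a, sample_b, alpha: float = 0.05,
                      comparison_id: str = "", feature: str = "",
                      unit: str = "bout") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Exact enumeration when min(n) <= 8 and the pooled sample is tie-free;
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MsgaitError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        p = 1.0
    else:
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    return GroupComparison(
        comparison_id=comparison_id,
        unit=unit,
        feature=feature,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        p_value=p,
        significant=bool(p < alpha),
    )


def _comparisons_to_frame(comps) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": c.comparison_id,
                "feature": c.feature,
                "median_1": c.median_a,
                "median_2": c.median_b,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for c in comps
        ]
    )


def benjamini_hochberg(pvals):
    """BH-adjusted p-values (optional; the default suites are uncorrected)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def comparison_suite(param_table: pd.DataFrame, cohort: pd.DataFrame,
                     config: PipelineConfig | None = None) -> dict:
    """The three comparison tables.

    duration: pooled bout-level values, class vs class (home context);
    context: lab vs each home class and vs all home, bout-level;
    fall_groups: faller vs non-faller subject-summary statistics per class.

    Returns a dict of DataFrames keyed by suite name; suites whose contexts
    are missing from the data are skipped.
    """
    config = config or PipelineConfig()
    alpha = config.alpha
    home = param_table[param_table["context"] == "home"]
    lab = param_table[param_table["context"] == "lab"]
    out: dict[str, pd.DataFrame] = {}

    # (i) duration vs duration, pooled bout level
    comps = []
    classes = [c for c in ("short", "medium", "long") if (home["duration_class"] == c).any()]
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a_cls, b_cls = classes[i], classes[j]
            ga = home[home["duration_class"] == a_cls]
            gb = home[home["duration_class"] == b_cls]
            for feat in FEATURES_BASE:
                comps.append(
                    wilcoxon_rank_sum(
                        ga[feat].dropna(), gb[feat].dropna(), alpha,
                        comparison_id=f"{a_cls}_vs_{b_cls}", feature=feat,
                    )
                )
    out["duration"] = _comparisons_to_frame(comps)

    # (ii) lab vs home
    if not lab.empty:
        comps = []
        targets = [(c, home[home["duration_class"] == c]) for c in classes]
        targets.append(("all_home", home))
        for name, grp in targets:
            if grp.empty:
                continue
            feats = list(FEATURES_BASE)
            if name == "long":
                extra = [f for f in ("entropy_ratio", "ly_ap_per_s", "ly_ml_per_s")
                         if f in grp.columns and grp[f].notna().any()
                         and f in lab.columns and lab[f].notna().any()]
                feats += extra
            for feat in feats:
                comps.append(
                    wilcoxon_rank_sum(
                        lab[feat].dropna(), grp[feat].dropna(), alpha,
                        comparison_id=f"lab_vs_{name}", feature=feat,
                    )
                )
        out["context"] = _comparisons_to_frame(comps)

    # (iii) faller vs non-faller on subject summaries
    label_map = cohort.set_index("subject_id")["fall_label"]
    summaries = summarize_subjects(home)
    if not summaries.empty:
        summaries = summaries.assign(fall_label=summaries["subject_id"].map(label_map))
        comps = []
        for (cls, feat), grp in summaries.groupby(["duration_class", "feature"]):
            fal = grp[grp["fall_label"] == "faller"]
            non = grp[grp["fall_label"] == "non_faller"]
            if fal.empty or non.empty:
                continue
            for stat in SUMMARY_STATS:
                comps.append(
                    wilcoxon_rank_sum(
                        fal[stat], non[stat], alpha,
                        comparison_id=f"fallers_vs_nonfallers_{cls}",
                        feature=f"{stat}_{feat}", unit="subject_summary",
                    )
                )
        out["fall_groups"] = _comparisons_to_frame(comps)
    return out


def impute_surveys_knn(cohort: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Fill missing survey entries by k-nearest-neighbour averaging.

    A missing value is the mean of that field over the k nearest complete
    rows, by Euclidean distance on the z-scored remaining survey fields
    (z-scoring statistics from the complete rows).
    """
    out = cohort.copy()
    fields = [f for f in SURVEY_FIELDS if f in out.columns]
    complete = out[fields].notna().all(axis=1)
    if complete.sum() < k:
        raise MsgaitError(f"k-NN imputation needs >= {k} complete rows")
    comp = out.loc[complete, fields]
    mu, sd = comp.mean(), comp.std(ddof=0).replace(0, 1.0)
    comp_z = (comp - mu) / sd
    for idx in out.index[~complete]:
        row = out.loc[idx, fields]
        missing = [f for f in fields if pd.isna(row[f])]
        present = [f for f in fields if not pd.isna(row[f])]
        if not present:
            raise MsgaitError(f"row {idx} has no survey fields to match on")
        row_z = (row[present].astype(float) - mu[present]) / sd[present]
        d = np.sqrt(((comp_z[present] - row_z) ** 2).sum(axis=1))
        nearest = d.to_numpy().argsort(kind="stable")[:k]
        neighbours = comp.iloc[nearest]
        for f in missing:
            out.loc[idx, f] = float(neighbours[f].mean())
    return out
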