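"""End-to-end orchestration: simulate/ingest → condition → metrics → stats → classify.

The pipeline turns per-hemisphere amplitude streams plus clinical metadata
into a tidy daily-metric table (patient, hemisphere, day, metric, value,
state, dichotomy), state-comparison tables, and LOPO classifier results
with permutation nulls.  All stages are deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks

from . import __version__
from .autoregressive import (
    cv_daily_r2_linear,
    cv_daily_r2_nonlinear,
    select_significant_lags,
)
from .classifier import lopo_logistic, permutation_test
from .clinical import day_labels
from .cosinor import statewise_cv_daily_r2
from .entropy import EntropyParams, daily_sample_entropy
from .ingest import bin_daily, condition_series, zscore_daily
from .simulate import ArtifactSpec, CohortConfig, PatientBundle, simulate_cohort
from .stats import compare_states, max_margin_threshold, pooled_compare
from .types import (
    BINS_PER_DAY,
    BURDENED,
    PRE_DBS,
    UNBURDENED,
    UNLABELED,
    AmplitudeSeries,
    ClinicalTrajectory,
    DailyMatrix,
)

METRICS = ("cosinor_r2", "linear_ar_r2", "nonlinear_ar_r2", "sample_entropy")


def suggest_n_components(matrix: DailyMatrix, prominence: float = 0.25,
                         max_components: int = 3) -> int:
    """Heuristic harmonic count: prominent peaks of the mean daily profile.

    Counts peaks with circular prominence above ``prominence`` (z-units) in
    the bin-wise mean profile; clipped to [1, max_components].
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(matrix.values, axis=0)
    profile = profile[np.isfinite(profile)]
    if len(profile) < 8:
        return 1
    wrapped = np.r_[profile, profile, profile]
    peaks, _ = find_peaks(wrapped, prominence=prominence)
    n = len(profile)
    count = np.sum((peaks >= n) & (peaks < 2 * n))
    return int(np.clip(count, 1, max_components))


@dataclass
class HemisphereResult:
    """Per patient-hemisphere analysis products."""

    patient_id: str
    hemisphere: str
    daily: pd.DataFrame               # day, metric, value, state
    state_means: dict                 # metric -> {state: mean CV R²}
    selected_lags: list[int]
    lag_history: list
    conditioning: dict
    n_components: int


def analyze_hemisphere(series: AmplitudeSeries, trajectory: ClinicalTrajectory,
                       n_components: int = 2, auto_components: bool = False,
                       include_nonlinear: bool = True, seed: int = 0,
                       entropy_params: EntropyParams | None = None,
                       n_folds: int = 5) -> HemisphereResult:
    """Condition one hemisphere's stream and compute the four daily metrics."""
    conditioned, report = condition_series(series)
    matrix = zscore_daily(bin_daily(conditioned, trajectory.dbs_activation_date))
    states = day_labels(trajectory.intervals, matrix.days)
    states = states[states["state"] != UNLABELED].reset_index(drop=True)

    if auto_components:
        n_components = suggest_n_components(matrix)

    x = matrix.values.reshape(-1)
    day_of_sample = np.repeat(matrix.days, BINS_PER_DAY)

    parts = []
    state_means = {}

    cos_means, cos_daily = statewise_cv_daily_r2(matrix, states,
                                                 n_components=n_components,
                                                 n_folds=n_folds)
    state_means["cosinor_r2"] = cos_means
    parts.append(cos_daily.assign(metric="cosinor_r2"))

    selection = select_significant_lags(x)
    lin_means, lin_daily = cv_daily_r2_linear(x, selection.lags, day_of_sample,
                                              states, n_folds=n_folds)
    state_means["linear_ar_r2"] = lin_means
    parts.append(lin_daily.assign(metric="linear_ar_r2"))

    if include_nonlinear:
        nl_means, nl_daily = cv_daily_r2_nonlinear(x, day_of_sample, states,
                                                   n_folds=n_folds, seed=seed)
        state_means["nonlinear_ar_r2"] = nl_means
        parts.append(nl_daily.assign(metric="nonlinear_ar_r2"))

    ent_daily = daily_sample_entropy(matrix, entropy_params)
    state_of_day = dict(zip(states["day"], states["state"]))
    ent_daily = ent_daily.assign(
        state=[state_of_day.get(int(d)) for d in ent_daily["day"]],
        metric="sample_entropy")
    ent_daily = ent_daily.dropna(subset=["state"])
    state_means["sample_entropy"] = {
        s: float(np.nanmean(g["value"]))
        for s, g in ent_daily.groupby("state") if np.isfinite(g["value"]).any()
    }
    parts.append(ent_daily)

    daily = pd.concat(parts, ignore_index=True)[["day", "metric", "value", "state"]]
    dicho = dict(zip(states["day"], states["dichotomy"]))
    daily["dichotomy"] = [dicho.get(int(d)) for d in daily["day"]]
    return HemisphereResult(
        patient_id=series.patient_id, hemisphere=series.hemisphere,
        daily=daily, state_means=state_means, selected_lags=selection.lags,
        lag_history=selection.history,
        conditioning=json.loads(report.to_json()), n_components=n_components)


@dataclass
class CohortResult:
    """Analysis products for a whole cohort."""

    hemisphere_results: list[HemisphereResult]
    trajectories: dict[str, ClinicalTrajectory]

    @property
    def daily(self) -> pd.DataFrame:
        frames = [
            r.daily.assign(patient=r.patient_id, hemisphere=r.hemisphere)
            for r in self.hemisphere_results
        ]
        return pd.concat(frames, ignore_index=True)


def analyze_cohort(bundles: list[PatientBundle], hemispheres=("L", "R"),
                   include_nonlinear: bool = True, seed: int = 0,
                   n_components: int = 2) -> CohortResult:
    results = []
    trajectories = {}
    for i, b in enumerate(bundles):
        trajectories[b.patient_id] = b.trajectory
        for hemi in hemispheres:
            if hemi not in b.series:
                continue
            results.append(analyze_hemisphere(
                b.series[hemi], b.trajectory, n_components=n_components,
                include_nonlinear=include_nonlinear,
                seed=seed + 97 * i + (0 if hemi == "L" else 1)))
    return CohortResult(hemisphere_results=results, trajectories=trajectories)


# ---------------------------------------------------------------------------
# statistics over a cohort result

def state_comparison_table(result: CohortResult, corrected_values=(False, True)
                           ) -> pd.DataFrame:
    """Per patient-hemisphere-metric pre-DBS vs post-DBS comparisons."""
    rows = []
    for r in result.hemisphere_results:
        post_states = [s for s in r.daily["state"].unique()
                       if s != PRE_DBS and s is not None]
        for metric in r.daily["metric"].unique():
            d = r.daily[r.daily["metric"] == metric]
            for post in post_states:
                for corrected in corrected_values:
                    cmp_ = compare_states(d, PRE_DBS, post, metric=metric,
                                          patient=r.patient_id,
                                          corrected=corrected)
                    if cmp_ is not None:
                        row = cmp_.to_row()
                        row["hemisphere"] = r.hemisphere
                        rows.append(row)
    return pd.DataFrame(rows)


def pooled_comparison_table(result: CohortResult, hemisphere: str = "L",
                            corrected_values=(False, True)) -> pd.DataFrame:
    """Cross-patient burdened vs unburdened comparisons per metric."""
    daily = result.daily
    daily = daily[(daily["hemisphere"] == hemisphere)
                  & daily["dichotomy"].notna()]
    rows = []
    for metric, g in daily.groupby("metric"):
        per_patient = {
            pid: gg.rename(columns={"dichotomy": "label"})[["day", "value", "label"]]
            for pid, gg in g.groupby("patient")
        }
        for corrected in corrected_values:
            try:
                cmp_ = pooled_compare(per_patient, BURDENED, UNBURDENED,
                                      metric=metric, corrected=corrected)
            except ValueError:
                continue
            row = cmp_.to_row()
            row["hemisphere"] = hemisphere
            rows.append(row)
    return pd.DataFrame(rows)


def build_feature_table(result: CohortResult, metric: str,
                        variant: str = "delta", hemisphere: str = "L"
                        ) -> pd.DataFrame:
    """Classifier features: (patient, day, value, label) for one metric.

    ``variant='daily'`` uses each day's raw metric value; ``'delta'``
    subtracts the patient's pre-DBS state mean (patients without pre-DBS
    data are excluded from the delta table).
    """
    if variant not in ("delta", "daily"):
        raise ValueError("variant must be 'delta' or 'daily'")
    daily = result.daily
    daily = daily[(daily["hemisphere"] == hemisphere)
                  & (daily["metric"] == metric)
                  & daily["dichotomy"].notna()]
    rows = []
    for pid, g in daily.groupby("patient"):
        values = g["value"].to_numpy(dtype=float)
        if variant == "delta":
            pre = g.loc[g["state"] == PRE_DBS, "value"].to_numpy(dtype=float)
            pre = pre[np.isfinite(pre)]
            if len(pre) == 0:
                continue
            values = values - pre.mean()
        rows.append(pd.DataFrame({
            "patient": pid, "day": g["day"].to_numpy(),
            "value": values, "label": g["dichotomy"].to_numpy(),
        }))
    if not rows:
        raise ValueError(f"no usable feature rows for {metric}/{variant}")
    return pd.concat(rows, ignore_index=True).dropna(subset=["value"])


def responder_margin_table(result: CohortResult, metric: str = "linear_ar_r2",
                           hemisphere: str = "L") -> dict:
    """Max-margin separability of per-patient pre-to-post metric changes."""
    deltas, labels = [], []
    for r in result.hemisphere_results:
        if r.hemisphere != hemisphere:
            continue
        d = r.daily[r.daily["metric"] == metric]
        pre = d.loc[d["state"] == PRE_DBS, "value"].mean()
        post = d.loc[d["state"] != PRE_DBS, "value"].mean()
        if not (np.isfinite(pre) and np.isfinite(post)):
            continue
        deltas.append(post - pre)
        labels.append(result.trajectories[r.patient_id].responder)
    separable, threshold, margin = max_margin_threshold(deltas, labels)
    return {"separable": separable, "threshold": threshold, "margin": margin,
            "deltas": deltas, "responder": labels}


# ---------------------------------------------------------------------------
# session-file cohorts

def load_session_cohort(session_paths, meta_csv, intervals_csv) -> list[PatientBundle]:
    """Build patient bundles from session files plus clinical metadata CSVs.

    ``meta_csv`` needs columns (patient_id, responder, ybocs_initial,
    ybocs_final, dbs_activation_date, tz_offset_min); ``intervals_csv``
    needs (patient_id, state, start_day, end_day) — the layout written by
    :func:`chronolfp.simulate.write_clinical_files`.
    """
    from .clinical import PatientMeta  # noqa: F401  (schema mirror)
    from .ingest import read_sessions
    from .types import StateInterval

    meta = pd.read_csv(meta_csv)
    intervals = pd.read_csv(intervals_csv)
    bundles = []
    for _, row in meta.iterrows():
        pid = row["patient_id"]
        tz = int(row.get("tz_offset_min", 0))
        own = [p for p in session_paths if Path(p).name.startswith(f"{pid}_")]
        if not own:
            raise ValueError(f"no session files found for patient {pid}")
        series = read_sessions(own, tz_offset_min=tz)
        ivs = [
            StateInterval(r.state, int(r.start_day), int(r.end_day))
            for r in intervals[intervals["patient_id"] == pid].itertuples()
        ]
        trajectory = ClinicalTrajectory(
            patient_id=pid, responder=bool(row["responder"]),
            ybocs_initial=int(row["ybocs_initial"]),
            ybocs_final=int(row["ybocs_final"]),
            dbs_activation_date=pd.Timestamp(row["dbs_activation_date"]),
            intervals=ivs)
        bundles.append(PatientBundle(
            series={h: s for (_, h), s in series.items()},
            trajectory=trajectory))
    return bundles


# ---------------------------------------------------------------------------
# config-driven run

@dataclass
class PipelineConfig:
    """YAML-mappable configuration for a full run."""

    mode: str = "synthetic"            # synthetic | session-files
    out_dir: str = "chronolfp_out"
    seed: int = 0
    session_paths: list[str] = field(default_factory=list)
    clinical_meta_csv: str | None = None
    state_intervals_csv: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    hemispheres: tuple[str, ...] = ("L",)
    n_components: int = 2
    include_nonlinear: bool = True
    n_perm: int = 1000
    classifier_metric: str = "linear_ar_r2"
    classifier_variant: str = "delta"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        artifacts_raw = cohort_raw.pop("artifacts", None)
        cohort = CohortConfig(**cohort_raw)
        if artifacts_raw is not None:
            cohort.artifacts = ArtifactSpec(**artifacts_raw)
        if "hemispheres" in raw:
            raw["hemispheres"] = tuple(raw["hemispheres"])
        return cls(cohort=cohort, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages per the config and write outputs under ``out_dir``.

    Writes the daily metric CSV, comparison tables, classifier results and
    a manifest (config hash, seed, package version).  Returns the result
    summary dict.
    """
    out = Path(config.out_dir)
    if config.mode == "synthetic":
        bundles = simulate_cohort(config.cohort, config.seed)
    elif config.mode == "session-files":
        needed = list(config.session_paths) + [config.clinical_meta_csv,
                                               config.state_intervals_csv]
        for p in needed:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"configured input path missing: {p}")
        bundles = load_session_cohort(config.session_paths,
                                      config.clinical_meta_csv,
                                      config.state_intervals_csv)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    result = analyze_cohort(bundles, hemispheres=config.hemispheres,
                            include_nonlinear=config.include_nonlinear,
                            seed=config.seed, n_components=config.n_components)
    out.mkdir(parents=True, exist_ok=True)
    result.daily.to_csv(out / "daily_metrics.csv", index=False)

    comparisons = state_comparison_table(result)
    comparisons.to_csv(out / "state_comparisons.csv", index=False)
    pooled = pooled_comparison_table(result, hemisphere=config.hemispheres[0])
    pooled.to_csv(out / "pooled_comparisons.csv", index=False)

    features = build_feature_table(result, config.classifier_metric,
                                   config.classifier_variant,
                                   config.hemispheres[0])
    clf = lopo_logistic(features)
    clf.roc_points.to_csv(out / "roc_points.csv", index=False)
    perms = {
        method: permutation_test(features, method=method, n_perm=config.n_perm,
                                 seed=config.seed, observed=clf).to_dict()
        for method in ("random", "circular")
    }

    margin = responder_margin_table(result, config.classifier_metric,
                                    config.hemispheres[0])
    summary = {
        "classifier": clf.to_dict(),
        "permutations": perms,
        "max_margin": {k: margin[k] for k in ("separable", "threshold", "margin")},
        "selected_lags": {
            f"{r.patient_id}_{r.hemisphere}": {
                "lags": r.selected_lags, "history": r.lag_history}
            for r in result.hemisphere_results
        },
        "conditioning": {
            f"{r.patient_id}_{r.hemisphere}": r.conditioning
            for r in result.hemisphere_results
        },
    }
    config_blob = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
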