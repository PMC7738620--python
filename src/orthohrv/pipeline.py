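"""End-to-end orchestration: simulate -> sessions -> HRV -> workload ->
well-being -> correlations -> model selection -> prediction flags.

Stages communicate only through the documented CSV/JSON artifacts, so
each one can also be run on its own (or from the CLI) against externally
collected data laid out the same way.  A run manifest (config hash,
seed, package version, row counts) makes every run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hrv import (
    DEFAULT_OVERLAP,
    DEFAULT_RESAMPLE_HZ,
    DEFAULT_SEGMENT_S,
    sessions_table,
)
from .models import (
    CANDIDATE_PREDICTORS,
    best_subset_search,
    flag_recovery,
    get_published_model,
    predict,
)
from .sessions import (
    DEFAULT_THRESHOLD_MS,
    DEFAULT_WINDOW_S,
    assemble_session,
    read_rr_text,
)
from .simulate import SimulationConfig, simulate_cohort, write_cohort_dataset
from .stats import correlation_table, wide_correlation_table
from .wellbeing import cohort_delta_wb, wb_vs_training
from .workload import hr_zone_durations, edwards_trimp, read_hr_trace_csv

log = logging.getLogger("orthohrv")

DEFAULT_INDEX_COLUMNS = (
    "mean_rr_supine",
    "mean_rr_standing",
    "rmssd_supine",
    "rmssd_standing",
    "delta_rr_mean",
    "delta_rmssd",
    "delta_ln_rmssd",
    "lf_nu_supine",
    "hf_nu_supine",
    "lf_hf_ratio_supine",
)
DEFAULT_INDICATOR_COLUMNS = (
    "stage_distance_km",
    "trimp",
    "rpe",
    "perceived_fatigue",
    "doms",
    "sleep_quality",
    "stress",
)


@dataclass
class PipelineConfig:
    """One reproducibility anchor for a whole run.

    When ``simulate`` is true the input paths are generated under
    ``outdir/dataset``; otherwise they must point at existing artifacts.
    """

    outdir: str = "orthohrv_run"
    simulate: bool = True
    seed: int = 0

    # external inputs (used when simulate is false)
    manifest: str | None = None
    traces_dir: str | None = None
    questionnaire: str | None = None
    profiles: str | None = None
    rpe: str | None = None

    # rr_sessions parameters
    threshold_ms: float = DEFAULT_THRESHOLD_MS
    window_s: float = DEFAULT_WINDOW_S

    # spectral parameters
    resample_hz: float = DEFAULT_RESAMPLE_HZ
    segment_s: float = DEFAULT_SEGMENT_S
    overlap_fraction: float = DEFAULT_OVERLAP

    # correlation options
    index_columns: tuple[str, ...] = DEFAULT_INDEX_COLUMNS
    indicator_columns: tuple[str, ...] = DEFAULT_INDICATOR_COLUMNS
    aggregate: str | None = None
    bh_fdr: bool = False

    # model selection
    responses: tuple[str, ...] = ("delta_rr_mean", "delta_ln_rmssd")
    candidates: tuple[str, ...] = CANDIDATE_PREDICTORS
    report_top: int = 10

    # prediction / flagging
    predict_model: str = "R1_deltaRR"
    margin_ms: float = 0.0

    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.simulation = SimulationConfig(**sim_raw)
        if "seed" in raw:
            cfg.simulation.seed = cfg.seed
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"pipeline config does not name a {what}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def run_sessions_stage(
    manifest_path: Path,
    rr_root: Path,
    threshold_ms: float,
    window_s: float,
):
    """Assemble QC'd orthostatic sessions from a manifest of RR text files."""
    manifest = pd.read_csv(manifest_path)
    sessions = []
    for (athlete_id, day_index), grp in manifest.groupby(
        ["athlete_id", "day_index"], sort=True
    ):
        by_phase = grp.set_index("phase")["path"]
        series = {
            phase: read_rr_text(rr_root / by_phase.loc[phase])
            for phase in ("supine", "standing")
        }
        sessions.append(
            assemble_session(
                series["supine"],
                series["standing"],
                athlete_id=str(athlete_id),
                day_index=int(day_index),
                threshold_ms=threshold_ms,
                window_s=window_s,
            )
        )
    return sessions


def run_workload_stage(
    traces_dir: Path, profiles: pd.DataFrame, rpe: pd.DataFrame
) -> pd.DataFrame:
    """Zone minutes and Edwards TRIMP per stage from the HR traces."""
    hr_max = profiles.set_index("athlete_id")["hr_max"]
    rpe_map = rpe.set_index(["athlete_id", "day_index"])
    rows = []
    for trace_path in sorted(traces_dir.glob("*.csv")):
        athlete_id, day_part = trace_path.stem.rsplit("_day", maxsplit=1)
        day_index = int(day_part)
        trace = read_hr_trace_csv(trace_path)
        minutes = hr_zone_durations(trace, float(hr_max.loc[athlete_id]))
        key = (athlete_id, day_index)
        rows.append(
            {
                "athlete_id": athlete_id,
                "day_index": day_index,
                **{f"zone{k + 1}_min": minutes[k] for k in range(5)},
                "trimp": edwards_trimp(minutes),
                "rpe": float(rpe_map.loc[key, "rpe"]) if key in rpe_map.index else np.nan,
                "stage_km": float(rpe_map.loc[key, "stage_distance_km"])
                if key in rpe_map.index
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the full artifact set under ``outdir``.

    Idempotent for a fixed config and seed.  Any stage failure raises
    with the stage name; input paths are validated before anything runs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.simulate:
        sim_config = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate_cohort(sim_config, include_rr=True)
        dataset_dir = outdir / "dataset"
        paths = write_cohort_dataset(cohort, dataset_dir)
        manifest_path = paths["manifest"]
        traces_dir = paths["traces"]
        questionnaire_path = paths["questionnaire"]
        profiles_path = paths["profiles"]
        rpe_path = paths["rpe"]
        artifacts.update({f"dataset_{k}": v for k, v in paths.items()})
        log.info("simulate: %d athlete-days", len(cohort.records))
    else:
        manifest_path = _require(config.manifest, "session manifest")
        traces_dir = _require(config.traces_dir, "HR trace directory")
        questionnaire_path = _require(config.questionnaire, "questionnaire CSV")
        profiles_path = _require(config.profiles, "profiles CSV")
        rpe_path = _require(config.rpe, "RPE CSV")

    profiles = pd.read_csv(profiles_path)

    # --- sessions + HRV -------------------------------------------------
    sessions = run_sessions_stage(
        manifest_path, manifest_path.parent, config.threshold_ms, config.window_s
    )
    n_rejected = sum(s.quality_flag == "rejected" for s in sessions)
    log.info("sessions: %d assembled, %d rejected (>=5%% corrected)", len(sessions), n_rejected)
    hrv_df = sessions_table(
        sessions,
        resample_hz=config.resample_hz,
        segment_s=config.segment_s,
        overlap_fraction=config.overlap_fraction,
    )
    artifacts["hrv"] = outdir / "hrv_indices.csv"
    hrv_df.to_csv(artifacts["hrv"], index=False)

    # --- workload -------------------------------------------------------
    rpe_df = pd.read_csv(rpe_path)
    workload_df = run_workload_stage(traces_dir, profiles, rpe_df)
    artifacts["workload"] = outdir / "workload.csv"
    workload_df.to_csv(artifacts["workload"], index=False)
    log.info("workload: %d stage traces", len(workload_df))

    # --- wellbeing ------------------------------------------------------
    questionnaire = pd.read_csv(questionnaire_path)
    wb_df = cohort_delta_wb(questionnaire)
    artifacts["wellbeing"] = outdir / "wellbeing.csv"
    wb_df.to_csv(artifacts["wellbeing"], index=False)
    per_athlete, per_load = wb_vs_training(wb_df, profiles)
    artifacts["wb_vs_training"] = outdir / "wb_vs_training.csv"
    merged_wb = per_athlete.merge(
        per_load, on="training_load", how="left"
    )
    merged_wb.to_csv(artifacts["wb_vs_training"], index=False)

    # --- merged analysis cohort ----------------------------------------
    cohort_df = (
        hrv_df.merge(wb_df, on=["athlete_id", "day_index"], how="left")
        .merge(
            workload_df[["athlete_id", "day_index", "trimp", "rpe", "stage_km"]],
            on=["athlete_id", "day_index"],
            how="left",
        )
        .merge(profiles, on="athlete_id", how="left")
    )
    cohort_df = cohort_df.rename(columns={"stage_km": "stage_distance_km"})
    cohort_df["trimp"] = cohort_df["trimp"].fillna(0.0)
    artifacts["cohort"] = outdir / "cohort_analysis.csv"
    cohort_df.to_csv(artifacts["cohort"], index=False)

    # --- correlations ---------------------------------------------------
    index_cols = [c for c in config.index_columns if c in cohort_df.columns]
    indicator_cols = [c for c in config.indicator_columns if c in cohort_df.columns]
    corr = correlation_table(
        cohort_df,
        index_cols,
        indicator_cols,
        aggregate=config.aggregate,
        bh_fdr=config.bh_fdr,
    )
    artifacts["correlations"] = outdir / "correlations.csv"
    corr.to_csv(artifacts["correlations"], index=False)
    artifacts["correlations_wide"] = outdir / "correlations_wide.csv"
    wide_correlation_table(corr).to_csv(artifacts["correlations_wide"])

    # --- model selection ------------------------------------------------
    for response in config.responses:
        if response not in cohort_df.columns:
            continue
        table = best_subset_search(cohort_df, response, config.candidates)
        path = outdir / f"model_table_{response}.csv"
        table.to_frame().to_csv(path, index=False)
        artifacts[f"model_table_{response}"] = path
        log.info(
            "select-models[%s]: %d fits, best subset %s (AIC %.1f)",
            response,
            len(table),
            "+".join(table.best.predictor_names) or "(intercept)",
            table.best.aic,
        )

    # --- prediction + imbalance flags ----------------------------------
    model = get_published_model(config.predict_model)
    needed = list(model.predictor_names)
    pred_df = cohort_df.dropna(subset=[c for c in needed if c in cohort_df.columns])
    if all(c in pred_df.columns for c in needed) and len(pred_df):
        predicted = predict(model, pred_df[needed])
        flags = pd.DataFrame(
            {
                "athlete_id": pred_df["athlete_id"],
                "day_index": pred_df["day_index"],
                "measured_delta_rr": pred_df["delta_rr_mean"],
                "predicted_delta_rr": predicted,
                "status": [
                    flag_recovery(m, p, config.margin_ms)
                    for m, p in zip(pred_df["delta_rr_mean"], predicted)
                ],
            }
        )
        artifacts["recovery_flags"] = outdir / "recovery_flags.csv"
        flags.to_csv(artifacts["recovery_flags"], index=False)
        log.info(
            "flags: %d sessions, %d imbalance",
            len(flags),
            int((flags["status"] == "imbalance").sum()),
        )

    # --- run manifest ---------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "n_sessions": len(sessions),
        "n_rejected_sessions": n_rejected,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    run_manifest = outdir / "run_manifest.json"
    with open(run_manifest, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    artifacts["run_manifest"] = run_manifest
    return artifacts
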