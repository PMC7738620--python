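"""Synthetic multistage-event cohort with known ground truth.

The raw recordings of the study this pipeline targets are not publicly
deposited, so every downstream stage is exercised against a fully
synthetic cohort whose generative parameters are known: ten athletes, a
26-day calendar (4 baseline days, 21 stages of ~200 km with 2 rest days
interleaved, 1 post-event day), a latent first-order fatigue state
driven by the daily Edwards TRIMP, questionnaire items binned from that
latent state, and an orthostatic mean-RR delta generated from a
configurable linear model (defaulting to the published best predictive
equation) plus Gaussian noise.  Raw RR tachograms are synthesized as a
mean level plus fixed-frequency sinusoids in the HF and LF bands plus
white noise, scaled so the realized mean RR and RMSSD hit their targets
exactly — which makes band placement and delta recovery analytically
checkable.

All randomness flows from one master seed through named substreams, so
identical configurations reproduce byte-identical outputs and individual
pieces can be regenerated independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sessions import OrthostaticSession, RRSeries, write_rr_text
from .workload import edwards_trimp
from .wellbeing import WB_ITEMS

ORTHOSTATIC_PHASE_S = 7 * 60.0  # per-phase recording length


def _substream(seed: int, name: str) -> np.random.Generator:
    """A named, order-independent child stream of the master seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _default_delta_rr_coefficients() -> dict[str, float]:
    # generative truth defaults to the published best delta-RR equation
    return {
        "intercept": 1249.37,
        "vo2max": 12.32,
        "training_load": 0.36,
        "hr_max": -8.83,
        "rpe": -5.90,
        "perceived_fatigue": -28.41,
    }


def _default_item_gains() -> dict[str, float]:
    # perceived fatigue is fatigue-oriented (higher latent fatigue -> higher
    # score); the other three items are well-being-oriented and fall as
    # fatigue accumulates.
    return {
        "perceived_fatigue": 1.0,
        "sleep_quality": -0.8,
        "doms": -0.9,
        "stress": -0.5,
    }


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults emulate the study setting."""

    n_athletes: int = 10
    seed: int = 0

    # athlete profile distribution (truncated normals)
    vo2max_mean: float = 53.6
    vo2max_sd: float = 5.2
    hr_max_mean: float = 185.7
    hr_max_sd: float = 7.2
    training_load_mean: float = 187.5
    training_load_sd: float = 51.5
    years_mean: float = 14.0
    years_sd: float = 8.9

    # event calendar
    n_baseline: int = 4
    n_stages: int = 21
    rest_after_stages: tuple[int, ...] = (9, 15)
    n_post: int = 1
    stage_km_mean: float = 200.0
    stage_km_sd: float = 40.0
    stage_km_min: float = 50.0

    # stage workload plan
    mean_speed_kmh: float = 27.0
    speed_sd_kmh: float = 1.5
    zone_base_fractions: tuple[float, ...] = (0.25, 0.35, 0.25, 0.12, 0.03)
    trace_hz: float = 1.0

    # latent fatigue dynamics
    rho: float = 0.6
    kappa: float = 0.005
    training_attenuates_fatigue: bool = True
    fatigue_center: float = 8.0
    fatigue_spread: float = 4.0
    item_gains: dict[str, float] = field(default_factory=_default_item_gains)
    item_noise_sd: float = 0.7

    # subjective load
    rpe_base: float = 5.0
    rpe_per_km: float = 0.02
    rpe_sd: float = 1.0

    # generative orthostatic response
    delta_rr_coefficients: dict[str, float] = field(
        default_factory=_default_delta_rr_coefficients
    )
    noise_sd: float = 30.0
    standing_rr_base: float = 700.0
    standing_rr_athlete_sd: float = 40.0
    standing_rr_day_sd: float = 10.0
    rmssd_supine_base: float = 60.0
    rmssd_standing_base: float = 25.0

    # tachogram synthesis
    resp_freq: float = 0.25  # Hz, HF band
    lf_freq: float = 0.10    # Hz, LF band
    hf_share: float = 0.75   # quadrature share of RMSSD carried by each part
    lf_share: float = 0.50

    def __post_init__(self) -> None:
        if self.n_athletes < 1:
            raise ValueError("n_athletes must be >= 1")
        for name in (
            "vo2max_sd",
            "hr_max_sd",
            "training_load_sd",
            "years_sd",
            "stage_km_sd",
            "noise_sd",
            "rpe_sd",
            "item_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0.15 <= self.resp_freq <= 0.40:
            raise ValueError("resp_freq must lie in the HF band [0.15, 0.40] Hz")
        if not 0.04 <= self.lf_freq < 0.15:
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.15) Hz")


@dataclass(frozen=True)
class LatentFatigueSeries:
    """Per-day fatigue state from F_t = rho*F_(t-1) + kappa*TRIMP_t, F_0 = 0."""

    values: np.ndarray
    rho: float
    kappa: float


@dataclass
class SyntheticCohort:
    """The generated dataset plus its ground truth."""

    config: SimulationConfig
    profiles: pd.DataFrame
    calendar: pd.DataFrame
    records: pd.DataFrame
    truth: dict
    sessions: list[OrthostaticSession] | None = None


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_athletes(config: SimulationConfig) -> pd.DataFrame:
    """Draw athlete profiles from truncated normals at the configured moments."""
    rng = _substream(config.seed, "athletes")
    n = config.n_athletes
    df = pd.DataFrame(
        {
            "athlete_id": [f"A{i + 1:03d}" for i in range(n)],
            "vo2max": _truncated_normal(
                rng, config.vo2max_mean, config.vo2max_sd, 30.0, 80.0, n
            ),
            "hr_max": _truncated_normal(
                rng, config.hr_max_mean, config.hr_max_sd, 150.0, 220.0, n
            ),
            "training_load": _truncated_normal(
                rng, config.training_load_mean, config.training_load_sd, 50.0, 350.0, n
            ),
            "years_experience": _truncated_normal(
                rng, config.years_mean, config.years_sd, 2.0, 40.0, n
            ),
        }
    )
    return df


def build_event_calendar(config: SimulationConfig) -> pd.DataFrame:
    """Day-by-day event structure with stage distances.

    Baseline days first, then the stages with rest days inserted after
    the configured stage numbers, then the post-event day(s).  Stage
    distances are truncated normals; non-stage days carry distance 0.
    """
    rng = _substream(config.seed, "calendar")
    day_types: list[str] = ["baseline"] * config.n_baseline
    stage_numbers: list[float] = [np.nan] * config.n_baseline
    for s in range(1, config.n_stages + 1):
        day_types.append("stage")
        stage_numbers.append(s)
        if s in config.rest_after_stages and s < config.n_stages:
            day_types.append("rest")
            stage_numbers.append(np.nan)
    day_types += ["post"] * config.n_post
    stage_numbers += [np.nan] * config.n_post
    distances = np.zeros(len(day_types))
    stage_mask = np.array([t == "stage" for t in day_types])
    if stage_mask.any():
        distances[stage_mask] = _truncated_normal(
            rng,
            config.stage_km_mean,
            config.stage_km_sd,
            config.stage_km_min,
            np.inf,
            int(stage_mask.sum()),
        )
    return pd.DataFrame(
        {
            "day_index": np.arange(len(day_types)),
            "day_type": day_types,
            "stage_number": stage_numbers,
            "stage_distance_km": distances,
        }
    )


def fatigue_dynamics(
    trimp_series, rho: float, kappa: float
) -> LatentFatigueSeries:
    """First-order accumulation/decay: F_t = rho*F_(t-1) + kappa*TRIMP_t.

    With zero workload the state decays geometrically by ``rho``; with a
    constant load c it converges to kappa*c/(1-rho).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    trimp = np.asarray(trimp_series, dtype=float)
    if np.any(trimp < 0):
        raise ValueError("TRIMP values must be >= 0")
    values = np.empty(trimp.size)
    state = 0.0
    for t, load in enumerate(trimp):
        state = rho * state + kappa * load
        values[t] = state
    return LatentFatigueSeries(values=values, rho=rho, kappa=kappa)


def plan_stage_workloads(
    profiles: pd.DataFrame, calendar: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Per athlete-day zone-minute plan and its exact Edwards TRIMP.

    Stage duration follows from distance and an athlete-level cruising
    speed; the time split over the five HR zones jitters around the
    configured base fractions.  Non-stage days carry zero workload.
    """
    rng = _substream(config.seed, "workload")
    base = np.asarray(config.zone_base_fractions, dtype=float)
    rows = []
    for athlete in profiles.itertuples():
        speed = float(
            _truncated_normal(
                rng, config.mean_speed_kmh, config.speed_sd_kmh, 18.0, 40.0, 1
            )[0]
        )
        for day in calendar.itertuples():
            if day.day_type != "stage":
                zone_minutes = np.zeros(5)
            else:
                duration_min = day.stage_distance_km / speed * 60.0
                jitter = np.clip(
                    base + rng.normal(0.0, 0.04, size=5), 0.005, None
                )
                fractions = jitter / jitter.sum()
                zone_minutes = fractions * duration_min
            rows.append(
                {
                    "athlete_id": athlete.athlete_id,
                    "day_index": day.day_index,
                    **{f"zone{k + 1}_min": zone_minutes[k] for k in range(5)},
                    "trimp": edwards_trimp(zone_minutes),
                }
            )
    return pd.DataFrame(rows)


def emit_observables(
    profiles: pd.DataFrame,
    calendar: pd.DataFrame,
    fatigue: dict[str, LatentFatigueSeries],
    config: SimulationConfig,
    workload_plan: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the per athlete-day observable records and the ground truth.

    The morning questionnaire items are ordinal bins of the previous
    evening's latent fatigue; RPE rises with stage distance; the
    orthostatic mean-RR delta is the configured linear predictor plus
    Gaussian noise, and the supine/standing mean-RR targets are built to
    reproduce that delta exactly.
    """
    if workload_plan is None:
        workload_plan = plan_stage_workloads(profiles, calendar, config)
    rng = _substream(config.seed, "observables")
    coefs = config.delta_rr_coefficients
    n_days = len(calendar)
    records = []
    truth_lp: dict[str, list[float]] = {}
    truth_fatigue: dict[str, list[float]] = {}
    plan = workload_plan.set_index(["athlete_id", "day_index"])
    for athlete in profiles.itertuples():
        fat = fatigue[athlete.athlete_id]
        if fat.values.size != n_days:
            raise ValueError(
                f"fatigue series for {athlete.athlete_id} has length "
                f"{fat.values.size}, calendar has {n_days} days"
            )
        # morning state on day t is the state after day t-1
        morning = np.concatenate([[0.0], fat.values[:-1]])
        z = (morning - config.fatigue_center) / config.fatigue_spread
        standing_base = config.standing_rr_base + rng.normal(
            0.0, config.standing_rr_athlete_sd
        )
        lp_list, fat_list = [], []
        for t, day in enumerate(calendar.itertuples()):
            items = {}
            for item in WB_ITEMS:
                gain = config.item_gains[item]
                raw = 4.0 + gain * z[t] + rng.normal(0.0, config.item_noise_sd)
                items[item] = int(np.clip(round(raw), 1, 7))
            wb = sum(items.values())
            if day.day_type == "stage":
                rpe = float(
                    np.clip(
                        round(
                            config.rpe_base
                            + config.rpe_per_km
                            * (day.stage_distance_km - config.stage_km_mean)
                            + rng.normal(0.0, config.rpe_sd),
                            1,
                        ),
                        0.0,
                        10.0,
                    )
                )
            else:
                rpe = float("nan")
            rpe_eff = rpe if day.day_type == "stage" else 0.0
            lp = (
                coefs.get("intercept", 0.0)
                + coefs.get("vo2max", 0.0) * athlete.vo2max
                + coefs.get("training_load", 0.0) * athlete.training_load
                + coefs.get("hr_max", 0.0) * athlete.hr_max
                + coefs.get("rpe", 0.0) * rpe_eff
                + coefs.get("perceived_fatigue", 0.0) * items["perceived_fatigue"]
            )
            delta_rr = lp + (
                rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            )
            standing = standing_base + (
                rng.normal(0.0, config.standing_rr_day_sd)
                if config.standing_rr_day_sd > 0
                else 0.0
            )
            supine = standing + delta_rr
            rmssd_sup = float(
                np.clip(
                    config.rmssd_supine_base - 4.0 * (items["perceived_fatigue"] - 4)
                    + rng.normal(0.0, 5.0),
                    8.0,
                    150.0,
                )
            )
            rmssd_sta = float(
                np.clip(
                    config.rmssd_standing_base
                    - 1.5 * (items["perceived_fatigue"] - 4)
                    + rng.normal(0.0, 3.0),
                    5.0,
                    80.0,
                )
            )
            pw = plan.loc[(athlete.athlete_id, day.day_index)]
            records.append(
                {
                    "athlete_id": athlete.athlete_id,
                    "day_index": day.day_index,
                    "day_type": day.day_type,
                    "stage_distance_km": day.stage_distance_km,
                    **{f"zone{k + 1}_min": float(pw[f"zone{k + 1}_min"]) for k in range(5)},
                    "trimp": float(pw["trimp"]),
                    "rpe": rpe,
                    **items,
                    "wb": wb,
                    "delta_rr_mean": delta_rr,
                    "mean_rr_supine": supine,
                    "mean_rr_standing": standing,
                    "rmssd_supine": rmssd_sup,
                    "rmssd_standing": rmssd_sta,
                    "vo2max": athlete.vo2max,
                    "hr_max": athlete.hr_max,
                    "training_load": athlete.training_load,
                    "quality_flag": "ok",
                }
            )
            lp_list.append(lp)
            fat_list.append(float(fat.values[t]))
        truth_lp[athlete.athlete_id] = lp_list
        truth_fatigue[athlete.athlete_id] = fat_list
    truth = {
        "delta_rr_coefficients": dict(coefs),
        "noise_sd": config.noise_sd,
        "rho": config.rho,
        "kappa": config.kappa,
        "linear_predictor": truth_lp,
        "latent_fatigue": truth_fatigue,
    }
    return pd.DataFrame(records), truth


def _tachogram(
    mean_rr: float,
    rmssd_target: float,
    duration_s: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> RRSeries:
    """Beat series = mean + HF sinusoid + LF sinusoid + white noise,
    rescaled so realized mean RR and RMSSD match their targets exactly."""
    if not 300.0 < mean_rr < 2000.0:
        raise ValueError(f"mean RR target {mean_rr} ms outside (300, 2000)")
    if rmssd_target < 0:
        raise ValueError("RMSSD target must be >= 0")
    n = int(np.ceil(duration_s * 1000.0 / mean_rr)) + 2
    if rmssd_target == 0:
        return RRSeries(np.full(n, mean_rr))
    t = np.arange(n) * mean_rr / 1000.0
    hf_share = config.hf_share
    lf_share = config.lf_share
    noise_share = np.sqrt(max(0.0, 1.0 - hf_share**2 - lf_share**2))
    phase_hf, phase_lf = rng.uniform(0.0, 2.0 * np.pi, size=2)
    d = (
        hf_share * np.sin(2.0 * np.pi * config.resp_freq * t + phase_hf)
        + lf_share * np.sin(2.0 * np.pi * config.lf_freq * t + phase_lf)
        + noise_share * rng.standard_normal(n)
    )
    diffs = np.diff(d)
    raw_rmssd = float(np.sqrt(np.mean(diffs * diffs)))
    if raw_rmssd == 0:
        raise ValueError("degenerate modulation; cannot reach a positive RMSSD")
    scale = rmssd_target / raw_rmssd
    x = mean_rr + scale * (d - d.mean())
    if np.any(x <= 0):
        raise ValueError(
            f"infeasible RMSSD target {rmssd_target} ms at mean RR {mean_rr} ms: "
            "modulation amplitude would force non-positive intervals"
        )
    return RRSeries(x)


def simulate_orthostatic_rr(
    mean_rr_supine: float,
    mean_rr_standing: float,
    rmssd_supine: float,
    rmssd_standing: float,
    config: SimulationConfig,
    rng: np.random.Generator | int,
    athlete_id: str = "",
    day_index: int = 0,
) -> OrthostaticSession:
    """Raw (pre-QC) paired supine/standing tachograms spanning >= 7 min each.

    The returned container carries zero corrected fractions and an ``ok``
    flag; quality control happens downstream.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    supine = _tachogram(mean_rr_supine, rmssd_supine, ORTHOSTATIC_PHASE_S, config, rng)
    standing = _tachogram(
        mean_rr_standing, rmssd_standing, ORTHOSTATIC_PHASE_S, config, rng
    )
    return OrthostaticSession(
        athlete_id=athlete_id,
        day_index=day_index,
        supine=supine,
        standing=standing,
        corrected_fraction_supine=0.0,
        corrected_fraction_standing=0.0,
        quality_flag="ok",
    )


def inject_ectopic_artifacts(
    series: RRSeries, fraction: float, rng: np.random.Generator | int
) -> RRSeries:
    """Corrupt a series with premature-beat pairs totalling floor(fraction*n)
    modified beats.

    Each event shortens one interval to 60% of the local mean and
    lengthens the next to preserve cumulative time, the classic
    premature-beat-plus-compensatory-pause signature.  Fractions above
    0.2 are outside the correction design range and rejected.
    """
    if not 0.0 <= fraction <= 0.2:
        raise ValueError("ectopic fraction must lie in [0, 0.2]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    x = series.intervals.copy()
    n = x.size
    n_beats = int(np.floor(fraction * n))
    n_events = n_beats // 2
    if n_events == 0:
        return RRSeries(x)
    candidates = np.arange(5, n - 6)
    rng.shuffle(candidates)
    chosen: list[int] = []
    for i in candidates:
        if all(abs(i - j) >= 3 for j in chosen):
            chosen.append(int(i))
            if len(chosen) == n_events:
                break
    for i in sorted(chosen):
        local = np.concatenate([x[max(0, i - 5) : i], x[i + 2 : i + 7]])
        m = float(local.mean())
        pair_sum = x[i] + x[i + 1]
        x[i] = 0.6 * m
        x[i + 1] = pair_sum - 0.6 * m
    return RRSeries(x)


def simulate_cohort(
    config: SimulationConfig, include_rr: bool = False
) -> SyntheticCohort:
    """Run the full generator: profiles, calendar, workload plan, latent
    fatigue, observable records, and (optionally) raw RR tachograms."""
    profiles = simulate_athletes(config)
    calendar = build_event_calendar(config)
    plan = plan_stage_workloads(profiles, calendar, config)
    fatigue: dict[str, LatentFatigueSeries] = {}
    kappa_truth: dict[str, float] = {}
    for athlete in profiles.itertuples():
        kappa_i = config.kappa
        if config.training_attenuates_fatigue and athlete.training_load > 0:
            kappa_i = config.kappa * (config.training_load_mean / athlete.training_load)
        kappa_truth[athlete.athlete_id] = kappa_i
        trimp = (
            plan[plan["athlete_id"] == athlete.athlete_id]
            .sort_values("day_index")["trimp"]
            .to_numpy()
        )
        fatigue[athlete.athlete_id] = fatigue_dynamics(trimp, config.rho, kappa_i)
    records, truth = emit_observables(profiles, calendar, fatigue, config, plan)
    truth["kappa_per_athlete"] = kappa_truth
    sessions = None
    if include_rr:
        sessions = []
        for row in records.itertuples():
            rng = _substream(
                config.seed, f"tachogram/{row.athlete_id}/{row.day_index}"
            )
            sessions.append(
                simulate_orthostatic_rr(
                    row.mean_rr_supine,
                    row.mean_rr_standing,
                    row.rmssd_supine,
                    row.rmssd_standing,
                    config,
                    rng,
                    athlete_id=row.athlete_id,
                    day_index=int(row.day_index),
                )
            )
    return SyntheticCohort(
        config=config,
        profiles=profiles,
        calendar=calendar,
        records=records,
        truth=truth,
        sessions=sessions,
    )


def _stage_trace(row, hr_max: float, config: SimulationConfig):
    """Piecewise-constant HR trace realizing the planned zone minutes,
    preceded by a 5-min sub-threshold warm-up."""
    midpoints = np.array([0.55, 0.65, 0.75, 0.85, 0.95]) * hr_max
    segments = [(5.0, 0.45 * hr_max)]
    for k in range(5):
        minutes = getattr(row, f"zone{k + 1}_min")
        if minutes > 0:
            segments.append((minutes, midpoints[k]))
    dt = 1.0 / config.trace_hz
    times, hrs = [], []
    t = 0.0
    for minutes, hr in segments:
        n = max(1, int(round(minutes * 60.0 * config.trace_hz)))
        times.append(t + dt * np.arange(n))
        hrs.append(np.full(n, hr))
        t += n * dt
    return np.concatenate(times), np.concatenate(hrs)


def write_cohort_dataset(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the standard exchange set; returns the paths written.

    Layout: profiles.csv, calendar.csv, cohort.csv, questionnaire.csv,
    rpe.csv, ground_truth.json, traces/<athlete>_day<d>.csv (stage days),
    and — when tachograms were generated — rr/<athlete>_day<d>_<phase>.txt
    plus manifest.csv (athlete_id, day_index, phase, path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["profiles"] = outdir / "profiles.csv"
    cohort.profiles.to_csv(paths["profiles"], index=False)
    paths["calendar"] = outdir / "calendar.csv"
    cohort.calendar.to_csv(paths["calendar"], index=False)
    paths["cohort"] = outdir / "cohort.csv"
    cohort.records.to_csv(paths["cohort"], index=False)
    questionnaire = cohort.records[
        ["athlete_id", "day_index", *WB_ITEMS]
    ]
    paths["questionnaire"] = outdir / "questionnaire.csv"
    questionnaire.to_csv(paths["questionnaire"], index=False)
    rpe = cohort.records.loc[
        cohort.records["day_type"] == "stage",
        ["athlete_id", "day_index", "rpe", "stage_distance_km"],
    ]
    paths["rpe"] = outdir / "rpe.csv"
    rpe.to_csv(paths["rpe"], index=False)
    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    traces_dir = outdir / "traces"
    traces_dir.mkdir(exist_ok=True)
    hr_max = cohort.profiles.set_index("athlete_id")["hr_max"]
    for row in cohort.records.itertuples():
        if row.day_type != "stage":
            continue
        times, hrs = _stage_trace(row, float(hr_max.loc[row.athlete_id]), cohort.config)
        pd.DataFrame({"time_s": times, "hr_bpm": hrs}).to_csv(
            traces_dir / f"{row.athlete_id}_day{row.day_index:02d}.csv", index=False
        )
    paths["traces"] = traces_dir
    if cohort.sessions is not None:
        rr_dir = outdir / "rr"
        rr_dir.mkdir(exist_ok=True)
        manifest_rows = []
        for session in cohort.sessions:
            for phase in ("supine", "standing"):
                name = f"{session.athlete_id}_day{session.day_index:02d}_{phase}.txt"
                write_rr_text(getattr(session, phase), rr_dir / name)
                manifest_rows.append(
                    {
                        "athlete_id": session.athlete_id,
                        "day_index": session.day_index,
                        "phase": phase,
                        "path": str(Path("rr") / name),
                    }
                )
        paths["manifest"] = outdir / "manifest.csv"
        pd.DataFrame(manifest_rows).to_csv(paths["manifest"], index=False)
    return paths
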