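"""Objective and subjective stage workload: Edwards TRIMP and RPE.

The internal load of a stage is quantified from the continuous HR trace
by the Edwards training-impulse method: time spent in five heart-rate
zones (50-60, 60-70, 70-80, 80-90 and 90-100% of the individual maximal
HR) is weighted by the zone index,

    TRIMP = 1*z1 + 2*z2 + 3*z3 + 4*z4 + 5*z5   (minutes, weighted)

Time below 50% HRmax carries no load; samples above HRmax clip into
zone 5.  The subjective load is the Borg CR-10 rating of perceived
exertion (RPE, 0-10), recorded shortly after each stage and carried
through as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ZONE_LOWER_FRACTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)
ZONE_WEIGHTS = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True, eq=False)
class HRTrace:
    """A continuous heart-rate recording: (time s, HR bpm) samples."""

    time_s: np.ndarray
    hr_bpm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        hr = np.asarray(self.hr_bpm, dtype=float)
        if t.shape != hr.shape or t.ndim != 1:
            raise ValueError("time_s and hr_bpm must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("HR trace must contain at least one sample")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("HR trace timestamps must be strictly increasing")
        if not np.all(hr > 0):
            raise ValueError("HR values must be positive")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "hr_bpm", hr)

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass(frozen=True)
class WorkloadRecord:
    """Per-stage workload summary."""

    zone_minutes: tuple[float, float, float, float, float]
    trimp: float
    rpe: float
    stage_km: float


def hr_zone_durations(trace: HRTrace, hr_max: float) -> np.ndarray:
    """Minutes spent in each of the five %HRmax zones.

    Duration is attributed sample-and-hold: each sample owns the interval
    up to the next timestamp, and the final sample owns the median
    sampling interval.  Zone k covers [50+10(k-1), 50+10k)% of HRmax for
    k = 1..4; zone 5 is everything at or above 90% (supra-maximal values
    clip into it).  Time below 50% accrues no zone.
    """
    if hr_max <= 0:
        raise ValueError("hr_max must be positive")
    t, hr = trace.time_s, trace.hr_bpm
    if t.size > 1:
        dt = np.diff(t)
        dt = np.append(dt, np.median(dt))
    else:
        dt = np.zeros(1)
    ratio = hr / hr_max
    minutes = np.zeros(5)
    for k in range(5):
        lo = ZONE_LOWER_FRACTIONS[k]
        if k < 4:
            in_zone = (ratio >= lo) & (ratio < lo + 0.1)
        else:
            in_zone = ratio >= lo
        minutes[k] = dt[in_zone].sum() / 60.0
    return minutes


def edwards_trimp(zone_minutes) -> float:
    """Edwards TRIMP: zone minutes weighted by zone index 1-5."""
    z = np.asarray(zone_minutes, dtype=float)
    if z.shape != (5,):
        raise ValueError("expected exactly five zone durations")
    if np.any(z < 0):
        raise ValueError("zone durations must be non-negative")
    return float(np.dot(z, ZONE_WEIGHTS))


def stage_workload(
    trace: HRTrace,
    hr_max: float,
    rpe: float = float("nan"),
    stage_km: float = float("nan"),
) -> WorkloadRecord:
    """Summarize one stage: zone minutes, TRIMP, and carried-through RPE."""
    if not np.isnan(rpe) and not 0.0 <= rpe <= 10.0:
        raise ValueError("RPE must lie on the 0-10 Borg CR-10 scale")
    minutes = hr_zone_durations(trace, hr_max)
    return WorkloadRecord(
        zone_minutes=tuple(minutes),
        trimp=edwards_trimp(minutes),
        rpe=float(rpe),
        stage_km=float(stage_km),
    )


def read_hr_trace_csv(path: str | Path) -> HRTrace:
    """Read a (time_s, hr_bpm) CSV trace."""
    df = pd.read_csv(path)
    return HRTrace(df["time_s"].to_numpy(), df["hr_bpm"].to_numpy())


def write_hr_trace_csv(trace: HRTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "hr_bpm": trace.hr_bpm}).to_csv(
        path, index=False
    )
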