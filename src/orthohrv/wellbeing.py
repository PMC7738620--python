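"""Daily well-being questionnaire scoring and day-to-day change.

Every morning the athlete rates four items — perceived general fatigue,
sleep quality, delayed-onset muscle soreness (DOMS) and stress — each on
a 7-point ordinal scale.  The overall well-being score WB is the plain
sum of the four items (4-28), and the per-stage impact is its day-to-day
change, delta_WB(t) = WB(t) - WB(t-1).  Items are stored exactly as
entered; no orientation reversal is ever applied silently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WB_ITEMS = ("perceived_fatigue", "sleep_quality", "doms", "stress")


def wb_score(
    perceived_fatigue: int, sleep_quality: int, doms: int, stress: int
) -> int:
    """Sum of the four 1-7 questionnaire items (4-28)."""
    total = 0
    for name, value in zip(
        WB_ITEMS, (perceived_fatigue, sleep_quality, doms, stress)
    ):
        if not float(value).is_integer() or not 1 <= int(value) <= 7:
            raise ValueError(f"{name} must be an integer in 1..7, got {value!r}")
        total += int(value)
    return total


def score_entries(entries: pd.DataFrame) -> pd.DataFrame:
    """Add a ``wb`` column to a questionnaire table (items validated)."""
    out = entries.copy()
    out["wb"] = [
        wb_score(r.perceived_fatigue, r.sleep_quality, r.doms, r.stress)
        for r in out.itertuples()
    ]
    return out


def delta_wb_series(entries: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-day WB change for one athlete, plus its mean over defined days.

    ``entries`` must hold one athlete's rows with ``day_index`` and ``wb``
    columns.  delta_wb on day t is defined only when day t-1 has an entry;
    calendar gaps yield missing deltas.  Returns (delta series indexed by
    day_index, mean over defined deltas — NaN when none are defined).
    """
    if entries["day_index"].duplicated().any():
        dupes = sorted(entries.loc[entries["day_index"].duplicated(), "day_index"])
        raise ValueError(f"duplicate day_index values: {dupes}")
    ordered = entries.sort_values("day_index")
    days = ordered["day_index"].to_numpy()
    wb = ordered["wb"].to_numpy(dtype=float)
    delta = np.full(len(ordered), np.nan)
    if len(ordered) > 1:
        consecutive = np.diff(days) == 1
        delta[1:][consecutive] = np.diff(wb)[consecutive]
    series = pd.Series(delta, index=pd.Index(days, name="day_index"), name="delta_wb")
    defined = series.dropna()
    mean = float(defined.mean()) if len(defined) else float("nan")
    return series, mean


def cohort_delta_wb(entries: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`delta_wb_series` athlete by athlete on a cohort table."""
    if "wb" not in entries.columns:
        entries = score_entries(entries)
    parts = []
    for athlete_id, grp in entries.groupby("athlete_id", sort=True):
        series, _ = delta_wb_series(grp)
        part = grp.sort_values("day_index").copy()
        part["delta_wb"] = series.to_numpy()
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def wb_vs_training(
    records: pd.DataFrame, profiles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean daily WB change per athlete against pre-event training volume.

    Returns ``(per_athlete, per_load)``: one row per athlete with her
    weekly training load (km/week) and mean delta_wb, and one aggregate
    row per distinct training load (the mean over athletes sharing it) —
    the table behind the training-level adaptation plot.
    """
    profile_map = profiles.set_index("athlete_id")["training_load"]
    rows = []
    for athlete_id, grp in records.groupby("athlete_id", sort=True):
        if athlete_id not in profile_map.index:
            raise ValueError(f"athlete {athlete_id!r} has no profile")
        scored = grp if "wb" in grp.columns else score_entries(grp)
        _, mean_delta = delta_wb_series(scored)
        rows.append(
            {
                "athlete_id": athlete_id,
                "training_load": float(profile_map.loc[athlete_id]),
                "mean_delta_wb": mean_delta,
            }
        )
    per_athlete = pd.DataFrame(rows)
    per_load = (
        per_athlete.groupby("training_load", as_index=False)["mean_delta_wb"]
        .mean()
        .rename(columns={"mean_delta_wb": "group_mean_delta_wb"})
    )
    return per_athlete, per_load


def plot_wb_vs_training(per_athlete: pd.DataFrame, per_load: pd.DataFrame, ax=None):
    """Scatter mean WB change against weekly training load (no fit drawn)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(
        per_athlete["training_load"],
        per_athlete["mean_delta_wb"],
        "o",
        ms=4,
        color="tab:blue",
        alpha=0.5,
        label="athletes",
    )
    ax.plot(
        per_load["training_load"],
        per_load["group_mean_delta_wb"],
        "o",
        ms=9,
        mfc="none",
        color="tab:blue",
        label="per-load mean",
    )
    ax.set_xlabel("weekly training load (km/week)")
    ax.set_ylabel("mean daily $\\Delta$WB (points)")
    ax.legend()
    return ax
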