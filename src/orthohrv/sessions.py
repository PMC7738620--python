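"""Ingestion and quality control of raw RR-interval recordings.

A morning orthostatic test consists of two consecutive phases — roughly
seven minutes lying supine followed by seven minutes standing — recorded
as a plain-text series of beat-to-beat (RR) intervals in milliseconds,
one value per line (the common Polar/Kubios export layout).  This module
reads those files, corrects ectopic/artifactual beats with a local-median
rule, extracts the last analysis window of each phase, and flags sessions
whose corrected-beat fraction exceeds the acceptable level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

#: Deviation from the local median (ms) beyond which a beat is corrected.
#: This is the "very low" correction level; configurable everywhere.
DEFAULT_THRESHOLD_MS = 450.0

#: Length of the analysis window taken from the end of each phase (s).
DEFAULT_WINDOW_S = 300.0

#: Sessions with at least this fraction of corrected beats are rejected.
REJECT_FRACTION = 0.05

#: Number of nearest accepted neighbours used for the local median.
_NEIGHBOURS = 11


class RRParseError(ValueError):
    """A text RR export contained a token that is not a number."""


class RRValidationError(ValueError):
    """An RR series violates a physical or length constraint."""


@dataclass(frozen=True, eq=False)
class RRSeries:
    """An ordered sequence of beat-to-beat intervals in milliseconds."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1:
            raise RRValidationError("RR intervals must form a 1-D sequence")
        if iv.size and not np.all(iv > 0):
            raise RRValidationError("RR intervals must all be positive")
        object.__setattr__(self, "intervals", iv)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_s(self) -> float:
        """Total recording span in seconds."""
        return float(self.intervals.sum() / 1000.0)

    @property
    def cumulative_time(self) -> np.ndarray:
        """Time of each beat (s), measured from the end of the first interval."""
        return np.cumsum(self.intervals) / 1000.0


@dataclass(frozen=True, eq=False)
class OrthostaticSession:
    """A paired supine/standing recording for one athlete-day, after QC."""

    athlete_id: str
    day_index: int
    supine: RRSeries
    standing: RRSeries
    corrected_fraction_supine: float
    corrected_fraction_standing: float
    quality_flag: str = "ok"  # "ok" | "rejected"


def read_rr_text(path: str | Path) -> RRSeries:
    """Read a plain-text RR export (one interval in ms per line).

    Blank lines and surrounding whitespace are tolerated.  A non-numeric
    token raises :class:`RRParseError` naming the offending line; a
    non-positive interval raises :class:`RRValidationError`.
    """
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.strip()
            if not token:
                continue
            try:
                value = float(token)
            except ValueError:
                raise RRParseError(
                    f"{path}: line {lineno}: {token!r} is not a number"
                ) from None
            if value <= 0:
                raise RRValidationError(
                    f"{path}: line {lineno}: non-positive RR interval {value!r}"
                )
            values.append(value)
    return RRSeries(np.asarray(values, dtype=float))


def write_rr_text(series: RRSeries, path: str | Path) -> None:
    """Write a series in the same one-value-per-line text layout."""
    with open(path, "w") as fh:
        for v in series.intervals:
            fh.write(format(v, ".12g"))
            fh.write("\n")


def _nearest_accepted(accepted: np.ndarray, i: int, k: int) -> list[int]:
    """Indices of the up-to-``k`` accepted beats nearest to ``i`` (excluding i)."""
    n = accepted.size
    out: list[int] = []
    left, right = i - 1, i + 1
    while len(out) < k and (left >= 0 or right < n):
        # prefer the closer side; ties go left for determinism
        dl = i - left if left >= 0 else np.inf
        dr = right - i if right < n else np.inf
        if dl <= dr:
            if accepted[left]:
                out.append(left)
            left -= 1
        else:
            if accepted[right]:
                out.append(right)
            right += 1
    return out


def correct_artifacts(
    series: RRSeries, threshold_ms: float = DEFAULT_THRESHOLD_MS
) -> tuple[RRSeries, float]:
    """Detect and replace artifactual beats with a local-median rule.

    A beat is flagged when it deviates from the median of its 11 nearest
    accepted neighbours by more than ``threshold_ms``.  Flagged beats are
    replaced by monotone piecewise-cubic interpolation over the accepted
    beats, so the beat count is preserved (correction, not deletion).

    Returns the corrected series and the fraction of corrected beats.
    """
    x = series.intervals
    n = x.size
    if n < _NEIGHBOURS + 1:
        raise RRValidationError(
            f"artifact correction needs at least {_NEIGHBOURS + 1} beats, got {n}"
        )
    accepted = np.ones(n, dtype=bool)
    for i in range(n):
        nb = _nearest_accepted(accepted, i, _NEIGHBOURS)
        if not nb:
            continue
        med = float(np.median(x[nb]))
        if abs(x[i] - med) > threshold_ms:
            accepted[i] = False
    if accepted.all():
        return series, 0.0
    good = np.flatnonzero(accepted)
    bad = np.flatnonzero(~accepted)
    if good.size < 2:
        raise RRValidationError("artifact correction flagged nearly every beat")
    interp = PchipInterpolator(good, x[good], extrapolate=True)
    y = x.copy()
    y[bad] = np.clip(interp(bad), 1.0, None)
    return RRSeries(y), bad.size / n


def extract_window(
    series: RRSeries,
    window_s: float = DEFAULT_WINDOW_S,
    take: str = "last",
    label: str = "recording",
) -> RRSeries:
    """Return the minimal suffix of beats spanning at least ``window_s`` seconds.

    Only ``take="last"`` is supported: the analysis uses the final window
    of each phase, once the posture change has settled.  Interval values
    are preserved exactly (no resampling).
    """
    if take != "last":
        raise ValueError(f"unsupported take={take!r}; only 'last' is implemented")
    x = series.intervals
    total_ms = float(x.sum())
    if total_ms < window_s * 1000.0:
        raise RRValidationError(
            f"{label} spans {total_ms / 1000.0:.1f} s, shorter than the "
            f"{window_s:.0f} s analysis window"
        )
    rev_cum = np.cumsum(x[::-1])
    k = int(np.searchsorted(rev_cum, window_s * 1000.0, side="left")) + 1
    return RRSeries(x[-k:])


def assemble_session(
    supine: RRSeries,
    standing: RRSeries,
    athlete_id: str = "",
    day_index: int = 0,
    threshold_ms: float = DEFAULT_THRESHOLD_MS,
    window_s: float = DEFAULT_WINDOW_S,
) -> OrthostaticSession:
    """Correct, window, and quality-flag one paired supine/standing recording.

    Each phase is artifact-corrected and then reduced to its last
    ``window_s`` seconds.  The session is flagged ``rejected`` when either
    phase needed >= 5% of its beats corrected.
    """
    if len(supine) == 0 or len(standing) == 0:
        raise RRValidationError("both phases must contain at least one beat")
    phases = {}
    fractions = {}
    for name, phase in (("supine", supine), ("standing", standing)):
        try:
            corrected, frac = correct_artifacts(phase, threshold_ms=threshold_ms)
            phases[name] = extract_window(corrected, window_s=window_s, label=name)
        except (RRValidationError, RRParseError) as exc:
            raise RRValidationError(f"{name} phase: {exc}") from exc
        fractions[name] = frac
    flag = (
        "rejected"
        if max(fractions["supine"], fractions["standing"]) >= REJECT_FRACTION
        else "ok"
    )
    return OrthostaticSession(
        athlete_id=athlete_id,
        day_index=day_index,
        supine=phases["supine"],
        standing=phases["standing"],
        corrected_fraction_supine=fractions["supine"],
        corrected_fraction_standing=fractions["standing"],
        quality_flag=flag,
    )
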