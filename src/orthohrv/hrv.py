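"""Time- and frequency-domain HRV indices and orthostatic delta statistics.

Per phase (supine or standing) the module computes mean RR, mean HR,
RMSSD and its natural log, and Welch-periodogram band powers: LF
(0.04-0.15 Hz), HF (0.15-0.40 Hz), their normalized units
HFnu = HF/(LF+HF), LFnu = LF/(LF+HF), and the LF/HF ratio.  Per session
it computes the orthostatic deltas, supine minus standing:

    delta_rr_mean   = mean RR(supine)  - mean RR(standing)
    delta_rmssd     = RMSSD(supine)    - RMSSD(standing)
    delta_ln_rmssd  = LnRMSSD(supine)  - LnRMSSD(standing)

A normal stand-up response shortens RR (vagal withdrawal), so the deltas
are positive; a blunted (low) delta marks a maladaptive stress-recovery
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .sessions import OrthostaticSession, RRSeries, RRValidationError

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)   # half-open [0.04, 0.15)
HF_BAND = (0.15, 0.40)   # closed top [0.15, 0.40]

#: Band powers below this floor (ms^2) are treated as numerically zero,
#: in which case the normalized units are undefined (NaN).
POWER_FLOOR = 1e-10

DEFAULT_RESAMPLE_HZ = 4.0
DEFAULT_SEGMENT_S = 150.0
DEFAULT_OVERLAP = 0.5


@dataclass(frozen=True)
class SpectralPowers:
    vlf_abs: float
    lf_abs: float
    hf_abs: float
    lf_nu: float
    hf_nu: float
    lf_hf_ratio: float


@dataclass(frozen=True)
class PhaseIndices:
    """All per-phase HRV indices; undefined values are NaN."""

    mean_rr: float
    mean_hr: float
    rmssd: float
    ln_rmssd: float
    lf_abs: float
    hf_abs: float
    lf_nu: float
    hf_nu: float
    lf_hf_ratio: float


@dataclass(frozen=True)
class DeltaIndices:
    delta_rr_mean: float
    delta_rmssd: float
    delta_ln_rmssd: float


def time_domain_indices(series: RRSeries) -> tuple[float, float, float, float]:
    """Return ``(mean_rr, mean_hr, rmssd, ln_rmssd)`` for one phase.

    RMSSD is the root mean square of successive RR differences.  A zero
    RMSSD (constant series) yields ``ln_rmssd = NaN`` rather than -inf so
    cohort tables stay numeric.
    """
    x = series.intervals
    if x.size < 2:
        raise RRValidationError("RMSSD needs at least two beats")
    mean_rr = float(x.mean())
    mean_hr = 60000.0 / mean_rr
    diffs = np.diff(x)
    rmssd = float(math.sqrt(np.mean(diffs * diffs)))
    ln_rmssd = math.log(rmssd) if rmssd > 0 else float("nan")
    return mean_rr, mean_hr, rmssd, ln_rmssd


def spectral_powers(
    series: RRSeries,
    resample_hz: float = DEFAULT_RESAMPLE_HZ,
    segment_s: float = DEFAULT_SEGMENT_S,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> SpectralPowers:
    """Welch band powers of the RR tachogram (ms^2).

    The irregularly sampled tachogram (interval vs cumulative beat time)
    is cubic-spline resampled onto a uniform grid, linearly detrended per
    segment, and analysed with Hann-tapered Welch segments.  LF power is
    integrated over [0.04, 0.15) Hz and HF over [0.15, 0.40] Hz, so no
    frequency bin is counted twice; VLF (< 0.04 Hz) is computed but never
    enters the normalized-unit denominator.
    """
    x = series.intervals
    t = series.cumulative_time
    if t.size < 4 or t[-1] - t[0] < segment_s:
        raise RRValidationError(
            f"spectral analysis needs at least one {segment_s:.0f} s segment"
        )
    spline = CubicSpline(t, x)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    resampled = spline(grid)
    nperseg = int(round(segment_s * resample_hz))
    freqs, psd = welch(
        resampled,
        fs=resample_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_fraction)),
        detrend="linear",
    )
    df = float(freqs[1] - freqs[0])
    vlf = float(psd[(freqs >= VLF_BAND[0]) & (freqs < VLF_BAND[1])].sum() * df)
    lf = float(psd[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])].sum() * df)
    hf = float(psd[(freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])].sum() * df)
    total = lf + hf
    if total > POWER_FLOOR:
        lf_nu = lf / total
        hf_nu = hf / total
    else:
        lf_nu = hf_nu = float("nan")
    ratio = lf / hf if hf > POWER_FLOOR else float("nan")
    return SpectralPowers(vlf, lf, hf, lf_nu, hf_nu, ratio)


def phase_indices(
    series: RRSeries,
    spectral: bool = True,
    resample_hz: float = DEFAULT_RESAMPLE_HZ,
    segment_s: float = DEFAULT_SEGMENT_S,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> PhaseIndices:
    """Compute the full per-phase index set (spectral part optional)."""
    mean_rr, mean_hr, rmssd, ln_rmssd = time_domain_indices(series)
    if spectral:
        sp = spectral_powers(series, resample_hz, segment_s, overlap_fraction)
        lf_abs, hf_abs = sp.lf_abs, sp.hf_abs
        lf_nu, hf_nu, ratio = sp.lf_nu, sp.hf_nu, sp.lf_hf_ratio
    else:
        lf_abs = hf_abs = lf_nu = hf_nu = ratio = float("nan")
    return PhaseIndices(
        mean_rr, mean_hr, rmssd, ln_rmssd, lf_abs, hf_abs, lf_nu, hf_nu, ratio
    )


def orthostatic_deltas(supine: PhaseIndices, standing: PhaseIndices) -> DeltaIndices:
    """Supine-minus-standing deltas; an undefined LnRMSSD propagates as NaN."""
    return DeltaIndices(
        delta_rr_mean=supine.mean_rr - standing.mean_rr,
        delta_rmssd=supine.rmssd - standing.rmssd,
        delta_ln_rmssd=supine.ln_rmssd - standing.ln_rmssd,
    )


def session_indices(session: OrthostaticSession, **spectral_kw) -> dict:
    """One flat row of per-phase indices and deltas for a session."""
    row: dict = {
        "athlete_id": session.athlete_id,
        "day_index": session.day_index,
        "quality_flag": session.quality_flag,
        "corrected_fraction_supine": session.corrected_fraction_supine,
        "corrected_fraction_standing": session.corrected_fraction_standing,
    }
    per_phase = {}
    for name, series in (("supine", session.supine), ("standing", session.standing)):
        idx = phase_indices(series, **spectral_kw)
        per_phase[name] = idx
        for fld in (
            "mean_rr",
            "mean_hr",
            "rmssd",
            "ln_rmssd",
            "lf_abs",
            "hf_abs",
            "lf_nu",
            "hf_nu",
            "lf_hf_ratio",
        ):
            row[f"{fld}_{name}"] = getattr(idx, fld)
    deltas = orthostatic_deltas(per_phase["supine"], per_phase["standing"])
    row["delta_rr_mean"] = deltas.delta_rr_mean
    row["delta_rmssd"] = deltas.delta_rmssd
    row["delta_ln_rmssd"] = deltas.delta_ln_rmssd
    return row


def sessions_table(sessions: Iterable[OrthostaticSession], **spectral_kw) -> pd.DataFrame:
    """Stack :func:`session_indices` rows into a tidy per-session table."""
    return pd.DataFrame([session_indices(s, **spectral_kw) for s in sessions])
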