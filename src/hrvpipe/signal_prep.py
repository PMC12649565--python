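"""RR-interval preprocessing: instantaneous heart rate, uniform resampling,
signal-quality scoring and analysis-window extraction.

The pipeline starts from detected beat times and RR intervals (no ECG
waveform processing).  Heart rate is computed per beat, averaged in a
centred moving window of ``tau`` seconds and resampled on a uniform grid
(default 20 Hz).  Ten-minute analysis windows are taken from the beginning
and end of each recording, each gated by a signal-quality index (SQI); a
window below the SQI threshold is replaced by its fallback candidate or
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default uniform sampling rate of the smoothed HR signal, Hz
DEFAULT_FS = 20.0
#: default moving-average width, seconds
DEFAULT_TAU = 2.0
#: analysis-window length, seconds
WINDOW_S = 600.0
#: SQI threshold below which a window is rejected
SQI_THRESHOLD = 0.9
#: physiological plausibility bounds on RR, ms
RR_PLAUSIBLE_MS = (250.0, 1800.0)
#: plausibility bounds on the ratio of successive RR intervals
RR_RATIO_BOUNDS = (0.7, 1.3)


@dataclass
class RRSeries:
    """A single recording: beat times (s, strictly increasing) and RR (ms).

    ``artifact_flags`` marks beats known to be corrupted (ectopic-like or
    merged); it is optional and defaults to all-clean.
    """

    beat_times: np.ndarray
    rr: np.ndarray
    artifact_flags: Optional[np.ndarray] = None
    subject: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.beat_times.shape != self.rr.shape:
            raise ValueError("beat_times and rr must have equal length")
        if self.beat_times.size == 0:
            raise ValueError("empty RR series")
        if not np.all(np.isfinite(self.beat_times)) or not np.all(np.isfinite(self.rr)):
            raise ValueError("beat_times and rr must be finite")
        if np.any(self.rr <= 0):
            raise ValueError("rr intervals must be positive")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.rr.size, dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if self.artifact_flags.shape != self.rr.shape:
                raise ValueError("artifact_flags must match rr length")

    @property
    def duration(self) -> float:
        """Recording span in seconds (start anchored at t = 0)."""
        return float(self.beat_times[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beat_time_s": self.beat_times, "rr_ms": self.rr,
             "artifact": self.artifact_flags.astype(int)}
        )

    @classmethod
    def from_csv(cls, path, subject: str = "", visit: str = "") -> "RRSeries":
        df = pd.read_csv(path)
        flags = df["artifact"].to_numpy(dtype=bool) if "artifact" in df else None
        return cls(df["beat_time_s"].to_numpy(), df["rr_ms"].to_numpy(),
                   artifact_flags=flags, subject=subject, visit=visit)


@dataclass
class UniformHRSeries:
    """Low-pass-filtered HR (bpm) on a uniform grid.

    Grid points whose averaging window contains no beat are NaN; they are
    explicit missing markers, never interpolated.
    """

    values: np.ndarray
    fs: float = DEFAULT_FS
    tau: float = DEFAULT_TAU
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.fs

    def segment(self, start_s: float, end_s: float) -> "UniformHRSeries":
        """Half-open slice [start_s, end_s) of the grid."""
        i0 = int(np.ceil((start_s - self.start_time) * self.fs - 1e-9))
        i1 = int(np.ceil((end_s - self.start_time) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.values.size)
        return UniformHRSeries(self.values[i0:i1], fs=self.fs, tau=self.tau,
                               start_time=self.start_time + i0 / self.fs)


@dataclass
class AnalysisWindow:
    """A 600-s SQI-gated HR segment for one subject/visit/position."""

    subject: str
    visit: str
    position: str  # "begin" or "end"
    samples: UniformHRSeries
    sqi: float
    source_interval: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.sqi <= 1.0:
            raise ValueError("sqi must lie in [0, 1]")


def rr_to_hr(rr: RRSeries) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous heart rate at each beat: HR_i = 60000 / rr_ms_i.

    Returns ``(beat_times_s, hr_bpm)``.
    """
    return rr.beat_times, 60000.0 / rr.rr


def smooth_resample(
    beat_times: np.ndarray,
    hr: np.ndarray,
    tau: float = DEFAULT_TAU,
    fs: float = DEFAULT_FS,
    start_time: Optional[float] = None,
    end_time: Optional[float] = None,
    rr_ms: Optional[np.ndarray] = None,
) -> UniformHRSeries:
    """Centred moving-average of the instantaneous HR onto a uniform grid.

    The instantaneous HR is treated as a piecewise-constant function of
    time (beat i's value holds over the interval that beat spans); the
    value at grid time t is its time-weighted mean over [t - tau/2,
    t + tau/2).  Portions of the window covered by no beat (dropouts,
    recording edges) are excluded from the average, and a grid point whose
    window has zero coverage is NaN.  Time-weighting keeps the output
    continuously varying - an equally-weighted mean of the beat samples
    would be piecewise constant at 20 Hz, which degenerates the downstream
    nearest-neighbour entropy estimator.  The operation is linear in the
    HR values and shift-equivariant.

    ``rr_ms`` (interval durations) locates each beat's coverage segment;
    when omitted, segments are taken contiguous between successive beats.
    """
    if tau <= 0 or fs <= 0:
        raise ValueError("tau and fs must be positive")
    beat_times = np.asarray(beat_times, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if beat_times.size == 0:
        raise ValueError("cannot resample an empty series")
    seg_end = beat_times
    if rr_ms is not None:
        seg_start = beat_times - np.asarray(rr_ms, dtype=float) / 1000.0
    else:
        seg_start = np.empty_like(beat_times)
        seg_start[1:] = beat_times[:-1]
        med = np.median(np.diff(beat_times)) if beat_times.size > 1 else 1.0
        seg_start[0] = beat_times[0] - med
    # forbid overlap: a segment may not start before the previous one ends
    seg_start[1:] = np.maximum(seg_start[1:], seg_end[:-1])
    seg_start = np.minimum(seg_start, seg_end)

    # piecewise-linear cumulatives at interleaved breakpoints:
    # F integrates HR (slope hr inside a segment, 0 in gaps); G integrates
    # coverage (slope 1 inside, 0 in gaps)
    dur = seg_end - seg_start
    bp = np.empty(2 * beat_times.size)
    bp[0::2], bp[1::2] = seg_start, seg_end
    f_cum = np.empty_like(bp)
    g_cum = np.empty_like(bp)
    f_inc = np.cumsum(hr * dur)
    g_inc = np.cumsum(dur)
    f_cum[1::2], g_cum[1::2] = f_inc, g_inc
    f_cum[0::2], g_cum[0::2] = f_inc - hr * dur, g_inc - dur
    # de-duplicate identical breakpoints (contiguous segments)
    bp, idx = np.unique(bp, return_index=True)
    f_cum, g_cum = f_cum[idx], g_cum[idx]

    t0 = seg_start[0] if start_time is None else float(start_time)
    t1 = beat_times[-1] if end_time is None else float(end_time)
    n = int(np.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    f_hi = np.interp(grid + tau / 2.0, bp, f_cum)
    f_lo = np.interp(grid - tau / 2.0, bp, f_cum)
    g_hi = np.interp(grid + tau / 2.0, bp, g_cum)
    g_lo = np.interp(grid - tau / 2.0, bp, g_cum)
    cover = g_hi - g_lo
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(cover > 1e-9, (f_hi - f_lo) / np.where(cover > 0, cover, 1.0),
                          np.nan)
    return UniformHRSeries(values, fs=fs, tau=tau, start_time=t0)


def compute_sqi(rr: RRSeries, interval: tuple[float, float]) -> float:
    """Signal-confidence index of an interval: valid-beat temporal coverage.

    A beat is valid when it is not artifact-flagged, its RR lies within
    physiological bounds (250-1800 ms) and the ratio to the previous RR lies
    in [0.7, 1.3] (the first beat is exempt from the ratio rule).  The SQI
    is the fraction of the interval's duration covered by valid beats; it is
    1.0 for a clean recording, falls with every artifact or dropout, and is
    0.0 when no valid beat covers the interval.
    """
    start, end = float(interval[0]), float(interval[1])
    if end <= start:
        raise ValueError("interval must have positive length")
    if start < -1e-9 or end > rr.duration + 1e-9:
        raise ValueError(
            f"interval ({start}, {end}) outside recording span (0, {rr.duration})"
        )
    lo_ms, hi_ms = RR_PLAUSIBLE_MS
    lo_ratio, hi_ratio = RR_RATIO_BOUNDS
    plaus = (rr.rr >= lo_ms) & (rr.rr <= hi_ms)
    ratio = np.ones(rr.rr.size)
    ratio[1:] = rr.rr[1:] / rr.rr[:-1]
    plaus &= (ratio >= lo_ratio) & (ratio <= hi_ratio)
    valid = plaus & ~rr.artifact_flags
    # beat i covers (beat_times[i] - rr_i/1000, beat_times[i]]
    b_end = rr.beat_times
    b_start = b_end - rr.rr / 1000.0
    cover = np.clip(np.minimum(b_end, end) - np.maximum(b_start, start), 0.0, None)
    covered = float(np.sum(cover[valid]))
    return min(covered / (end - start), 1.0)


def extract_windows(
    rr: RRSeries,
    sqi_threshold: float = SQI_THRESHOLD,
    tau: float = DEFAULT_TAU,
    fs: float = DEFAULT_FS,
    window_s: float = WINDOW_S,
) -> dict[str, Optional[AnalysisWindow]]:
    """Extract the begin and end analysis windows with fallback rules.

    begin: minutes 10-20 of the recording if its SQI passes, else minutes
    20-30, else absent.  end: the final 10 minutes if its SQI passes, else
    the penultimate 10 minutes, else absent.  Returned windows always carry
    SQI >= threshold.
    """
    out: dict[str, Optional[AnalysisWindow]] = {"begin": None, "end": None}
    T = rr.duration
    hr_t, hr_v = rr_to_hr(rr)

    def try_candidates(position: str, candidates: list[tuple[float, float]]) -> None:
        for (a, b) in candidates:
            if a < 0 or b > T:
                logger.info("%s/%s %s candidate (%.0f, %.0f) outside recording",
                            rr.subject, rr.visit, position, a, b)
                continue
            sqi = compute_sqi(rr, (a, b))
            if sqi >= sqi_threshold:
                seg = smooth_resample(hr_t, hr_v, tau=tau, fs=fs,
                                      start_time=a, end_time=b, rr_ms=rr.rr)
                # drop the grid point at b itself to keep duration 600 s
                seg = UniformHRSeries(seg.values[: int(round(window_s * fs))],
                                      fs=fs, tau=tau, start_time=a)
                out[position] = AnalysisWindow(rr.subject, rr.visit, position,
                                               seg, sqi, (a, b))
                return
            logger.info("%s/%s %s candidate (%.0f, %.0f) rejected, sqi=%.3f",
                        rr.subject, rr.visit, position, a, b, sqi)

    if T < 2 * window_s:
        logger.info("%s/%s recording too short (%.0f s) for a begin window",
                    rr.subject, rr.visit, T)
    else:
        try_candidates("begin", [(window_s, 2 * window_s),
                                 (2 * window_s, 3 * window_s)])
    if T >= window_s:
        try_candidates("end", [(T - window_s, T),
                               (T - 2 * window_s, T - window_s)])
    return out


def window_manifest(windows: list[AnalysisWindow]) -> pd.DataFrame:
    """Tidy accounting table of extracted windows."""
    rows = [
        {"subject": w.subject, "visit": w.visit, "position": w.position,
         "sqi": w.sqi, "start_s": w.source_interval[0],
         "end_s": w.source_interval[1], "included": w.sqi >= SQI_THRESHOLD}
        for w in windows
    ]
    return pd.DataFrame(rows)
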