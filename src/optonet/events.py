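"""Calcium-event detection and characterization on ΔF/F traces.

An event opens when ΔF/F crosses the detection threshold upward, peaks at
the local maximum, and closes when the trace falls back below a fraction
of that peak. Each event is summarised by its amplitude (maximum ΔF/F
over baseline), rise time (time from onset crossing to peak) and fall
time constant (exponential decay fitted to the post-peak segment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import TraceMatrix

__all__ = ["CalciumEvent", "detect_events", "characterize_event", "events_table"]


@dataclass
class CalciumEvent:
    """One detected calcium transient.

    ``fall_tau`` is ``None`` when the post-peak segment is too short for a
    decay fit (fewer than 3 usable frames); the event is still reported.
    """

    onset: float  # s
    peak_time: float  # s
    amplitude: float  # ΔF/F
    rise_time: float  # s
    fall_tau: float | None  # s
    roi: int | None = None


def _fit_fall_tau(
    y: np.ndarray, peak_idx: int, end: int, frame_rate: float, floor_fraction: float = 0.2
) -> float | None:
    """Log-linear LSQ exponential fit of the decay from peak to 20% of peak."""
    peak = y[peak_idx]
    seg_end = end
    for k in range(peak_idx + 1, end):
        if y[k] < floor_fraction * peak:
            seg_end = k + 1
            break
    seg = y[peak_idx:seg_end]
    pos = seg > 0
    if pos.sum() < 3:
        return None
    t = np.arange(seg.size)[pos] / frame_rate
    slope, _ = np.polyfit(t, np.log(seg[pos]), 1)
    if slope >= 0:
        return None
    return float(-1.0 / slope)


def characterize_event(
    dff: np.ndarray,
    window: tuple[int, int],
    frame_rate: float,
    floor_fraction: float = 0.2,
) -> CalciumEvent:
    """Characterize the single event inside a frame window.

    Amplitude is the window maximum of ΔF/F; the onset is the first frame
    of the window (the detector passes the threshold-crossing frame, with
    no sub-frame extrapolation); rise time is onset-to-peak; the fall time
    constant comes from a log-linear least-squares exponential fit of the
    segment from the peak down to ``floor_fraction`` of the peak.
    """
    start, end = int(window[0]), int(window[1])
    y = np.asarray(dff, dtype=float).ravel()
    if not (0 <= start < end <= y.size):
        raise ValueError("window out of range")
    seg = y[start:end]
    peak_idx = start + int(np.argmax(seg))
    amplitude = float(y[peak_idx])
    return CalciumEvent(
        onset=start / frame_rate,
        peak_time=peak_idx / frame_rate,
        amplitude=amplitude,
        rise_time=(peak_idx - start) / frame_rate,
        fall_tau=_fit_fall_tau(y, peak_idx, end, frame_rate, floor_fraction),
    )


def detect_events(
    dff: np.ndarray,
    frame_rate: float,
    threshold: float = 0.2,
    min_separation: float = 0.5,
    close_fraction: float = 0.2,
) -> list[CalciumEvent]:
    """Detect calcium events in one ΔF/F trace.

    The trace is scanned for upward threshold crossings; each event
    extends past its peak until ΔF/F drops below ``close_fraction`` of
    the running peak (or a new suprathreshold excursion begins). Events
    whose onset follows the previous event's close by less than
    ``min_separation`` seconds are merged into a single event. A quiet
    trace returns an empty list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    y = np.asarray(dff, dtype=float).ravel()
    T = y.size
    windows: list[list[int]] = []
    i = 0
    while i < T:
        if y[i] > threshold:
            start = i
            peak = y[i]
            j = i + 1
            while j < T:
                if y[j] > peak:
                    peak = y[j]
                if y[j] < close_fraction * peak:
                    break
                j += 1
            end = min(j + 1, T)
            gap_frames = int(round(min_separation * frame_rate))
            if windows and start - windows[-1][1] < gap_frames:
                windows[-1][1] = end
            else:
                windows.append([start, end])
            i = end
        else:
            i += 1
    return [characterize_event(y, (s, e), frame_rate, close_fraction) for s, e in windows]


def events_table(
    dff: TraceMatrix,
    threshold: float = 0.2,
    min_separation: float = 0.5,
    close_fraction: float = 0.2,
) -> pd.DataFrame:
    """Detect events on every ROI; one row per event.

    Columns: roi, onset, peak_time, amplitude, rise_time, fall_tau.
    """
    rows = []
    for j in range(dff.n_rois):
        for ev in detect_events(
            dff.data[:, j], dff.frame_rate, threshold, min_separation, close_fraction
        ):
            ev.roi = j
            rows.append(
                {
                    "roi": j,
                    "onset": ev.onset,
                    "peak_time": ev.peak_time,
                    "amplitude": ev.amplitude,
                    "rise_time": ev.rise_time,
                    "fall_tau": ev.fall_tau,
                }
            )
    return pd.DataFrame(
        rows, columns=["roi", "onset", "peak_time", "amplitude", "rise_time", "fall_tau"]
    )
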