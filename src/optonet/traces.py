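"""ΔF/F computation with photobleaching baseline correction.

Raw somatic fluorescence decays slowly under continuous illumination
(photobleaching) on top of a static camera background. The baseline is
modelled as ``a · exp(−t/τ) + c`` and estimated by a two-pass ("double")
fit: an ordinary least-squares fit over the whole trace, followed by a
refit after masking out frames whose positive residual marks a calcium
transient. ΔF/F is then (F − F_baseline) / F_baseline, which has zero
median over baseline frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TraceMatrix",
    "BaselineFit",
    "noise_sd",
    "fit_baseline",
    "fit_baselines",
    "dff",
    "dff_matrix",
]


@dataclass
class TraceMatrix:
    """Per-ROI time series, one column per ROI.

    ``kind`` labels the processing stage: "raw", "baseline" or "dff".
    """

    data: np.ndarray  # (n_frames, n_rois)
    frame_rate: float
    kind: str = "raw"

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("trace data must be 2-D (frames × ROIs)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate


def _exp_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


@dataclass
class BaselineFit:
    """Fitted photobleaching baseline ``a · exp(−t/τ) + c`` for one trace.

    ``inlier_mask`` is True on frames used by the second-pass fit (i.e.
    frames not flagged as transients). ``first_pass`` keeps the
    (a, τ, c) of the initial all-frames fit for diagnostics. When the fit
    degenerates, ``fallback`` is True and the baseline is the constant
    ``offset`` (a low percentile of the trace).
    """

    amplitude: float
    decay_tau: float
    offset: float
    inlier_mask: np.ndarray
    frame_rate: float
    fallback: bool = False
    first_pass: tuple[float, float, float] | None = None

    def predict(self, t: np.ndarray | None = None) -> np.ndarray:
        """Baseline curve evaluated at times ``t`` (defaults to the fitted frames)."""
        if t is None:
            t = np.arange(self.inlier_mask.size) / self.frame_rate
        t = np.asarray(t, dtype=float)
        if self.fallback:
            return np.full_like(t, self.offset)
        return _exp_model(t, self.amplitude, self.decay_tau, self.offset)


def noise_sd(trace: np.ndarray) -> float:
    """Robust frame-to-frame noise SD from first differences.

    ``1.4826 · median(|ΔF|) / √2`` — calcium transients are smooth and
    sparse relative to the frame interval, so successive differences are
    dominated by sensor noise even on traces dense with events.
    """
    d = np.diff(np.asarray(trace, dtype=float).ravel())
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def fit_baseline(
    trace: np.ndarray,
    frame_rate: float,
    exclusion_threshold: float = 2.5,
    mask_extend: float = 4.0,
    min_frames: int = 20,
    fallback_percentile: float = 10.0,
) -> BaselineFit:
    """Two-pass exponential-decay baseline fit of one raw trace.

    Pass 1 fits ``a·exp(−t/τ) + c`` to every frame. Frames whose residual
    exceeds ``exclusion_threshold`` noise SDs above the fit are flagged
    as calcium transients; because an indicator transient decays over
    seconds, the flag is extended ``mask_extend`` seconds forward (and
    one rise time, 0.3 s, backward) so the sub-threshold decay tail is
    excluded too. Negative excursions are never masked (the indicator
    reports positive-going events). Pass 2 refits on the surviving
    frames. The noise SD comes from first differences of the trace
    (:func:`noise_sd`), not from the pass-1 residuals, which are inflated
    when transients occupy much of the recording. If the optimiser fails
    or fewer than ``min_frames`` frames survive, the result falls back to
    a constant baseline at ``fallback_percentile`` of the trace, with
    ``fallback=True``.
    """
    y = np.asarray(trace, dtype=float).ravel()
    if y.size < min_frames:
        raise ValueError(f"trace has {y.size} frames; at least {min_frames} required")
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    t = np.arange(y.size) / frame_rate
    duration = max(t[-1], 1.0 / frame_rate)

    def _fallback():
        return BaselineFit(
            amplitude=0.0,
            decay_tau=np.inf,
            offset=float(np.percentile(y, fallback_percentile)),
            inlier_mask=np.ones(y.size, dtype=bool),
            frame_rate=frame_rate,
            fallback=True,
        )

    lo = float(np.percentile(y, fallback_percentile))
    p0 = (max(y[0] - lo, 1e-6), duration / 2.0, lo)
    # τ capped at 50 × the recording length: beyond that the exponential is
    # indistinguishable from a line and the fit degenerates.
    bounds = ([0.0, 1e-1, -np.inf], [np.inf, 50.0 * duration, np.inf])
    try:
        p1, _ = curve_fit(_exp_model, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return _fallback()

    resid = y - _exp_model(t, *p1)
    sd = noise_sd(y)
    if sd > 0:
        transient = resid > exclusion_threshold * sd
        fwd = int(round(mask_extend * frame_rate))
        back = int(round(0.3 * frame_rate))
        for i in np.flatnonzero(transient):
            transient[max(i - back, 0) : i + fwd + 1] = True
        inliers = ~transient
    else:
        inliers = np.ones(y.size, dtype=bool)
    if inliers.sum() < min_frames:
        return _fallback()

    try:
        p2, _ = curve_fit(
            _exp_model, t[inliers], y[inliers], p0=tuple(p1), bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        return _fallback()

    return BaselineFit(
        amplitude=float(p2[0]),
        decay_tau=float(p2[1]),
        offset=float(p2[2]),
        inlier_mask=inliers,
        frame_rate=frame_rate,
        first_pass=tuple(float(v) for v in p1),
    )


def fit_baselines(traces: TraceMatrix, **kwargs) -> list[BaselineFit]:
    """Fit a baseline for every column of a raw TraceMatrix."""
    return [fit_baseline(traces.data[:, j], traces.frame_rate, **kwargs) for j in range(traces.n_rois)]


def dff(trace: np.ndarray, baseline: BaselineFit) -> np.ndarray:
    """ΔF/F(t) = (F(t) − F_base(t)) / F_base(t).

    Raises ``ValueError`` (naming the first offending frame) if the
    baseline is not strictly positive everywhere.
    """
    y = np.asarray(trace, dtype=float).ravel()
    t = np.arange(y.size) / baseline.frame_rate
    base = baseline.predict(t)
    bad = np.flatnonzero(base <= 0)
    if bad.size:
        raise ValueError(f"baseline is non-positive at frame {bad[0]}")
    return (y - base) / base


def dff_matrix(traces: TraceMatrix, baselines: list[BaselineFit]) -> TraceMatrix:
    """ΔF/F for every ROI; returns a TraceMatrix of kind "dff"."""
    if len(baselines) != traces.n_rois:
        raise ValueError("one baseline fit per ROI is required")
    out = np.column_stack([dff(traces.data[:, j], baselines[j]) for j in range(traces.n_rois)])
    return TraceMatrix(out, traces.frame_rate, kind="dff")
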