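"""Zone partition relative to the stimulation mask and per-pulse peaks.

The field of view is split into three concentric regions around the
stimulation mask: *stimulated* (inside the mask radius), *zone1* (between
one and two mask radii — with the standard 300 μm mask the outer boundary
sits at 600 μm) and *zone2* (beyond). Per-pulse peak ΔF/F is extracted
for every neuron and summarised per zone as mean ± SEM against the pulse
irradiance, which quantifies how far evoked excitation spreads beyond the
directly stimulated cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import StimulationProtocol
from .segmentation import RoiSet
from .traces import TraceMatrix

__all__ = ["ZonePartition", "partition", "partition_positions", "per_stimulus_peaks", "zone_summary"]

ZONE_LABELS = ("stimulated", "zone1", "zone2")


@dataclass
class ZonePartition:
    """Zone label per ROI plus the generating geometry (μm).

    ``zone1_outer`` is always twice the stimulation radius. For a
    full-field protocol every ROI is labelled "stimulated" and
    ``full_field`` is set.
    """

    labels: np.ndarray  # (n,) of {"stimulated", "zone1", "zone2"}
    stim_center: tuple[float, float] | None
    stim_radius: float | None
    full_field: bool = False

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(ZONE_LABELS)
        if bad:
            raise ValueError(f"unknown zone labels: {bad}")

    @property
    def zone1_outer(self) -> float | None:
        return None if self.stim_radius is None else 2.0 * self.stim_radius

    def counts(self) -> dict[str, int]:
        return {z: int(np.sum(self.labels == z)) for z in ZONE_LABELS}

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "stim_center": None if self.stim_center is None else list(self.stim_center),
            "stim_radius": self.stim_radius,
            "zone1_outer": self.zone1_outer,
            "full_field": self.full_field,
        }


def partition_positions(positions_um: np.ndarray, protocol: StimulationProtocol) -> ZonePartition:
    """Classify (x, y) μm positions by distance to the mask centre.

    stimulated ⇔ d ≤ r; zone1 ⇔ r < d ≤ 2r; zone2 ⇔ d > 2r. Without a
    spatial mask everything is stimulated and the partition is flagged
    full-field.
    """
    positions = np.atleast_2d(np.asarray(positions_um, dtype=float))
    if not protocol.is_masked:
        return ZonePartition(
            labels=np.array(["stimulated"] * len(positions), dtype=object),
            stim_center=None,
            stim_radius=None,
            full_field=True,
        )
    cx, cy = protocol.mask_center
    r = protocol.mask_radius
    d = np.hypot(positions[:, 0] - cx, positions[:, 1] - cy)
    labels = np.where(d <= r, "stimulated", np.where(d <= 2 * r, "zone1", "zone2"))
    return ZonePartition(
        labels=labels.astype(object),
        stim_center=(float(cx), float(cy)),
        stim_radius=float(r),
    )


def partition(rois: RoiSet, protocol: StimulationProtocol) -> ZonePartition:
    """Zone partition of detected ROIs (centres, not edges, are classified)."""
    return partition_positions(rois.centers_um, protocol)


def per_stimulus_peaks(dff: TraceMatrix, protocol: StimulationProtocol) -> np.ndarray:
    """Peak ΔF/F per neuron per pulse; shape (n_neurons, n_pulses).

    The peak for pulse *i* is the maximum over the half-open frame window
    [onset_i, onset_{i+1}); the last window extends to the end of the
    trace. Windows must lie inside the trace.
    """
    windows = protocol.pulse_windows()
    if windows and windows[-1][1] > dff.n_frames:
        raise ValueError("protocol pulses extend beyond the trace")
    peaks = np.empty((dff.n_rois, len(windows)))
    for p, (s, e) in enumerate(windows):
        peaks[:, p] = dff.data[s:e].max(axis=0)
    return peaks


def zone_summary(
    peaks: np.ndarray, part: ZonePartition, protocol: StimulationProtocol
) -> pd.DataFrame:
    """Mean ± SEM of per-pulse peaks over the neurons of each zone.

    Returns one row per (zone, pulse) with columns zone, pulse, intensity,
    mean_peak, sem, n. SEM is SD/√n (sample SD, ddof=1); a single-neuron
    zone reports SEM = 0 by convention and an empty zone reports NaN with
    n = 0 rather than erroring.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.shape[0] != len(part.labels):
        raise ValueError("one peak row per ROI is required")
    rows = []
    for zone in ZONE_LABELS:
        sel = part.labels == zone
        n = int(sel.sum())
        for p, intensity in enumerate(protocol.pulse_intensities):
            if n == 0:
                mean, sem = np.nan, np.nan
            else:
                vals = peaks[sel, p]
                mean = float(vals.mean())
                sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append(
                {"zone": zone, "pulse": p, "intensity": intensity, "mean_peak": mean, "sem": sem, "n": n}
            )
    return pd.DataFrame(rows, columns=["zone", "pulse", "intensity", "mean_peak", "sem", "n"])
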