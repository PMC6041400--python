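"""Optical stimulation protocols.

A recording is driven by a train of blue-light pulses of increasing
irradiance delivered either full-field or through a circular spatial mask.
All quantities are in physical units: seconds, micrometres, mW/cm².
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["StimulationProtocol", "make_protocol"]


@dataclass(frozen=True)
class StimulationProtocol:
    """Pulse train plus acquisition parameters for one recording.

    Parameters
    ----------
    frame_rate : float
        Acquisition rate in frames/s.
    n_frames : int
        Number of frames in the recording.
    pulse_onsets : tuple of float
        Pulse start times in seconds, strictly increasing.
    pulse_duration : float
        Duration of each pulse in seconds.
    pulse_intensities : tuple of float
        Irradiance of each pulse in mW/cm², one entry per onset.
    mask_center, mask_radius : optional
        Centre (x, y) in μm and radius in μm of the circular stimulation
        mask. Both ``None`` means full-field illumination.
    """

    frame_rate: float
    n_frames: int
    pulse_onsets: tuple[float, ...]
    pulse_duration: float
    pulse_intensities: tuple[float, ...]
    mask_center: tuple[float, float] | None = None
    mask_radius: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "pulse_onsets", tuple(float(t) for t in self.pulse_onsets))
        object.__setattr__(
            self, "pulse_intensities", tuple(float(v) for v in self.pulse_intensities)
        )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if len(self.pulse_intensities) != len(self.pulse_onsets):
            raise ValueError("one intensity per pulse is required")
        onsets = np.asarray(self.pulse_onsets)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("pulse_onsets must be strictly increasing")
        if any(v < 0 for v in self.pulse_intensities):
            raise ValueError("pulse intensities must be non-negative")
        if self.pulse_duration < 0:
            raise ValueError("pulse_duration must be non-negative")
        if onsets.size and onsets[-1] + self.pulse_duration > self.duration:
            raise ValueError(
                f"last pulse ends at {onsets[-1] + self.pulse_duration:.3f} s, "
                f"beyond the {self.duration:.3f} s recording"
            )
        if (self.mask_center is None) != (self.mask_radius is None):
            raise ValueError("mask_center and mask_radius must be given together")
        if self.mask_radius is not None and self.mask_radius <= 0:
            raise ValueError("mask_radius must be positive")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets)

    @property
    def is_masked(self) -> bool:
        return self.mask_center is not None

    def onset_frames(self) -> np.ndarray:
        """Frame index of each pulse onset."""
        return np.round(np.asarray(self.pulse_onsets) * self.frame_rate).astype(int)

    def pulse_windows(self) -> list[tuple[int, int]]:
        """Half-open frame windows ``[onset_i, onset_{i+1})`` per pulse.

        The last window runs to the end of the recording, so every frame
        at or after the first onset belongs to exactly one pulse.
        """
        starts = self.onset_frames()
        ends = np.append(starts[1:], self.n_frames)
        return [(int(s), int(e)) for s, e in zip(starts, ends)]

    def in_mask(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of which (x, y) μm positions receive the stimulus."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if not self.is_masked:
            return np.ones(len(positions), dtype=bool)
        d = np.hypot(
            positions[:, 0] - self.mask_center[0], positions[:, 1] - self.mask_center[1]
        )
        return d <= self.mask_radius

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pulse_onsets"] = list(d["pulse_onsets"])
        d["pulse_intensities"] = list(d["pulse_intensities"])
        if d["mask_center"] is not None:
            d["mask_center"] = list(d["mask_center"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        d = dict(d)
        if d.get("mask_center") is not None:
            d["mask_center"] = tuple(d["mask_center"])
        return cls(**d)


def make_protocol(
    pulse_duration: float = 0.1,
    n_pulses: int = 10,
    intensity_step: float = 7.0,
    interval: float = 5.5,
    frame_rate: float = 10.0,
    duration: float = 60.0,
    t_start: float = 2.0,
    mask_center: tuple[float, float] | None = None,
    mask_radius: float | None = None,
) -> StimulationProtocol:
    """Build the standard staircase stimulation protocol.

    Pulse ``i`` (0-based) has irradiance ``i * intensity_step``, so the
    staircase starts dark and increases linearly; onsets are spaced by
    ``interval`` seconds starting at ``t_start``. Defaults reproduce the
    assay's standard acquisition: 10 pulses of 100 ms in 7 mW/cm² steps,
    5.5 s apart, recorded at 10 frames/s for 1 min (600 frames).

    Raises
    ------
    ValueError
        If the pulse train does not fit inside the recording.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be at least 1")
    if intensity_step <= 0:
        raise ValueError("intensity_step must be positive")
    last_end = t_start + (n_pulses - 1) * interval + pulse_duration
    if last_end > duration:
        raise ValueError(
            f"{n_pulses} pulses every {interval} s starting at {t_start} s end at "
            f"{last_end:.2f} s and do not fit in a {duration} s recording"
        )
    onsets = tuple(t_start + i * interval for i in range(n_pulses))
    intensities = tuple(i * intensity_step for i in range(n_pulses))
    return StimulationProtocol(
        frame_rate=frame_rate,
        n_frames=int(round(frame_rate * duration)),
        pulse_onsets=onsets,
        pulse_duration=pulse_duration,
        pulse_intensities=intensities,
        mask_center=mask_center,
        mask_radius=mask_radius,
    )
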