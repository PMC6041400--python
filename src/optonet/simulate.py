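"""Ground-truthed synthetic recordings of an optogenetically driven network.

The generator emulates a wide-field calcium-imaging experiment on a
dissociated cortical culture expressing a channelrhodopsin and a red
calcium indicator: ~60 somata in an 832 × 702 μm field of view imaged at
10 Hz for 1 min while a staircase of blue pulses drives the cells either
full-field or inside a 300 μm-radius mask.

The forward model has four stages, each exposed separately so every
downstream analysis stage can be tested against a known truth:

1. :func:`make_network` — soma positions and a ground-truth synaptic graph;
2. :func:`simulate_spikes` — optogenetic drive (saturating sigmoid of
   irradiance) plus a discrete-event synaptic cascade with Bernoulli
   transmission, fixed delay and an absolute refractory period;
3. :func:`spikes_to_calcium` — double-exponential indicator kernel summed
   linearly over spikes (ground-truth ΔF/F);
4. :func:`render_movie` — disk rendering on the binned sensor grid with a
   static background, multiplicative photobleaching of the signal and
   additive Gaussian sensor noise.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .protocol import StimulationProtocol
from .traces import TraceMatrix

__all__ = [
    "SyntheticNetwork",
    "SpikeRaster",
    "MovieStack",
    "make_network",
    "simulate_spikes",
    "spikes_to_calcium",
    "render_movie",
]

#: Field of view in μm (x, y) matching a 640 × 540 sensor with 4 × 4 binning
#: at 1.3 μm/px, i.e. 160 × 135 binned pixels of 5.2 μm.
DEFAULT_FOV = (832.0, 702.0)
DEFAULT_PIXEL_SIZE = 5.2


@dataclass
class SyntheticNetwork:
    """Planted neuron geometry, synaptic graph and excitability.

    ``adjacency_true[i, j] = 1`` means a synapse from neuron *i* onto
    neuron *j*; the default generator draws a symmetric graph. The
    excitability triple (half, slope, p_max) parametrises the saturating
    firing-probability curve ``p(I) = p_max / (1 + exp(−(I − half)/slope))``
    per neuron, with p(0) ≡ 0 (no light, no drive).
    """

    positions: np.ndarray  # (n, 2) μm, (x, y)
    soma_radius: np.ndarray  # (n,) μm
    adjacency_true: np.ndarray  # (n, n) binary, zero diagonal
    transmission_prob: float
    synaptic_delay: float  # s
    excitability_half: np.ndarray  # (n,) mW/cm²
    excitability_slope: np.ndarray  # (n,) mW/cm²
    excitability_pmax: np.ndarray  # (n,)
    fov: tuple[float, float] = DEFAULT_FOV

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = len(self.positions)
        self.soma_radius = np.broadcast_to(np.asarray(self.soma_radius, float), (n,)).copy()
        self.adjacency_true = np.asarray(self.adjacency_true, dtype=np.int8)
        for name in ("excitability_half", "excitability_slope", "excitability_pmax"):
            setattr(self, name, np.broadcast_to(np.asarray(getattr(self, name), float), (n,)).copy())
        if self.adjacency_true.shape != (n, n):
            raise ValueError("adjacency_true must be n × n")
        if np.any(np.diag(self.adjacency_true) != 0):
            raise ValueError("adjacency_true must have a zero diagonal")
        if not 0.0 <= self.transmission_prob <= 1.0:
            raise ValueError("transmission_prob must be in [0, 1]")
        if np.any(self.soma_radius <= 0):
            raise ValueError("soma_radius must be positive")
        if np.any(self.positions < 0) or np.any(self.positions > np.asarray(self.fov)):
            raise ValueError("positions must lie inside the field of view")

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    def firing_probability(self, intensity: float) -> np.ndarray:
        """Per-neuron firing probability for one pulse at the given irradiance."""
        if intensity <= 0:
            return np.zeros(self.n_neurons)
        p = self.excitability_pmax / (
            1.0 + np.exp(-(intensity - self.excitability_half) / self.excitability_slope)
        )
        return np.clip(p, 0.0, 1.0)


@dataclass
class SpikeRaster:
    """Spike times per neuron, seconds, sorted ascending."""

    spike_times: list[np.ndarray]
    duration: float

    def __post_init__(self):
        self.spike_times = [np.sort(np.asarray(s, dtype=float)) for s in self.spike_times]
        for s in self.spike_times:
            if s.size and (s[0] < 0 or s[-1] >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    def counts(self) -> np.ndarray:
        return np.array([s.size for s in self.spike_times])


@dataclass
class MovieStack:
    """T × H × W fluorescence movie with pixel-size and timing metadata."""

    frames: np.ndarray
    pixel_size: float  # μm/pixel
    frame_rate: float  # frames/s

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T × H × W array")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("frame intensities must be finite and non-negative")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def make_network(
    n_neurons: int = 60,
    fov: tuple[float, float] = DEFAULT_FOV,
    connection_rule: float | np.ndarray = 0.15,
    soma_radius: float = 15.0,
    transmission_prob: float = 0.5,
    synaptic_delay: float = 0.05,
    excitability: tuple[float, float, float] = (12.0, 4.0, 0.98),
    seed: int | None = None,
    max_tries: int = 10000,
) -> SyntheticNetwork:
    """Place non-overlapping somata in the field of view and wire them.

    ``connection_rule`` is either an Erdős–Rényi edge probability (a
    symmetric graph is drawn, one Bernoulli per unordered pair) or an
    explicit binary adjacency matrix used as-is. Placement rejects
    candidates whose centre is closer than the sum of soma radii to an
    accepted soma; an error is raised if the field cannot accommodate
    ``n_neurons`` within ``max_tries`` draws.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be at least 1")
    rng = np.random.default_rng(seed)
    radius = float(soma_radius)
    lo = np.array([radius, radius])
    hi = np.asarray(fov, dtype=float) - radius
    if np.any(hi <= lo):
        raise ValueError("field of view too small for the soma radius")

    positions = np.empty((n_neurons, 2))
    placed = 0
    tries = 0
    while placed < n_neurons:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_neurons} non-overlapping somata in a "
                f"{fov[0]:.0f} × {fov[1]:.0f} μm field after {max_tries} tries"
            )
        cand = rng.uniform(lo, hi)
        tries += 1
        if placed:
            d = np.hypot(*(positions[:placed] - cand).T)
            if np.any(d < 2 * radius):
                continue
        positions[placed] = cand
        placed += 1

    if np.isscalar(connection_rule):
        p = float(connection_rule)
        if not 0.0 <= p <= 1.0:
            raise ValueError("connection probability must be in [0, 1]")
        upper = rng.random((n_neurons, n_neurons)) < p
        adj = np.triu(upper, k=1)
        adj = (adj | adj.T).astype(np.int8)
    else:
        adj = np.asarray(connection_rule, dtype=np.int8)

    half, slope, pmax = excitability
    return SyntheticNetwork(
        positions=positions,
        soma_radius=np.full(n_neurons, radius),
        adjacency_true=adj,
        transmission_prob=transmission_prob,
        synaptic_delay=synaptic_delay,
        excitability_half=np.full(n_neurons, half),
        excitability_slope=np.full(n_neurons, slope),
        excitability_pmax=np.full(n_neurons, pmax),
        fov=tuple(float(v) for v in fov),
    )


def simulate_spikes(
    network: SyntheticNetwork,
    protocol: StimulationProtocol,
    seed: int | None = None,
    refractory: float = 0.4,
    extra_spikes: list[tuple[int, float]] | None = None,
) -> SpikeRaster:
    """Optogenetic drive plus recursive synaptic cascade.

    For each pulse, every neuron inside the stimulation mask fires at the
    pulse onset with the probability given by its excitability curve at
    that pulse's irradiance. Each accepted spike is delivered to all
    postsynaptic neighbours after ``network.synaptic_delay`` and triggers
    them with probability ``network.transmission_prob``, recursively; a
    neuron cannot fire twice within ``refractory`` seconds. With the
    default delay (50 ms) and refractory period (400 ms) a cascade is a
    single synchronous wave per pulse: every return path delivers during
    the originating neuron's refractory window.

    ``extra_spikes`` forces additional (neuron, time) spikes regardless of
    the light protocol — useful for deterministic propagation tests.
    """
    rng = np.random.default_rng(seed)
    n = network.n_neurons
    duration = protocol.duration
    stimulated = protocol.in_mask(network.positions)

    counter = 0
    pending: list[tuple[float, int, int]] = []  # (time, tiebreak, neuron)
    for onset, intensity in zip(protocol.pulse_onsets, protocol.pulse_intensities):
        p = network.firing_probability(intensity)
        draws = rng.random(n)
        for i in np.flatnonzero(stimulated & (draws < p)):
            heapq.heappush(pending, (onset, counter, int(i)))
            counter += 1
    for i, t in extra_spikes or []:
        heapq.heappush(pending, (float(t), counter, int(i)))
        counter += 1

    spikes: list[list[float]] = [[] for _ in range(n)]
    last = np.full(n, -np.inf)
    while pending:
        t, _, i = heapq.heappop(pending)
        if t >= duration:
            continue
        if t - last[i] < refractory:
            continue
        last[i] = t
        spikes[i].append(t)
        targets = np.flatnonzero(network.adjacency_true[i])
        if targets.size and network.transmission_prob > 0:
            hit = rng.random(targets.size) < network.transmission_prob
            for j in targets[hit]:
                heapq.heappush(pending, (t + network.synaptic_delay, counter, int(j)))
                counter += 1
    return SpikeRaster([np.array(s) for s in spikes], duration=duration)


def _kernel_scale(tau_rise: float, tau_decay: float) -> float:
    """Scale making the double-exponential kernel peak at exactly 1."""
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return 1.0 / peak


def spikes_to_calcium(
    raster: SpikeRaster,
    tau_rise: float = 0.1,
    tau_decay: float = 1.5,
    amplitude_per_spike: float = 0.8,
    frame_rate: float = 10.0,
    n_frames: int | None = None,
) -> TraceMatrix:
    """Ground-truth ΔF/F traces from spike times.

    Each spike adds ``A · s · (exp(−t/τ_decay) − exp(−t/τ_rise))`` for
    t ≥ spike time, with ``s`` chosen so the continuous-time kernel peaks
    at exactly ``amplitude_per_spike``; kernels sum linearly (the
    indicator is assumed far from saturation).
    """
    if not (tau_decay > tau_rise > 0):
        raise ValueError("tau_decay > tau_rise > 0 is required")
    if n_frames is None:
        n_frames = int(round(raster.duration * frame_rate))
    t = np.arange(n_frames) / frame_rate
    scale = amplitude_per_spike * _kernel_scale(tau_rise, tau_decay)
    out = np.zeros((n_frames, raster.n_neurons))
    for i, stimes in enumerate(raster.spike_times):
        for s in stimes:
            dt = t - s
            sel = dt >= 0
            out[sel, i] += scale * (np.exp(-dt[sel] / tau_decay) - np.exp(-dt[sel] / tau_rise))
    return TraceMatrix(out, frame_rate, kind="dff")


def render_movie(
    network: SyntheticNetwork,
    calcium: TraceMatrix,
    baseline_f0: float = 100.0,
    background: float = 2.0,
    bleach_tau: float = 120.0,
    noise_sd: float = 15.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int | None = None,
) -> MovieStack:
    """Render the network onto the sensor grid.

    Inside each soma disk the pixel value is
    ``background + baseline_f0 · (1 + ΔF/F(t)) · exp(−t/bleach_tau)``:
    photobleaching multiplies the fluorescent signal, not the additive
    camera background. i.i.d. Gaussian noise of SD ``noise_sd`` is added
    to every pixel and the result is clipped at zero (somatic intensities
    sit far above the clip point at the default settings).
    """
    if bleach_tau <= 0:
        raise ValueError("bleach_tau must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    T = calcium.n_frames
    W = int(round(network.fov[0] / pixel_size))
    H = int(round(network.fov[1] / pixel_size))
    t = np.arange(T) / calcium.frame_rate
    bleach = np.exp(-t / bleach_tau)

    frames = np.full((T, H, W), float(background), dtype=np.float64)
    rows, cols = np.mgrid[0:H, 0:W]
    for i in range(network.n_neurons):
        x, y = network.positions[i]
        r_px = network.soma_radius[i] / pixel_size
        cr, cc = y / pixel_size, x / pixel_size
        mask = (rows - cr) ** 2 + (cols - cc) ** 2 <= r_px**2
        rr, cc_idx = np.nonzero(mask)
        if rr.size == 0:
            continue
        vals = background + baseline_f0 * (1.0 + calcium.data[:, i]) * bleach
        frames[:, rr, cc_idx] = vals[:, None]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)
        np.clip(frames, 0.0, None, out=frames)
    return MovieStack(frames.astype(np.float32), pixel_size=pixel_size, frame_rate=calcium.frame_rate)
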