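"""Functional connectivity from pairwise cross-correlation of ΔF/F traces.

For every pair of neurons the statistic is the maximum, over lags within
a short window, of the normalized (mean-removed, unit-variance) circular
cross-correlation of their ΔF/F traces. Significance is calibrated per
pair by a surrogate null: one trace is circularly time-shifted by a
uniform random offset — preserving its autocorrelation while destroying
any cross-correlation — and the statistic recomputed 100 times; an edge
A(i,j) = 1 is declared when the observed statistic strictly exceeds the
empirical (1 − α) null quantile, symmetrically. The network-level
summary is the mean global connectivity, mean node degree / (N − 1),
which is 0 for an empty graph and 1 when every node connects to every
other node.

Because the observed statistic and the surrogate statistic are both
circular, the null draws are exchangeable with the observation under
independence, which gives the test its type-I calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import RoiSet
from .traces import TraceMatrix

__all__ = [
    "ConnectivityResult",
    "pairwise_xcorr",
    "reshuffle_null",
    "build_adjacency",
    "mean_global_connectivity",
    "infer_connectivity",
    "connectivity_map",
]


def _as_data(dff) -> np.ndarray:
    data = dff.data if isinstance(dff, TraceMatrix) else np.asarray(dff, dtype=float)
    if data.ndim != 2:
        raise ValueError("traces must be a (frames × neurons) matrix")
    return data


def _resolve_frame_rate(dff, frame_rate: float | None) -> float:
    if isinstance(dff, TraceMatrix):
        return dff.frame_rate
    if frame_rate is None:
        raise ValueError("frame_rate is required when traces are a bare array")
    return float(frame_rate)


def _zscore(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores; zero-variance columns become all-zero and are flagged."""
    mu = data.mean(axis=0)
    sd = data.std(axis=0)
    zero_var = sd == 0
    safe = np.where(zero_var, 1.0, sd)
    z = (data - mu) / safe
    z[:, zero_var] = 0.0
    return z, zero_var


def _circular_corr(z: np.ndarray) -> np.ndarray:
    """Circular cross-correlation c[i, j, k] = (1/T) Σ_t z_i[t] · z_j[t − k].

    Computed by FFT for all pairs at once; shape (N, N, T).
    """
    T = z.shape[0]
    F = np.fft.rfft(z, axis=0)
    prod = F[:, :, None] * np.conj(F)[:, None, :]
    return np.fft.irfft(prod, n=T, axis=0).transpose(1, 2, 0) / T


def _lag_window(max_lag: float, frame_rate: float, T: int) -> np.ndarray:
    L = int(round(max_lag * frame_rate))
    if L >= T:
        raise ValueError("max_lag must be shorter than the trace")
    return np.arange(-L, L + 1)


def pairwise_xcorr(
    dff, max_lag: float = 0.5, frame_rate: float | None = None
) -> np.ndarray:
    """N × N matrix of max-over-lag normalized cross-correlation.

    corr(i, j) is the maximum over lags |ℓ| ≤ max_lag (seconds) of the
    circular Pearson cross-correlation of traces i and j; the diagonal is
    1 by definition. Zero-variance traces get correlation 0 against
    everything (their diagonal stays 1).
    """
    data = _as_data(dff)
    fr = _resolve_frame_rate(dff, frame_rate)
    if data.shape[1] < 2:
        raise ValueError("at least 2 neurons are required")
    z, _ = _zscore(data)
    lags = _lag_window(max_lag, fr, data.shape[0])
    c = _circular_corr(z)
    corr = c[:, :, lags].max(axis=2)
    np.fill_diagonal(corr, 1.0)
    return corr


def reshuffle_null(
    dff,
    n_shuffles: int = 100,
    max_lag: float = 0.5,
    alpha: float = 0.05,
    seed: int | None = None,
    frame_rate: float | None = None,
) -> np.ndarray:
    """Per-pair significance cutoffs from circular-shift surrogates.

    For each pair (i, j) one trace is circularly shifted by a uniform
    random offset and the max-over-lag statistic recomputed; after
    ``n_shuffles`` repeats the cutoff is the empirical (1 − α) quantile
    of the null sample, taken as an order statistic (``higher``
    interpolation) so the subsequent strict-inequality test is
    conservative. Offsets are drawn away from zero by more than twice
    the lag window, so a surrogate never overlaps the observed
    alignment. The diagonal is +inf (a node is never its own edge).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    data = _as_data(dff)
    fr = _resolve_frame_rate(dff, frame_rate)
    T, N = data.shape
    rng = np.random.default_rng(seed)
    z, _ = _zscore(data)
    lags = _lag_window(max_lag, fr, T)
    c = _circular_corr(z)
    L = lags[-1]
    off_lo, off_hi = 2 * L + 1, T - 2 * L
    if off_lo >= off_hi:
        raise ValueError("trace too short for the requested max_lag")
    null_q = np.full((N, N), np.inf)
    for i in range(N):
        for j in range(i + 1, N):
            offsets = rng.integers(off_lo, off_hi, size=n_shuffles)
            idx = (offsets[:, None] + lags[None, :]) % T
            null_vals = c[i, j, idx].max(axis=1)
            q = float(np.quantile(null_vals, 1.0 - alpha, method="higher"))
            null_q[i, j] = null_q[j, i] = q
    return null_q


def build_adjacency(corr: np.ndarray, null_quantiles: np.ndarray) -> np.ndarray:
    """Binary adjacency: A(i,j) = 1 iff corr(i,j) strictly exceeds its cutoff.

    The (i,j) and (j,i) decisions are combined by logical AND and the
    diagonal forced to zero, yielding an undirected graph.
    """
    corr = np.asarray(corr, dtype=float)
    null_quantiles = np.asarray(null_quantiles, dtype=float)
    if corr.shape != null_quantiles.shape:
        raise ValueError("corr and null_quantiles shapes differ")
    decide = corr > null_quantiles
    A = (decide & decide.T).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


def mean_global_connectivity(A: np.ndarray) -> float:
    """Mean node degree divided by (N − 1); in [0, 1] for simple graphs.

    1 for a complete graph (every node connected to every other node),
    0 for an empty one. Undefined — and an error — for fewer than 2 nodes.
    """
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    N = A.shape[0]
    if N < 2:
        raise ValueError("mean global connectivity requires at least 2 nodes")
    if not np.array_equal(A, A.T):
        raise ValueError("A must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("A must have a zero diagonal")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("A must be binary")
    degrees = A.sum(axis=1)
    return float(degrees.mean() / (N - 1))


@dataclass
class ConnectivityResult:
    """Full output of the connectivity inference for one recording."""

    corr: np.ndarray
    null_quantiles: np.ndarray
    adjacency: np.ndarray
    mgc: float
    degrees: np.ndarray
    zero_variance: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self):
        """Undirected graph with per-edge correlation weights."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_neurons))
        for i, j in zip(*np.triu_indices(self.n_neurons, k=1)):
            if self.adjacency[i, j]:
                g.add_edge(int(i), int(j), weight=float(self.corr[i, j]))
        return g


def infer_connectivity(
    dff,
    max_lag: float = 0.5,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    frame_rate: float | None = None,
) -> ConnectivityResult:
    """Run the full chain: correlation → surrogate null → adjacency → MGC."""
    data = _as_data(dff)
    fr = _resolve_frame_rate(dff, frame_rate)
    corr = pairwise_xcorr(data, max_lag=max_lag, frame_rate=fr)
    null_q = reshuffle_null(
        data, n_shuffles=n_shuffles, max_lag=max_lag, alpha=alpha, seed=seed, frame_rate=fr
    )
    A = build_adjacency(corr, null_q)
    _, zero_var = _zscore(data)
    return ConnectivityResult(
        corr=corr,
        null_quantiles=null_q,
        adjacency=A,
        mgc=mean_global_connectivity(A),
        degrees=A.sum(axis=1),
        zero_variance=zero_var,
        params={
            "max_lag": max_lag,
            "n_shuffles": n_shuffles,
            "alpha": alpha,
            "seed": seed,
            "surrogate": "circular-shift",
        },
    )


def connectivity_map(
    result: ConnectivityResult, rois: RoiSet
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Edge list as pairs of (x, y) μm endpoints, one entry per edge i < j."""
    if len(rois) != result.n_neurons:
        raise ValueError("ROI count does not match the adjacency matrix")
    pos = rois.centers_um
    edges = []
    for i, j in zip(*np.triu_indices(result.n_neurons, k=1)):
        if result.adjacency[i, j]:
            edges.append((tuple(pos[i]), tuple(pos[j])))
    return edges


def plot_connectivity_map(result: ConnectivityResult, rois: RoiSet, ax=None):
    """Draw nodes at their ROI positions with a line per inferred edge."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (x0, y0), (x1, y1) in connectivity_map(result, rois):
        ax.plot([x0, x1], [y0, y1], color="0.4", lw=0.8, zorder=1)
    pos = rois.centers_um
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=result.degrees, cmap="viridis", zorder=2)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_aspect("equal")
    ax.figure.colorbar(sc, ax=ax, label="degree")
    return ax
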