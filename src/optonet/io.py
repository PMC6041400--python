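"""Reading and writing of the pipeline's standard formats.

Movies travel as multi-page TIFF with a JSON metadata block (pixel size,
frame rate) in the image description; traces as CSV with one column per
ROI; everything else (protocols, networks, rasters, results) as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .protocol import StimulationProtocol
from .simulate import MovieStack, SpikeRaster, SyntheticNetwork
from .traces import TraceMatrix

__all__ = [
    "write_movie",
    "read_movie",
    "write_traces",
    "read_traces",
    "write_json",
    "read_json",
    "network_to_dict",
    "network_from_dict",
    "raster_to_dict",
    "raster_from_dict",
]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_NumpyEncoder, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_movie(movie: MovieStack, path) -> None:
    meta = {"pixel_size_um": movie.pixel_size, "frame_rate_hz": movie.frame_rate}
    tifffile.imwrite(path, movie.frames, description=json.dumps(meta))


def read_movie(
    path, pixel_size: float | None = None, frame_rate: float | None = None
) -> MovieStack:
    """Read a TIFF stack; explicit arguments override embedded metadata."""
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = {}
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    frame_rate = frame_rate if frame_rate is not None else meta.get("frame_rate_hz")
    if pixel_size is None or frame_rate is None:
        raise ValueError(
            f"{path}: pixel size / frame rate not found in TIFF metadata; pass them explicitly"
        )
    return MovieStack(frames, pixel_size=pixel_size, frame_rate=frame_rate)


def write_traces(traces: TraceMatrix, path) -> None:
    df = pd.DataFrame(traces.data, columns=[f"roi_{j}" for j in range(traces.n_rois)])
    df.insert(0, "time_s", traces.times)
    df.to_csv(path, index=False)


def read_traces(path, kind: str = "raw") -> TraceMatrix:
    df = pd.read_csv(path)
    t = df.pop("time_s").to_numpy()
    frame_rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    return TraceMatrix(df.to_numpy(), frame_rate=float(frame_rate), kind=kind)


def network_to_dict(net: SyntheticNetwork) -> dict:
    return {
        "positions_um": net.positions,
        "soma_radius_um": net.soma_radius,
        "adjacency_true": net.adjacency_true,
        "transmission_prob": net.transmission_prob,
        "synaptic_delay_s": net.synaptic_delay,
        "excitability_half": net.excitability_half,
        "excitability_slope": net.excitability_slope,
        "excitability_pmax": net.excitability_pmax,
        "fov_um": list(net.fov),
    }


def network_from_dict(d: dict) -> SyntheticNetwork:
    return SyntheticNetwork(
        positions=np.asarray(d["positions_um"]),
        soma_radius=np.asarray(d["soma_radius_um"]),
        adjacency_true=np.asarray(d["adjacency_true"]),
        transmission_prob=d["transmission_prob"],
        synaptic_delay=d["synaptic_delay_s"],
        excitability_half=np.asarray(d["excitability_half"]),
        excitability_slope=np.asarray(d["excitability_slope"]),
        excitability_pmax=np.asarray(d["excitability_pmax"]),
        fov=tuple(d["fov_um"]),
    )


def raster_to_dict(raster: SpikeRaster) -> dict:
    return {
        "duration_s": raster.duration,
        "spike_times_s": [s.tolist() for s in raster.spike_times],
    }


def raster_from_dict(d: dict) -> SpikeRaster:
    return SpikeRaster(
        spike_times=[np.asarray(s) for s in d["spike_times_s"]], duration=d["duration_s"]
    )
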