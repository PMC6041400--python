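"""Soma detection by circular Hough transform and ROI trace extraction.

Somata carry a static baseline fluorescence, so the temporal mean of the
movie is a high-SNR reference image (sensor noise averages down by √T).
Cell bodies are detected on that image as circles: Canny edges feed a
circular Hough accumulator over a radius range, and accumulator peaks
ranked by score become ROIs, with close detections suppressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .simulate import MovieStack
from .traces import TraceMatrix

__all__ = ["RoiSet", "reference_image", "detect_somata", "extract_traces"]


@dataclass
class RoiSet:
    """Circular ROIs in pixel coordinates.

    Centers are (row, col) with 0-based pixel indices; physical (x, y)
    positions in μm are ``col · pixel_size, row · pixel_size``.
    """

    centers: np.ndarray  # (n, 2) pixels, (row, col)
    radii: np.ndarray  # (n,) pixels
    pixel_size: float  # μm/pixel

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if len(self.radii) != len(self.centers):
            raise ValueError("one radius per centre is required")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def centers_um(self) -> np.ndarray:
        """(x, y) centre positions in μm."""
        return self.centers[:, ::-1] * self.pixel_size

    @property
    def radii_um(self) -> np.ndarray:
        return self.radii * self.pixel_size

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "centers_px": self.centers.tolist(),
            "radii_px": self.radii.tolist(),
            "centers_um": self.centers_um.tolist(),
            "radii_um": self.radii_um.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RoiSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(centers=d["centers_px"], radii=d["radii_px"], pixel_size=d["pixel_size"])


def reference_image(movie: MovieStack, method: str = "mean") -> np.ndarray:
    """Temporal mean or max projection of the movie."""
    if movie.n_frames == 0:
        raise ValueError("movie is empty")
    if method == "mean":
        return movie.frames.mean(axis=0)
    if method == "max":
        return movie.frames.max(axis=0)
    raise ValueError(f"unknown reference method {method!r}")


def detect_somata(
    image: np.ndarray,
    radius_range: tuple[int, int] = (2, 6),
    sensitivity: float = 0.5,
    min_separation: float | None = None,
    edge_sigma: float = 1.0,
    pixel_size: float = 1.0,
    max_somata: int | None = None,
) -> RoiSet:
    """Detect cell bodies as circles in a 2-D reference image.

    The normalized Hough accumulator scores each candidate circle by the
    fraction of its perimeter supported by edge pixels; candidates scoring
    at least ``1 − sensitivity`` are kept (higher sensitivity admits
    weaker circles, as in MATLAB's ``imfindcircles``), ranked by score,
    and thinned so no two accepted centres are closer than
    ``min_separation`` pixels (default: the minimum search diameter).
    A blank or constant image yields an empty RoiSet.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("reference image must be 2-D")
    r_min, r_max = int(radius_range[0]), int(radius_range[1])
    if r_min < 1 or r_max < r_min:
        raise ValueError("radius_range must satisfy 1 <= min <= max")
    if not 0.0 < sensitivity <= 1.0:
        raise ValueError("sensitivity must be in (0, 1]")
    if min_separation is None:
        min_separation = 2.0 * r_min

    ptp = image.max() - image.min()
    if ptp == 0:
        return RoiSet(np.empty((0, 2)), np.empty(0), pixel_size)
    norm = (image - image.min()) / ptp
    edges = canny(norm, sigma=edge_sigma)
    if not edges.any():
        return RoiSet(np.empty((0, 2)), np.empty(0), pixel_size)

    radii = np.arange(r_min, r_max + 1)
    accum = hough_circle(edges, radii)
    sep = max(int(np.ceil(min_separation)), 1)
    _, cx, cy, rad = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=sep,
        min_ydistance=sep,
        threshold=1.0 - sensitivity,
        num_peaks=np.inf,
        total_num_peaks=max_somata if max_somata is not None else np.inf,
    )
    if len(cx) == 0:
        return RoiSet(np.empty((0, 2)), np.empty(0), pixel_size)

    # hough_circle_peaks suppresses along x and y independently; enforce a
    # true Euclidean minimum separation, keeping the higher-scoring circle.
    centers = np.column_stack([cy, cx]).astype(float)  # (row, col)
    keep: list[int] = []
    for i in range(len(centers)):
        if all(np.hypot(*(centers[i] - centers[k])) >= min_separation for k in keep):
            keep.append(i)
    return RoiSet(centers[keep], np.asarray(rad, dtype=float)[keep], pixel_size)


def extract_traces(movie: MovieStack, rois: RoiSet) -> TraceMatrix:
    """Mean in-disk pixel intensity per frame for every ROI (raw traces)."""
    T, H, W = movie.shape
    data = np.empty((T, len(rois)))
    for j in range(len(rois)):
        rr, cc = draw_disk(tuple(rois.centers[j]), rois.radii[j] + 0.5, shape=(H, W))
        if rr.size == 0:
            raise ValueError(f"ROI {j} lies entirely outside the image")
        data[:, j] = movie.frames[:, rr, cc].mean(axis=1)
    return TraceMatrix(data, movie.frame_rate, kind="raw")
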