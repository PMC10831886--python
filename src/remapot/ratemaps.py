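"""Firing-rate map data model, construction, smoothing and text I/O.

A :class:`RateMap` is the universal currency of every metric in this package:
a dense, nonnegative 2D grid of intensities (spikes/s, or unitless mass once
normalized).  Linear-track maps are stored as a single-row grid (``1 x n``).

Conventions
-----------
* 0-based ``(row, col)`` indexing; bin centers sit at integer coordinates.
* Ground distances are in bin units unless ``bin_size`` converts them.
* Negative intensities are rejected on construction everywhere: the transport
  metrics move nonnegative mass and are not defined for signed maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RateMap",
    "SpikeSample",
    "OccupancyMap",
    "build_ratemap_2d",
    "build_ratemap_1d",
    "smooth",
    "normalize",
    "pad",
    "crop",
    "read_ratemap",
    "write_ratemap",
]

_MASS_ATOL = 1e-9


@dataclass(frozen=True)
class RateMap:
    """Dense nonnegative intensity grid with bin geometry.

    Parameters
    ----------
    values
        2D array of intensities.  A 1D array is promoted to shape ``(1, n)``.
    bin_size
        Physical side length of one bin (e.g. cm); defaults to 1 bin-unit.
    normalized
        Set when the total mass is 1; verified on construction.
    """

    values: np.ndarray
    bin_size: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValueError(f"ratemap must be 1D or 2D, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("ratemap must have at least one bin per axis")
        if not np.all(np.isfinite(arr)):
            raise ValueError("ratemap contains non-finite values")
        if np.any(arr < 0):
            raise ValueError(
                "ratemap contains negative intensities; transport metrics "
                "require nonnegative mass"
            )
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        if self.normalized and abs(arr.sum() - 1.0) > _MASS_ATOL:
            raise ValueError(
                f"normalized flag set but total mass is {arr.sum():.12g}"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    @property
    def is_1d(self) -> bool:
        return self.n_rows == 1

    def with_values(self, values: np.ndarray, *, normalized: bool = False) -> "RateMap":
        return RateMap(values, bin_size=self.bin_size, normalized=normalized)

    def bin_centers(self) -> np.ndarray:
        """(n_bins, 2) array of ``(row, col)`` bin-center coordinates."""
        r, c = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return np.column_stack([r.ravel(), c.ravel()]).astype(float)


@dataclass(frozen=True)
class SpikeSample:
    """Spike timestamps (s) with the animal's position at each spike."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if t.ndim != 1 or x.shape != t.shape:
            raise ValueError("timestamps and x must be equal-length 1D arrays")
        if np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be sorted ascending")
        if not np.all(np.isfinite(x)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "x", x)
        if self.y is not None:
            y = np.asarray(self.y, dtype=float)
            if y.shape != t.shape or not np.all(np.isfinite(y)):
                raise ValueError("y must match timestamps and be finite")
            object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class OccupancyMap:
    """Seconds spent per bin, matching a RateMap's geometry."""

    seconds: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.seconds, dtype=float)
        if s.ndim != 2:
            raise ValueError("occupancy must be 2D")
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise ValueError("occupancy seconds must be finite and >= 0")
        object.__setattr__(self, "seconds", s)

    @property
    def shape(self) -> tuple[int, int]:
        return self.seconds.shape


def build_ratemap_2d(
    spikes: SpikeSample,
    occupancy: OccupancyMap,
    shape: tuple[int, int],
    extent: tuple[float, float, float, float] | None = None,
) -> RateMap:
    """Bin spikes into a grid and divide by occupancy time per bin.

    Each bin's rate is ``spike count / occupancy seconds``; bins the animal
    never visited (zero occupancy) get rate 0 so the map stays a valid mass
    distribution downstream.

    Parameters
    ----------
    extent
        ``(x_min, x_max, y_min, y_max)`` of the arena.  Defaults to
        ``(0, n_cols, 0, n_rows)`` so one bin spans one arena unit.
    """
    rows, cols = shape
    if occupancy.shape != (rows, cols):
        raise ValueError(
            f"occupancy shape {occupancy.shape} does not match requested {shape}"
        )
    if spikes.y is None:
        raise ValueError("2D ratemap requires y positions")
    if extent is None:
        extent = (0.0, float(cols), 0.0, float(rows))
    x_min, x_max, y_min, y_max = extent
    if len(spikes) == 0:
        return RateMap(np.zeros(shape))
    x, y = spikes.x, spikes.y
    if np.any((x < x_min) | (x > x_max) | (y < y_min) | (y > y_max)):
        raise ValueError("spike positions fall outside the arena extent")
    counts, _, _ = np.histogram2d(
        y, x, bins=[rows, cols], range=[[y_min, y_max], [x_min, x_max]]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy.seconds > 0, counts / occupancy.seconds, 0.0)
    return RateMap(rate)


def build_ratemap_1d(
    activity: Sequence[float],
    positions: Sequence[float],
    track_length: float,
    n_bins: int,
    averaging_window: int = 112,
) -> RateMap:
    """Build a ``1 x n_bins`` linear-track rate map from per-frame activity.

    Activity is first averaged in non-overlapping windows of
    ``averaging_window`` frames (the default 112 frames corresponds to 15 s at
    the two-photon frame rate this pipeline was designed around), then windows
    are accumulated into position bins and divided by the per-bin occupancy
    (window count).  Negative activity is rejected: the transport metrics
    cannot carry signed mass.
    """
    a = np.asarray(activity, dtype=float)
    p = np.asarray(positions, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("activity and positions must be equal-length 1D series")
    if np.any(a < 0):
        raise ValueError("negative activity values are not supported")
    if np.any((p < 0) | (p > track_length)):
        raise ValueError("positions must lie within [0, track_length]")
    if averaging_window < 1:
        raise ValueError("averaging_window must be >= 1")
    n_win = a.size // averaging_window
    if n_win == 0:  # shorter than one window: use the whole series
        n_win, averaging_window = 1, a.size
    trim = n_win * averaging_window
    a_win = a[:trim].reshape(n_win, averaging_window).mean(axis=1)
    p_win = p[:trim].reshape(n_win, averaging_window).mean(axis=1)
    edges = np.linspace(0.0, track_length, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, p_win, side="right") - 1, 0, n_bins - 1)
    mass = np.bincount(idx, weights=a_win, minlength=n_bins)
    occ = np.bincount(idx, minlength=n_bins).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ > 0, mass / occ, 0.0)
    return RateMap(rate[np.newaxis, :], bin_size=track_length / n_bins)


def _gaussian_kernel_1d(kernel_size: int, sigma: float) -> np.ndarray:
    radius = (kernel_size - 1) // 2
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth(m: RateMap, kernel_size: int = 5, sigma: float = 1.0) -> RateMap:
    """Gaussian smoothing with a normalized truncated kernel.

    Boundary handling is zero-value (constant) padding, so mass may decrease
    near borders; this mirrors the explicit zero padding used in the
    localization workflow rather than reflecting mass back into the map.
    """
    if kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k = _gaussian_kernel_1d(kernel_size, sigma)
    out = np.asarray(m.values, dtype=float)
    if not m.is_1d:
        out = ndimage.convolve1d(out, k, axis=0, mode="constant", cval=0.0)
    out = ndimage.convolve1d(out, k, axis=1, mode="constant", cval=0.0)
    np.clip(out, 0.0, None, out=out)  # guard tiny negative round-off
    return m.with_values(out)


def normalize(m: RateMap) -> RateMap:
    """Divide by total mass so the map sums to one (a probability map)."""
    total = m.total_mass
    if total <= 0:
        raise ValueError("cannot normalize a zero-mass map")
    if m.normalized:
        return m
    return m.with_values(m.values / total, normalized=True)


def pad(m: RateMap, n: int = 2, value: float = 0.0) -> RateMap:
    """Surround the map with ``n`` bins of ``value`` on every side."""
    if n < 0:
        raise ValueError("pad width must be >= 0")
    if n == 0:
        return m
    out = np.pad(m.values, n, mode="constant", constant_values=value)
    return RateMap(out, bin_size=m.bin_size)


def crop(m: RateMap, n: int) -> RateMap:
    """Inverse of :func:`pad`: drop ``n`` border bins on every side."""
    if n == 0:
        return m
    if 2 * n >= min(m.shape):
        raise ValueError("crop width exceeds map size")
    return RateMap(m.values[n:-n, n:-n], bin_size=m.bin_size)


def write_ratemap(m: RateMap, path: str | Path, delimiter: str = ",") -> None:
    """Write a delimited text matrix plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, m.values, delimiter=delimiter, fmt="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"bin_size": m.bin_size, "normalized": m.normalized, "origin": [0, 0]})
    )


def read_ratemap(path: str | Path, delimiter: str | None = None) -> RateMap:
    """Read a delimited text matrix; picks up the JSON sidecar if present."""
    path = Path(path)
    if delimiter is None:
        head = path.read_text().lstrip().splitlines()[0] if path.exists() else ""
        delimiter = "\t" if "\t" in head else ","
    try:
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"could not parse ratemap file {path}: {exc}") from exc
    bin_size, normalized = 1.0, False
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        bin_size = float(meta.get("bin_size", 1.0))
        normalized = bool(meta.get("normalized", False))
    return RateMap(arr, bin_size=bin_size, normalized=normalized)
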