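"""Synthetic place fields, elliptical fields, grid modules, and noise.

Fields are analytic Gaussian blobs evaluated on integer bin centers, so every
generated map is exactly reproducible.  Translation is implemented the way the
validation experiments define it: the field is generated on a wider canvas
(3N x 3N) and the relevant N x N window is sliced out, so truncation at the
map border arises naturally instead of by clipping the field formula.

Grid "cells" are sums of truncated Gaussian stamps laid out on a hexagonal
lattice across a wide canvas (``N*8 + 2*kernel`` per side); slices of that
canvas at different offsets model grid-phase remapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ratemaps import RateMap

__all__ = [
    "GaussianFieldSpec",
    "GridModuleSpec",
    "NoiseSpec",
    "make_place_field",
    "make_translated_pair",
    "make_grid_module",
    "grid_periods",
    "add_noise",
]


@dataclass(frozen=True)
class GaussianFieldSpec:
    """An (optionally elliptical, optionally rotated) Gaussian firing field.

    ``sigma_y``/``sigma_x`` are the standard deviations along the row/column
    axes before rotation by ``orientation`` (degrees, counterclockwise in
    (col, -row) image convention; 0 = axis-aligned).
    """

    map_size: int
    centroid: tuple[float, float]
    sigma_y: float = 1.0
    sigma_x: float = 1.0
    orientation: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.map_size < 3:
            raise ValueError("map_size must be >= 3")
        if self.sigma_y <= 0 or self.sigma_x <= 0:
            raise ValueError("field standard deviations must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class GridModuleSpec:
    """Hexagonal module of identical Gaussian fields.

    ``kernel`` is the half-extent (in bins) of each field's truncated stamp;
    ``gap`` is the edge-to-edge separation between neighboring stamps, so the
    horizontal center-to-center spacing is ``2*kernel + gap``.
    """

    map_size: int
    sigma: float = 1.0
    gap: int = 6
    kernel: int | None = None  # default ceil(3*sigma)
    shift: tuple[int, int] = (0, 0)  # (down, right) slice offset on the canvas

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        d, r = self.shift
        if d < 0 or r < 0:
            raise ValueError("shift components must be >= 0")

    @property
    def kernel_extent(self) -> int:
        return int(math.ceil(3 * self.sigma)) if self.kernel is None else self.kernel

    @property
    def spacing(self) -> int:
        """Horizontal center-to-center spacing in bins."""
        return 2 * self.kernel_extent + self.gap


@dataclass(frozen=True)
class NoiseSpec:
    """Per-bin i.i.d. noise, clipped at zero after addition."""

    sigma: float
    seed: int
    distribution: str = "normal"  # or "uniform" (half-width = sigma)
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.distribution not in ("normal", "uniform"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")


def _evaluate_gaussian(
    rows: np.ndarray, cols: np.ndarray, spec: GaussianFieldSpec, centroid: tuple[float, float]
) -> np.ndarray:
    dr = rows - centroid[0]
    dc = cols - centroid[1]
    theta = math.radians(spec.orientation)
    # rotate offsets into the field's principal frame
    ur = math.cos(theta) * dr - math.sin(theta) * dc
    uc = math.sin(theta) * dr + math.cos(theta) * dc
    z = (ur / spec.sigma_y) ** 2 + (uc / spec.sigma_x) ** 2
    return spec.amplitude * np.exp(-0.5 * z)


def make_place_field(spec: GaussianFieldSpec) -> RateMap:
    """Evaluate a Gaussian field on the N x N bin grid (truncated at borders)."""
    n = spec.map_size
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    return RateMap(_evaluate_gaussian(rows, cols, spec, spec.centroid))


def make_translated_pair(
    n: int,
    sigma: float,
    target_centroid: tuple[float, float],
    sigma_x: float | None = None,
    orientation: float = 0.0,
    amplitude: float = 1.0,
) -> tuple[RateMap, RateMap]:
    """A fixed centered field and a copy translated to ``target_centroid``.

    The moved field is generated on a 3N canvas and the central window is
    sliced out, so a target near the border yields a genuinely truncated
    field (mass falls off the map) rather than a re-normalized one.
    """
    if not (0 <= target_centroid[0] <= n - 1 and 0 <= target_centroid[1] <= n - 1):
        raise ValueError("target centroid must lie within the N x N map")
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    sx = sigma if sigma_x is None else sigma_x
    fixed = make_place_field(
        GaussianFieldSpec(n, center, sigma, sx, orientation, amplitude)
    )
    wide_spec = GaussianFieldSpec(
        3 * n,
        (n + target_centroid[0], n + target_centroid[1]),
        sigma,
        sx,
        orientation,
        amplitude,
    )
    wide = make_place_field(wide_spec)
    moved = RateMap(wide.values[n : 2 * n, n : 2 * n])
    return fixed, moved


def _grid_canvas(spec: GridModuleSpec) -> np.ndarray:
    n, k = spec.map_size, spec.kernel_extent
    s = spec.spacing
    if s <= 2 * k:
        raise ValueError("grid spacing too small: fields would overlap")
    side = n * 8 + 2 * k
    canvas = np.zeros((side, side))
    # one truncated Gaussian stamp shared by all fields
    g = np.mgrid[-k : k + 1, -k : k + 1].astype(float)
    stamp = np.exp(-0.5 * (g[0] ** 2 + g[1] ** 2) / spec.sigma**2)
    row_step = int(round(s * math.sqrt(3) / 2))
    half = int(round(s / 2))
    i = 0
    r = k
    while r <= side - 1 - k:
        offset = half if (i % 2) else 0
        c = k + offset
        while c <= side - 1 - k:
            canvas[r - k : r + k + 1, c - k : c + k + 1] += stamp
            c += s
        r += row_step
        i += 1
    return canvas


def make_grid_module(spec: GridModuleSpec) -> RateMap:
    """Slice an N x N grid-cell map out of the wide hexagonal canvas."""
    canvas = _grid_canvas(spec)
    n = spec.map_size
    if canvas.shape[0] < 3 * spec.spacing:
        raise ValueError("canvas too small to hold a 3x3 field neighborhood")
    d, r = spec.shift
    if d + n > canvas.shape[0] or r + n > canvas.shape[1]:
        raise ValueError("shift pushes the slice off the wide canvas")
    return RateMap(canvas[d : d + n, r : r + n])


def grid_periods(spec: GridModuleSpec) -> tuple[int, int]:
    """Lattice periods of the sliced module as (vertical, horizontal) bins.

    Horizontally the pattern repeats every ``spacing`` bins; vertically every
    two rows (``2 * row_step``) because alternate rows are offset by half the
    spacing.
    """
    row_step = int(round(spec.spacing * math.sqrt(3) / 2))
    return 2 * row_step, spec.spacing


def add_noise(m: RateMap, noise: NoiseSpec) -> RateMap:
    """Add i.i.d. per-bin noise, clipping the result at zero.

    Clipping keeps the map a valid mass distribution for the transport
    metrics.  Correlation baselines that want the signed, unclipped noisy map
    can use :func:`noisy_values` instead.
    """
    vals = np.clip(noisy_values(m, noise), 0.0, None)
    return m.with_values(vals)


def noisy_values(m: RateMap, noise: NoiseSpec) -> np.ndarray:
    """The unclipped noisy array (may contain negatives); deterministic."""
    rng = np.random.default_rng(noise.seed)
    if noise.distribution == "normal":
        eta = rng.normal(noise.mu, noise.sigma, m.shape)
    else:
        eta = rng.uniform(noise.mu - noise.sigma, noise.mu + noise.sigma, m.shape)
    return m.values + eta
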