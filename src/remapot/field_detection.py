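"""Firing-field (blob) extraction by peak-rate thresholding.

A firing field is a contiguous set of bins whose rate exceeds a fraction
(default 20%) of the map's peak rate.  "Exceeds" is strict, so bins exactly
at the threshold are excluded, and the threshold is relative — rescaling the
map by any positive constant leaves the extracted bin sets unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ratemaps import RateMap

__all__ = ["FiringField", "detect_fields", "field_centroid", "fields_to_mask"]


@dataclass(frozen=True)
class FiringField:
    """A contiguous above-threshold region of a rate map."""

    bins: np.ndarray  # (k, 2) int array of (row, col)
    centroid: tuple[float, float]  # rate-weighted
    area: int
    peak_rate: float

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=int)
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] == 0:
            raise ValueError("bins must be a nonempty (k, 2) array")
        object.__setattr__(self, "bins", b)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.bins[:, 0], self.bins[:, 1]] = True
        return m


def detect_fields(
    m: RateMap,
    peak_fraction: float = 0.2,
    min_area: int = 1,
    connectivity: int = 4,
) -> list[FiringField]:
    """Label contiguous regions above ``peak_fraction`` of the global peak.

    Returns fields sorted by descending peak rate; an all-zero map yields an
    empty list.  ``connectivity`` is 4 (edge-sharing neighbors) or 8 (also
    diagonal).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if not 0 < peak_fraction < 1:
        raise ValueError("peak_fraction must be in (0, 1)")
    vals = m.values
    peak = vals.max()
    if peak <= 0:
        return []
    above = vals > peak_fraction * peak
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n_labels = ndimage.label(above, structure=structure)
    fields: list[FiringField] = []
    for lab in range(1, n_labels + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < min_area:
            continue
        w = vals[rows, cols]
        centroid = (float(np.sum(rows * w) / w.sum()), float(np.sum(cols * w) / w.sum()))
        fields.append(
            FiringField(
                bins=np.column_stack([rows, cols]),
                centroid=centroid,
                area=int(rows.size),
                peak_rate=float(w.max()),
            )
        )
    fields.sort(key=lambda f: f.peak_rate, reverse=True)
    return fields


def field_centroid(
    field: FiringField, m: RateMap, weighted: bool = True
) -> tuple[float, float]:
    """Centroid of a field: rate-weighted by default, geometric otherwise."""
    rows = field.bins[:, 0].astype(float)
    cols = field.bins[:, 1].astype(float)
    if not weighted:
        return float(rows.mean()), float(cols.mean())
    w = m.values[field.bins[:, 0], field.bins[:, 1]]
    return float(np.sum(rows * w) / w.sum()), float(np.sum(cols * w) / w.sum())


def fields_to_mask(fields: list[FiringField], shape: tuple[int, int]) -> np.ndarray:
    """Union of the fields' bin sets as a boolean map."""
    mask = np.zeros(shape, dtype=bool)
    for f in fields:
        mask[f.bins[:, 0], f.bins[:, 1]] = True
    return mask
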