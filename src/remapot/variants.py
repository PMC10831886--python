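"""Polymorphisms of the transport distance for different remapping questions.

* whole-map: the distance between two full rate maps;
* field-restricted: rates outside detected firing fields are imputed to zero,
  isolating the fields' geometry from background activity;
* binary: 0/1 indicator maps of the fields, silencing rate effects entirely —
  by construction invariant to any rescaling of the source rates;
* centroid distance: plain Euclidean distance between two points;
* region distance: a field against a uniform-mass region (e.g. an arena
  quadrant) when the target is an area rather than a point.

An experimental spike-density variant computes the sliced distance directly
on raw spike positions without binning.
"""

from __future__ import annotations

import math

import numpy as np

from .emd_core import EMDResult, TransportConfig, sliced_emd, sliced_point_emd
from .field_detection import FiringField, fields_to_mask
from .ratemaps import RateMap

__all__ = [
    "whole_map_distance",
    "field_restricted_distance",
    "binary_distance",
    "centroid_distance",
    "region_distance",
    "spike_density_distance",
    "mask_ratemap",
]


def _tagged(result: EMDResult, variant: str) -> EMDResult:
    return EMDResult(
        value=result.value,
        variant=variant,
        normalized=result.normalized,
        n_projections=result.n_projections,
        seed=result.seed,
        slice_correction=result.slice_correction,
    )


def _as_mask(mask, shape: tuple[int, int] | None = None) -> np.ndarray:
    if isinstance(mask, FiringField):
        if shape is None:
            raise ValueError("shape required to rasterize a FiringField")
        return mask.mask(shape)
    if isinstance(mask, (list, tuple)) and mask and isinstance(mask[0], FiringField):
        if shape is None:
            raise ValueError("shape required to rasterize FiringFields")
        return fields_to_mask(list(mask), shape)
    arr = np.asarray(mask)
    if arr.dtype != bool:
        arr = arr > 0
    return arr


def mask_ratemap(m: RateMap, mask) -> RateMap:
    """Impute rates to zero outside the mask (fields keep their rates)."""
    mk = _as_mask(mask, m.shape)
    if mk.shape != m.shape:
        raise ValueError("mask shape must match the map")
    if not mk.any():
        raise ValueError("empty field mask")
    out = np.where(mk, m.values, 0.0)
    if out.sum() <= 0:
        raise ValueError("mask carries no mass")
    return m.with_values(out)


def whole_map_distance(a: RateMap, b: RateMap, config: TransportConfig) -> EMDResult:
    """Sliced distance between the two full maps."""
    return _tagged(sliced_emd(a, b, config), "whole_map")


def field_restricted_distance(
    a: RateMap, fields_a, b: RateMap, fields_b, config: TransportConfig
) -> EMDResult:
    """Sliced distance after zeroing all rates outside the firing fields."""
    return _tagged(
        sliced_emd(mask_ratemap(a, fields_a), mask_ratemap(b, fields_b), config),
        "field",
    )


def binary_distance(mask_a, mask_b, config: TransportConfig,
                    shape: tuple[int, int] | None = None) -> EMDResult:
    """Sliced distance between 0/1 indicator maps of the two field sets.

    Each indicator map is normalized to unit mass, so the result depends only
    on the masks: any change to in-field rates leaves it exactly unchanged.
    """
    ma = _as_mask(mask_a, shape)
    mb = _as_mask(mask_b, shape)
    if not ma.any() or not mb.any():
        raise ValueError("empty field mask")
    cfg = config if config.mass_policy == "normalize" else TransportConfig(
        seed=config.seed,
        n_projections=config.n_projections,
        mass_policy="normalize",
        slice_correction=config.slice_correction,
        distance_scale=config.distance_scale,
    )
    return _tagged(
        sliced_emd(RateMap(ma.astype(float)), RateMap(mb.astype(float)), cfg),
        "binary",
    )


def centroid_distance(
    p1: tuple[float, float], p2: tuple[float, float], distance_scale: float = 1.0
) -> float:
    """Euclidean distance between two (row, col) points, in bin units."""
    if not all(math.isfinite(v) for v in (*p1, *p2)):
        raise ValueError("points must be finite")
    return math.hypot(p1[0] - p2[0], p1[1] - p2[1]) * distance_scale


def region_distance(
    field_map: RateMap, region, config: TransportConfig
) -> EMDResult:
    """Sliced distance between a (masked) field map and a uniform region.

    The region is represented as uniform unit mass over its bins — the
    least-informative mass model for an area target like an arena quadrant.
    """
    mk = _as_mask(region, field_map.shape)
    if not mk.any():
        raise ValueError("empty region")
    region_map = RateMap(mk.astype(float))
    cfg = config if config.mass_policy == "normalize" else TransportConfig(
        seed=config.seed,
        n_projections=config.n_projections,
        mass_policy="normalize",
        slice_correction=config.slice_correction,
        distance_scale=config.distance_scale,
    )
    return _tagged(sliced_emd(field_map, region_map, cfg), "region")


def spike_density_distance(
    points_a: np.ndarray, points_b: np.ndarray, config: TransportConfig
) -> EMDResult:
    """Sliced distance between raw spike-position point sets (experimental).

    Each spike carries equal weight; no binning into a rate map.  This is the
    point-cloud analogue of :func:`binary_distance` for when spike positions
    are available directly.
    """
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    if pa.ndim != 2 or pa.shape[1] != 2 or pb.ndim != 2 or pb.shape[1] != 2:
        raise ValueError("spike positions must be (k, 2) arrays")
    wa = np.full(pa.shape[0], 1.0 / pa.shape[0])
    wb = np.full(pb.shape[0], 1.0 / pb.shape[0])
    return _tagged(sliced_point_emd(pa, wa, pb, wb, config), "spike_density")
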