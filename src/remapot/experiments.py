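"""Scripted sweep experiments comparing transport metrics to correlations.

Each function builds its synthetic inputs, runs the metrics over a grid of
conditions, and returns a tidy :class:`pandas.DataFrame` (one row per
condition) so results can be saved, plotted, or asserted on directly.  Every
stochastic sweep takes explicit seeds; a sweep re-run with the same arguments
is bit-identical.

Canonical pair geometries
-------------------------
The noise experiments use two sigma-1 field pairs on a 17 x 17 map whose
no-noise Pearson baselines pin them down: centroids (8,4)/(8,12) give
r = -0.0454 (wholly non-overlapping) and (8,7)/(8,9) give r = 0.339
(partially overlapping).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baselines import pearson_map, spearman_map
from .emd_core import TransportConfig, emd_1d, single_point_wasserstein
from .field_detection import detect_fields
from .quantiles import build_reference, quantile_of, sample_reference_points
from .ratemaps import RateMap, normalize, smooth
from .synthetic_fields import (
    GaussianFieldSpec,
    GridModuleSpec,
    NoiseSpec,
    add_noise,
    grid_periods,
    make_grid_module,
    make_place_field,
    make_translated_pair,
)
from .variants import (
    binary_distance,
    centroid_distance,
    field_restricted_distance,
    mask_ratemap,
    region_distance,
    whole_map_distance,
)

__all__ = [
    "NON_OVERLAPPING_PAIR",
    "OVERLAPPING_PAIR",
    "translation_sweep",
    "grid_phase_sweep",
    "noise_sweep",
    "scale_sweep",
    "rate_ratio_sweep",
    "rotation_sweep",
    "object_tracking",
    "make_linear_population",
    "make_template",
    "population_decode_1d",
]

# centroid pairs fixed by the published no-noise Pearson baselines (see module docstring)
NON_OVERLAPPING_PAIR = ((8.0, 4.0), (8.0, 12.0))
OVERLAPPING_PAIR = ((8.0, 7.0), (8.0, 9.0))


def translation_sweep(
    n: int = 17,
    sigma: float = 1.0,
    config: TransportConfig | None = None,
) -> pd.DataFrame:
    """One fixed centered field vs. a copy translated to every bin.

    Returns N^2 rows with the centroid separation, sliced EMD, Pearson r and
    Spearman rho per target bin.  The same projection seed is reused for
    every pair so the EMD surface differences reflect geometry, not
    Monte-Carlo noise.
    """
    cfg = config or TransportConfig(seed=0, n_projections=100)
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    rows = []
    for r in range(n):
        for c in range(n):
            fixed, moved = make_translated_pair(n, sigma, (float(r), float(c)))
            rows.append(
                {
                    "target_row": r,
                    "target_col": c,
                    "separation": centroid_distance(center, (r, c)),
                    "emd": whole_map_distance(fixed, moved, cfg).value,
                    "pearson": pearson_map(fixed, moved),
                    "spearman": spearman_map(fixed, moved),
                }
            )
    return pd.DataFrame(rows)


def grid_phase_sweep(
    spec: GridModuleSpec | None = None,
    config: TransportConfig | None = None,
) -> pd.DataFrame:
    """Shift a grid module by (down, right) in [0, N)^2 against shift (0, 0).

    Minima of the EMD recur at lattice-period shifts (horizontal period =
    field spacing; vertical period = two row steps).
    """
    spec = spec or GridModuleSpec(map_size=17, sigma=1.0, gap=6)
    cfg = config or TransportConfig(seed=0, n_projections=100)
    ref = make_grid_module(spec)
    v_period, h_period = grid_periods(spec)
    rows = []
    for down in range(spec.map_size):
        for right in range(spec.map_size):
            shifted = make_grid_module(
                GridModuleSpec(
                    map_size=spec.map_size,
                    sigma=spec.sigma,
                    gap=spec.gap,
                    kernel=spec.kernel,
                    shift=(down, right),
                )
            )
            rows.append(
                {
                    "down": down,
                    "right": right,
                    "emd": whole_map_distance(ref, shifted, cfg).value,
                    "pearson": pearson_map(ref, shifted),
                    "h_period": h_period,
                    "v_period": v_period,
                }
            )
    return pd.DataFrame(rows)


def _noise_pair(pair: str, n: int, sigma: float) -> tuple[RateMap, RateMap]:
    c1, c2 = NON_OVERLAPPING_PAIR if pair == "non_overlapping" else OVERLAPPING_PAIR
    a = make_place_field(GaussianFieldSpec(n, c1, sigma, sigma))
    b = make_place_field(GaussianFieldSpec(n, c2, sigma, sigma))
    return a, b


def noise_sweep(
    pair: str = "non_overlapping",
    sigma_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    seeds=tuple(range(10)),
    pipeline: str = "raw",
    shared_noise: bool = True,
    n: int = 17,
    field_sigma: float = 1.0,
    config: TransportConfig | None = None,
) -> pd.DataFrame:
    """Degrade a field pair with additive noise and track each metric.

    ``shared_noise=True`` (default) adds the same noise field to both maps of
    the pair, modeling a common degradation of the recording session; this is
    the regime in which bin-to-bin correlation is swamped by the shared noise
    (r climbs toward 1) while the raw transport distance barely moves, since
    identical noise mass needs no transport.  ``pipeline`` selects the map
    treatment before scoring: ``raw`` (unnormalized, unsmoothed; distances use
    the scale-to-min mass policy), ``normalized``, or ``smoothed_normalized``.

    Returns one row per (noise sigma, seed) with whole-map EMD, field EMD,
    and Pearson r, plus each metric's no-noise baseline.
    """
    if pair not in ("non_overlapping", "overlapping"):
        raise ValueError("pair must be 'non_overlapping' or 'overlapping'")
    if pipeline not in ("raw", "normalized", "smoothed_normalized"):
        raise ValueError(f"unknown pipeline {pipeline!r}")
    base_cfg = config or TransportConfig(seed=0, n_projections=1000)
    policy = "scale_to_min" if pipeline == "raw" else "normalize"
    cfg = TransportConfig(
        seed=base_cfg.seed,
        n_projections=base_cfg.n_projections,
        mass_policy=policy,
        slice_correction=base_cfg.slice_correction,
        distance_scale=base_cfg.distance_scale,
    )
    a0, b0 = _noise_pair(pair, n, field_sigma)

    def prep(m: RateMap) -> RateMap:
        if pipeline == "smoothed_normalized":
            return normalize(smooth(m))
        if pipeline == "normalized":
            return normalize(m)
        return m

    def score(x: RateMap, y: RateMap) -> dict:
        xp, yp = prep(x), prep(y)
        out = {
            "whole_emd": whole_map_distance(xp, yp, cfg).value,
            "pearson": pearson_map(xp, yp),
        }
        fx = detect_fields(xp)
        fy = detect_fields(yp)
        if fx and fy:
            out["field_emd"] = field_restricted_distance(xp, fx, yp, fy, cfg).value
        else:
            out["field_emd"] = np.nan
        return out

    base = score(a0, b0)
    rows = []
    for sig in sigma_grid:
        for seed in seeds:
            if sig == 0:
                x, y = a0, b0
            else:
                eta_a = NoiseSpec(sigma=float(sig), seed=int(seed))
                eta_b = eta_a if shared_noise else NoiseSpec(
                    sigma=float(sig), seed=int(seed) + 104729
                )
                x, y = add_noise(a0, eta_a), add_noise(b0, eta_b)
            s = score(x, y)
            rows.append(
                {
                    "noise_sigma": float(sig),
                    "seed": int(seed),
                    **s,
                    "whole_emd_base": base["whole_emd"],
                    "field_emd_base": base["field_emd"],
                    "pearson_base": base["pearson"],
                }
            )
    return pd.DataFrame(rows)


def scale_sweep(
    fixed_sigma: float = 3.0,
    sigma_grid=tuple(np.round(np.arange(0.5, 6.01, 0.5), 2)),
    n: int = 33,
    config: TransportConfig | None = None,
) -> pd.DataFrame:
    """Scale a centered field's sigma against a fixed sigma-3 field.

    Reports whole-map, field-restricted and binary EMD in both normalized and
    unnormalized (scale-to-min) regimes, plus the correlations.  The EMD is
    zero at the matched sigma and grows in both directions — scaling down is
    quantified as well as scaling up.
    """
    cfg_n = config or TransportConfig(seed=0, n_projections=1000)
    cfg_u = TransportConfig(
        seed=cfg_n.seed,
        n_projections=cfg_n.n_projections,
        mass_policy="scale_to_min",
        slice_correction=cfg_n.slice_correction,
        distance_scale=cfg_n.distance_scale,
    )
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    fixed = make_place_field(GaussianFieldSpec(n, center, fixed_sigma, fixed_sigma))
    f_fixed = detect_fields(fixed)
    rows = []
    for sig in sigma_grid:
        moving = make_place_field(GaussianFieldSpec(n, center, float(sig), float(sig)))
        f_mov = detect_fields(moving)
        rows.append(
            {
                "sigma": float(sig),
                "emd_normalized": whole_map_distance(fixed, moving, cfg_n).value,
                "emd_unnormalized": whole_map_distance(fixed, moving, cfg_u).value,
                "field_emd_normalized": field_restricted_distance(
                    fixed, f_fixed, moving, f_mov, cfg_n
                ).value,
                "binary_emd": binary_distance(
                    np.any([f.mask(fixed.shape) for f in f_fixed], axis=0),
                    np.any([f.mask(moving.shape) for f in f_mov], axis=0),
                    cfg_n,
                ).value,
                "pearson": pearson_map(fixed, moving),
                "spearman": spearman_map(fixed, moving),
            }
        )
    return pd.DataFrame(rows)


def rate_ratio_sweep(
    ratios=(0.25, 0.5, 1.0, 2.0, 4.0),
    n: int = 17,
    sigma: float = 1.0,
    config: TransportConfig | None = None,
) -> pd.DataFrame:
    """Identical fields at different firing-rate ratios.

    Normalized and binary EMD are invariant to the ratio by construction;
    the unnormalized (scale-to-min) distance is too once the heavier map is
    rescaled, isolating pure rate remapping from spatial remapping.
    """
    cfg_n = config or TransportConfig(seed=0, n_projections=1000)
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    base = make_place_field(GaussianFieldSpec(n, center, sigma, sigma))
    f_base = detect_fields(base)
    mask = np.any([f.mask(base.shape) for f in f_base], axis=0)
    rows = []
    for ratio in ratios:
        scaled = base.with_values(base.values * ratio)
        f_scaled = detect_fields(scaled)
        mask_s = np.any([f.mask(scaled.shape) for f in f_scaled], axis=0)
        rows.append(
            {
                "ratio": float(ratio),
                "emd_normalized": whole_map_distance(base, scaled, cfg_n).value,
                "binary_emd": binary_distance(mask, mask_s, cfg_n).value,
                "pearson": pearson_map(base, scaled),
            }
        )
    return pd.DataFrame(rows)


def rotation_sweep(
    n: int = 33,
    sigma: float = 3.0,
    orbit_radius: float = 8.0,
    angles=tuple(range(0, 361, 15)),
    config: TransportConfig | None = None,
) -> pd.DataFrame:
    """Orbit a moving field around a fixed one and score every angle.

    The moving field's centroid travels a circle of ``orbit_radius`` bins
    around the fixed centroid, reproducing overlap -> disjoint -> overlap.
    For identical translated fields the corrected EMD approximates the chord
    length 2 * radius * sin(angle/2).
    """
    cfg = config or TransportConfig(seed=0, n_projections=1000)
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    start = (center[0], center[1] + orbit_radius)
    if center[1] + orbit_radius > n - 1:
        raise ValueError("orbit exits the map; reduce orbit_radius")
    fixed = make_place_field(GaussianFieldSpec(n, start, sigma, sigma))
    rows = []
    for ang in angles:
        rad = np.deg2rad(float(ang))
        c = (
            center[0] + orbit_radius * np.sin(rad),
            center[1] + orbit_radius * np.cos(rad),
        )
        if not (0 <= c[0] <= n - 1 and 0 <= c[1] <= n - 1):
            raise ValueError("orbit exits the map; reduce orbit_radius")
        moving = make_place_field(GaussianFieldSpec(n, c, sigma, sigma))
        rows.append(
            {
                "angle": float(ang),
                "chord": 2 * orbit_radius * abs(np.sin(rad / 2)),
                "emd": whole_map_distance(fixed, moving, cfg).value,
                "pearson": pearson_map(fixed, moving),
                "spearman": spearman_map(fixed, moving),
            }
        )
    return pd.DataFrame(rows)


def object_tracking(
    n: int = 17,
    sigma: float = 1.0,
    field_centroid: tuple[float, float] = (4.0, 4.0),
    corner_inset: int = 2,
    config: TransportConfig | None = None,
) -> pd.DataFrame:
    """Score a field against four candidate object locations (arena corners).

    Per corner: centroid distance, whole-map-to-point Wasserstein, field-to-
    quadrant EMD, field-to-point Wasserstein, and Pearson r against a one-hot
    object map.  The corner the field overlaps attains every minimum; the two
    corners equidistant from the field share identical map-to-point values
    (the reflective property that flags rotational remapping).
    """
    cfg = config or TransportConfig(seed=0, n_projections=1000)
    lo, hi = float(corner_inset), float(n - 1 - corner_inset)
    corners = [
        ("top_left", (lo, lo)),
        ("top_right", (lo, hi)),
        ("bottom_right", (hi, hi)),
        ("bottom_left", (hi, lo)),
    ]
    field_map = make_place_field(GaussianFieldSpec(n, field_centroid, sigma, sigma))
    fields = detect_fields(field_map)
    masked = mask_ratemap(field_map, fields)
    half = n // 2
    rows = []
    for name, (qr, qc) in corners:
        quadrant = np.zeros((n, n), dtype=bool)
        r_slice = slice(0, half) if qr < half else slice(n - half, n)
        c_slice = slice(0, half) if qc < half else slice(n - half, n)
        quadrant[r_slice, c_slice] = True
        onehot = np.zeros((n, n))
        onehot[int(qr), int(qc)] = 1.0
        rows.append(
            {
                "corner": name,
                "object_row": qr,
                "object_col": qc,
                "centroid_distance": centroid_distance(field_centroid, (qr, qc)),
                "map_to_point_emd": single_point_wasserstein(
                    field_map, (qr, qc), normalize=True
                ),
                "field_to_quadrant_emd": region_distance(masked, quadrant, cfg).value,
                "field_to_point_emd": single_point_wasserstein(
                    masked, (qr, qc), normalize=True
                ),
                "pearson": pearson_map(field_map.values, onehot),
            }
        )
    return pd.DataFrame(rows)


def make_linear_population(
    n_cells: int = 60,
    n_bins: int = 100,
    tuning_sigma: float = 5.0,
    seed: int = 0,
    nonspatial_fraction: float = 0.0,
    noise_sigma: float = 0.0,
    tile: bool = True,
) -> list[RateMap]:
    """Synthetic linear-track population of Gaussian tuning curves.

    Spatial cells get Gaussian tuning curves (sigma in bins) with centers
    tiling the track (or drawn uniformly with ``tile=False``); a fraction of
    non-spatial cells get uniform rate plus noise.  Seeded noise is additive
    Gaussian, clipped at zero.  This is the stand-in for a real 1D population
    recording.
    """
    rng = np.random.default_rng(seed)
    n_nonspatial = int(round(nonspatial_fraction * n_cells))
    n_spatial = n_cells - n_nonspatial
    if tile:
        centers = np.linspace(0, n_bins - 1, n_spatial)
    else:
        centers = rng.uniform(0, n_bins - 1, n_spatial)
    x = np.arange(n_bins, dtype=float)
    maps = []
    for c in centers:
        rate = np.exp(-0.5 * ((x - c) / tuning_sigma) ** 2)
        if noise_sigma > 0:
            rate = np.clip(rate + rng.normal(0, noise_sigma, n_bins), 0, None)
        maps.append(RateMap(rate[np.newaxis, :]))
    for _ in range(n_nonspatial):
        rate = np.full(n_bins, 0.3)
        rate = np.clip(rate + rng.normal(0, max(noise_sigma, 0.1), n_bins), 0, None)
        maps.append(RateMap(rate[np.newaxis, :]))
    return maps


def make_template(
    n_bins: int, kind: str, position: int, width: int = 10, sigma: float = 5.0
) -> np.ndarray:
    """Normalized 1D reference template: one bin, a window, or a Gaussian."""
    t = np.zeros(n_bins)
    if kind == "single_bin":
        t[position] = 1.0
    elif kind == "window":
        lo = max(0, position - width // 2)
        t[lo : lo + width] = 1.0
    elif kind == "gaussian":
        x = np.arange(n_bins, dtype=float)
        t = np.exp(-0.5 * ((x - position) / sigma) ** 2)
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    return t / t.sum()


def population_decode_1d(
    cells: list[RateMap],
    template: np.ndarray,
    reference: str = "across_cells",
    n_reference_points: int = 100,
    reference_seed: int = 0,
) -> pd.DataFrame:
    """Score every cell's 1D map against a reference template.

    Cells are sorted by peak-rate position; per cell the closed-form 1D EMD
    and Pearson r against the template are reported together with a quantile:
    against the other cells' distances (``across_cells``) or against the
    cell's own distances to randomly sampled track positions
    (``within_cell``).  Zero-rate cells are skipped and flagged.
    """
    n_bins = cells[0].n_cols
    if any(c.n_cols != n_bins or not c.is_1d for c in cells):
        raise ValueError("all cells must be 1 x n_bins maps on the same track binning")
    t = np.asarray(template, dtype=float)
    if t.size != n_bins:
        raise ValueError("template length must match the track binning")
    records = []
    for i, cell in enumerate(cells):
        vals = cell.values.ravel()
        if vals.sum() <= 0:
            records.append(
                {"cell": i, "peak_bin": np.nan, "emd": np.nan, "pearson": np.nan,
                 "skipped": True}
            )
            continue
        records.append(
            {
                "cell": i,
                "peak_bin": int(np.argmax(vals)),
                "emd": emd_1d(vals, t, mass_policy="normalize"),
                "pearson": pearson_map(vals, t),
                "skipped": False,
            }
        )
    df = pd.DataFrame(records)
    good = df[~df["skipped"]].copy()
    if reference == "across_cells":
        quantiles = []
        for i, row in good.iterrows():
            others = good.loc[good.index != i, "emd"].to_numpy()
            quantiles.append(quantile_of(build_reference(others), row["emd"]))
        good["quantile"] = quantiles
    elif reference == "within_cell":
        quantiles = []
        pts = sample_reference_points(
            (1, n_bins), "uniform_random", n_reference_points, seed=reference_seed
        )
        for i, row in good.iterrows():
            cell = cells[int(row["cell"])]
            dists = [
                single_point_wasserstein(cell, (0.0, float(p[1])), normalize=True)
                for p in pts
            ]
            obs = single_point_wasserstein(
                cell, (0.0, float(np.argmax(t))), normalize=True
            )
            quantiles.append(quantile_of(build_reference(dists), obs))
        good["quantile"] = quantiles
    else:
        raise ValueError(f"unknown reference {reference!r}")
    good = good.sort_values("peak_bin").reset_index(drop=True)
    good["emd_running_avg"] = good["emd"].expanding().mean()
    good["pearson_running_avg"] = good["pearson"].expanding().mean()
    return good
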