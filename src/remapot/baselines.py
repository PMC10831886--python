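"""Bin-to-bin correlation baselines: Pearson r and Spearman rho.

These are the conventional remapping statistics the transport metrics are
compared against.  Both demand identical map shapes — itself a documented
limitation the EMD side does not share — and both are undefined for constant
maps, in which case ``nan`` is returned with a warning rather than 0, so a
degenerate comparison can never masquerade as "no correlation".
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .ratemaps import RateMap

__all__ = ["pearson_map", "spearman_map"]


def _flatten_pair(a: RateMap | np.ndarray, b: RateMap | np.ndarray):
    va = a.values if isinstance(a, RateMap) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, RateMap) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(
            f"bin-to-bin correlation requires identical shapes, got {va.shape} vs {vb.shape}"
        )
    return va.ravel(), vb.ravel()


def pearson_map(a: RateMap | np.ndarray, b: RateMap | np.ndarray) -> float:
    """Product-moment correlation over flattened bins.

    Accepts raw arrays as well as rate maps so unclipped (signed) noisy maps
    can be correlated, mirroring how correlations tolerate negative values
    while transport metrics do not.
    """
    xa, xb = _flatten_pair(a, b)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        warnings.warn("correlation undefined for a constant map; returning nan")
        return float("nan")
    return float(stats.pearsonr(xa, xb).statistic)


def spearman_map(a: RateMap | np.ndarray, b: RateMap | np.ndarray) -> float:
    """Rank correlation over flattened bins (average ranks on ties)."""
    xa, xb = _flatten_pair(a, b)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        warnings.warn("correlation undefined for a constant map; returning nan")
        return float("nan")
    return float(stats.spearmanr(xa, xb).statistic)
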