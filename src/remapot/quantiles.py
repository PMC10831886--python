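"""Reference quantiles: standardizing raw transport distances.

Raw EMD values are unbounded and depend on arena geometry, bin size and
behavior, so comparisons across animals, sessions or groups standardize them
against a counterfactual distribution — e.g. distances from mismatched cell
pairings within the same ensemble, or distances to randomly sampled
reference locations.  The observed distance is then reported as its quantile
q = n/N, the fraction of reference samples strictly below it, interpretable
as a one-tailed p-value for stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceDistribution",
    "build_reference",
    "build_reference_groups",
    "quantile_of",
    "mismatched_pairs",
    "sample_reference_points",
]


@dataclass(frozen=True)
class ReferenceDistribution:
    """Sorted counterfactual score sample with free-form grouping labels."""

    scores: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("reference requires a nonempty 1D score sample")
        s = np.sort(s)
        s.setflags(write=False)
        object.__setattr__(self, "scores", s)

    @property
    def n(self) -> int:
        return self.scores.size


def build_reference(scores, labels: dict | None = None) -> ReferenceDistribution:
    """Sort a score sample into a reference distribution (multiset kept)."""
    return ReferenceDistribution(np.asarray(scores, dtype=float), labels or {})


def build_reference_groups(scores, group_labels) -> dict[object, ReferenceDistribution]:
    """One reference per subgroup label, for hierarchical data."""
    scores = np.asarray(scores, dtype=float)
    group_labels = np.asarray(group_labels)
    if scores.shape != group_labels.shape:
        raise ValueError("scores and group labels must align")
    return {
        lab: build_reference(scores[group_labels == lab], {"group": lab})
        for lab in np.unique(group_labels)
    }


def quantile_of(
    ref: ReferenceDistribution, observed: float, midrank: bool = False
) -> float:
    """q = (number of reference samples strictly below observed) / N.

    ``midrank=True`` counts ties as half, the conventional mid-rank variant;
    the strict rule is the default.
    """
    lo = int(np.searchsorted(ref.scores, observed, side="left"))
    if not midrank:
        return lo / ref.n
    hi = int(np.searchsorted(ref.scores, observed, side="right"))
    return (lo + 0.5 * (hi - lo)) / ref.n


def mismatched_pairs(n_cells: int, n_pairs: int, seed: int) -> np.ndarray:
    """Seeded (i, j) index pairs with i != j, for across-cell references."""
    if n_cells < 2:
        raise ValueError("need at least two cells to mismatch")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n_cells, n_pairs)
    j = rng.integers(0, n_cells - 1, n_pairs)
    j = np.where(j >= i, j + 1, j)  # skip the diagonal
    return np.column_stack([i, j])


def sample_reference_points(
    map_shape: tuple[int, int],
    scheme: str,
    n: int,
    seed: int = 0,
    min_distance_from: tuple[float, float] | None = None,
    min_distance: float = 0.0,
) -> np.ndarray:
    """In-bounds reference locations for within-cell quantile references.

    Schemes: ``uniform_random`` (seeded), ``rectangular_grid`` (even lattice),
    ``hexagonal_grid`` (offset rows, for circular/masked arenas).  An optional
    exclusion radius around a focal point drops nearby samples; it is an error
    if that leaves nothing.
    """
    rows, cols = map_shape
    if n < 1:
        raise ValueError("n must be >= 1")
    if scheme == "uniform_random":
        rng = np.random.default_rng(seed)
        pts = np.column_stack(
            [rng.uniform(0, rows - 1, 2 * n + 16), rng.uniform(0, cols - 1, 2 * n + 16)]
        )
    elif scheme == "rectangular_grid":
        k = int(np.ceil(np.sqrt(n)))
        r = np.linspace(0, rows - 1, k)
        c = np.linspace(0, cols - 1, k)
        pts = np.array([(ri, ci) for ri in r for ci in c])
    elif scheme == "hexagonal_grid":
        k = int(np.ceil(np.sqrt(n)))
        r = np.linspace(0, rows - 1, k)
        step = (cols - 1) / max(k - 1, 1)
        pts = []
        for i, ri in enumerate(r):
            off = step / 2 if i % 2 else 0.0
            pts.extend((ri, min(ci + off, cols - 1)) for ci in np.linspace(0, cols - 1, k))
        pts = np.asarray(pts)
    else:
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    if min_distance_from is not None and min_distance > 0:
        d = np.hypot(pts[:, 0] - min_distance_from[0], pts[:, 1] - min_distance_from[1])
        pts = pts[d >= min_distance]
        if pts.shape[0] == 0:
            raise ValueError("exclusion radius leaves no feasible reference points")
    return pts[:n]
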