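"""Jenks natural-breaks classification and population summaries.

Access scores are mapped in five classes chosen by Jenks natural breaks —
the optimal partition of the sorted scores into contiguous classes
minimizing within-class sum of squared deviations from class means — with
no-access and excluded blocks kept as their own categorical colours (the
grey / cream convention on access maps) rather than letting zeros absorb
the bottom class.

The breaks are computed by exact dynamic programming over the distinct
values (Fisher's optimal partition), not by the iterative reallocation
heuristic, so small instances agree exactly with exhaustive enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gravity import AccessSurface
from .region import Region

__all__ = [
    "ClassifiedSurface",
    "AccessSummary",
    "jenks_breaks",
    "classify",
    "summarize",
]


def _weighted_jenks(values: np.ndarray, weights: np.ndarray, k: int) -> list[int]:
    """Exact optimal contiguous partition of weighted distinct values.

    Returns the split indices: ``splits[c]`` is the index one past the
    last value of class ``c`` (len k, last entry == len(values)).  Dynamic
    program over prefix sums; O(k n^2) time, exact in the Fisher sense.
    Ties between equal-cost partitions resolve to the smallest split
    indices, making the result deterministic.
    """
    n = len(values)
    w = np.concatenate([[0.0], np.cumsum(weights)])
    wv = np.concatenate([[0.0], np.cumsum(weights * values)])
    wv2 = np.concatenate([[0.0], np.cumsum(weights * values * values)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-class weighted SSE for values[i:j], vectorized over i
        ww = w[j] - w[i]
        sv = wv[j] - wv[i]
        sv2 = wv2[j] - wv2[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            cost = sv2 - np.where(ww > 0, sv * sv / np.where(ww > 0, ww, 1.0), 0.0)
        return np.maximum(cost, 0.0)  # clamp tiny negative round-off

    # best[c, j] = min cost of splitting values[:j] into c+1 classes
    best = np.full((k, n + 1), np.inf)
    back = np.zeros((k, n + 1), dtype=int)
    for j in range(1, n + 1):
        best[0, j] = seg_cost(np.array([0]), j)[0]
    for c in range(1, k):
        for j in range(c + 1, n + 1):
            i = np.arange(c, j)
            tot = best[c - 1, i] + seg_cost(i, j)
            a = int(np.argmin(tot))
            best[c, j] = tot[a]
            back[c, j] = i[a]

    splits = [0] * k
    j = n
    for c in range(k - 1, -1, -1):
        splits[c] = j
        j = back[c, j] if c > 0 else 0
    return splits


def jenks_breaks(values, k: int = 5) -> list[float]:
    """Jenks natural breaks of positive values into ``k`` classes.

    Returns the ``k - 1`` internal break values, each the upper (maximum)
    value of one class; class membership downstream uses inclusive upper
    bounds, so a value equal to a break belongs to the lower class.  Equal
    values are never split across classes.

    Raises
    ------
    ValueError
        If ``values`` is empty, ``k < 1``, or ``k`` exceeds the number of
        distinct values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("jenks_breaks requires a non-empty value collection")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    distinct, counts = np.unique(arr, return_counts=True)
    if k > distinct.size:
        raise ValueError(
            f"cannot form {k} classes from {distinct.size} distinct value(s)"
        )
    if k == 1:
        return []
    splits = _weighted_jenks(distinct, counts.astype(float), k)
    return [float(distinct[s - 1]) for s in splits[:-1]]


@dataclass
class ClassifiedSurface:
    """Access surface with a mapping class per block.

    ``labels`` maps each block to ``"1"``..``"k"`` (class 1 is the lowest
    access), or to the categorical ``"no_access"`` / ``"excluded"``.
    ``breaks`` holds the k-1 internal break values (ascending).
    """

    breaks: list[float]
    labels: dict[str, str]
    k: int
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError(f"breaks must be strictly ascending: {self.breaks}")


def classify(surface: AccessSurface, k: int = 5) -> ClassifiedSurface:
    """Classify scored blocks into ``k`` Jenks classes.

    Breaks are computed on the strictly positive scores only; ``no_access``
    (score 0) and ``excluded`` blocks pass through as their own categories.
    If fewer than ``k`` distinct positive scores exist, ``k`` is reduced to
    that count with a warning; with no positive scores at all the result
    carries only the categorical labels.
    """
    positives = sorted({s for _, s in surface.scored_items() if s > 0})
    k_eff = min(k, len(positives))
    if 0 < k_eff < k:
        warnings.warn(
            f"only {len(positives)} distinct positive scores; "
            f"reducing classes from {k} to {k_eff}",
            stacklevel=2,
        )
    breaks = jenks_breaks(positives, k_eff) if k_eff >= 1 else []

    labels: dict[str, str] = {}
    for bid, st in surface.status.items():
        if st == "excluded":
            labels[bid] = "excluded"
        elif st == "no_access":
            labels[bid] = "no_access"
        else:
            score = surface.scores[bid]
            if score == 0.0:
                # scored-but-zero cannot occur (empty row => no_access),
                # but route it with the zeros if it ever does
                labels[bid] = "no_access"
            else:
                # inclusive upper bounds: value <= break -> lower class
                cls = int(np.searchsorted(breaks, score, side="left")) + 1
                labels[bid] = str(min(cls, max(k_eff, 1)))

    meta = dict(surface.metadata)
    meta["jenks_k_requested"] = k
    meta["jenks_k_effective"] = k_eff
    return ClassifiedSurface(breaks=breaks, labels=labels, k=max(k_eff, 0),
                             metadata=meta)


@dataclass
class AccessSummary:
    """Population-weighted shares of the access landscape per category.

    Categories are the numeric classes plus ``no_access`` and
    ``excluded``; shares sum to 1 over all categories (within floating
    round-off).
    """

    population_by_category: dict[str, float]
    share_by_category: dict[str, float]
    blocks_by_category: dict[str, int]
    total_population: float

    @property
    def no_access_share(self) -> float:
        return self.share_by_category.get("no_access", 0.0)

    @property
    def excluded_share(self) -> float:
        return self.share_by_category.get("excluded", 0.0)


def summarize(region: Region, classified: ClassifiedSurface) -> AccessSummary:
    """Population totals and shares per access category.

    Raises
    ------
    ValueError
        If the classification does not cover every block in the region.
    """
    missing = [b.id for b in region.blocks if b.id not in classified.labels]
    if missing:
        raise ValueError(f"classification missing blocks: {missing}")

    pop: dict[str, float] = {}
    cnt: dict[str, int] = {}
    total = 0.0
    for b in region.blocks:
        cat = classified.labels[b.id]
        pop[cat] = pop.get(cat, 0.0) + b.population
        cnt[cat] = cnt.get(cat, 0) + 1
        total += b.population

    share = {c: (p / total if total > 0 else 0.0) for c, p in pop.items()}
    return AccessSummary(
        population_by_category=pop,
        share_by_category=share,
        blocks_by_category=cnt,
        total_population=total,
    )
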