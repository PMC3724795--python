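"""Bias-threshold filtering of scored tag sets and the matched random-removal
control.

Filtering retains tags whose bias score is at or below a threshold — the
most cleavage-preferred (highest scoring) tags are removed first.  Tags
without a score (window off the contig edge or over an N) carry no evidence
of bias and are always retained.  The control arm removes the same number
of tags uniformly at random, so any difference between the two arms is
attributable to *which* tags were removed, not how many.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import Tag

__all__ = ["ScoredTagSet", "filter_by_score", "remove_random", "threshold_sequence"]


@dataclass
class ScoredTagSet:
    """Tags with a parallel array of bias scores (NaN = unscored edge/N tag)."""

    tags: list[Tag]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.tags) != len(self.scores):
            raise ValueError("tags and scores must have equal length")

    def __len__(self) -> int:
        return len(self.tags)

    def subset(self, mask: np.ndarray) -> "ScoredTagSet":
        idx = np.flatnonzero(mask)
        return ScoredTagSet([self.tags[i] for i in idx], self.scores[idx])

    @property
    def max_score(self) -> float:
        finite = self.scores[~np.isnan(self.scores)]
        if finite.size == 0:
            raise ValueError("no scored tags")
        return float(finite.max())


def filter_by_score(tagset: ScoredTagSet, threshold: float) -> ScoredTagSet:
    """Retain tags with score <= threshold (ties retained); NaN-scored tags
    are kept."""
    keep = ~(tagset.scores > threshold)  # NaN compares False -> kept
    return tagset.subset(keep)


def remove_random(tagset: ScoredTagSet, k: int, seed: int) -> ScoredTagSet:
    """Drop k tags uniformly at random without replacement (seeded)."""
    n = len(tagset)
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    rng = np.random.default_rng(seed)
    drop = rng.choice(n, size=k, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return tagset.subset(keep)


def threshold_sequence(
    scores: Sequence[float] | np.ndarray, step: float = 0.5, floor: float = -1.0
) -> np.ndarray:
    """Descending threshold ladder: max, max-step, ... down to the smallest
    value >= floor.  Thresholds below the floor are excluded (tag sets there
    are too small to call peaks from)."""
    scores = np.asarray(scores, dtype=float)
    finite = scores[~np.isnan(scores)]
    if finite.size == 0:
        raise ValueError("threshold_sequence requires at least one finite score")
    top = float(finite.max())
    if top < floor:
        return np.array([top])
    n_steps = int(np.floor((top - floor) / step + 1e-12))
    return top - step * np.arange(n_steps + 1)
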