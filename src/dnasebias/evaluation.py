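"""Gold-standard construction, base-level precision/recall, F-beta, and the
filtering-sweep experiment.

Predicted DHS calls are compared with a gold-standard interval set (for real
data, the union of transcription-factor narrowPeak files; for simulations,
the planted gold peaks) at single-base resolution: tp is the number of bases
in both sets, fp predicted-only, fn gold-only.  The discriminant score is

    F_beta = (1 + beta^2) * P * R / (beta^2 * P + R)

with beta = 0.5 by default, weighting precision over recall because a
limited TF panel makes recall a conservative estimate.

The sweep experiment walks a descending ladder of bias-score thresholds;
at each threshold one arm removes tags scoring above the threshold, the
control arm removes the same number of tags at random, and both arms are
taken through DHS calling and scoring against the gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dhs_calling import DensityParams, call_dhs
from .filtering import (
    ScoredTagSet,
    filter_by_score,
    remove_random,
    threshold_sequence,
)
from .io_formats import GenomeSequence, Interval, IntervalSet

__all__ = [
    "OverlapCounts",
    "union_intervals",
    "overlap_counts",
    "f_beta",
    "run_filter_sweep",
]


@dataclass(frozen=True)
class OverlapCounts:
    """Base-level confusion counts against a gold standard."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


def union_intervals(*sets: IntervalSet) -> IntervalSet:
    """Minimal sorted disjoint cover of the union of the input bases.

    Accepts any number of interval sets (or a single list of them);
    idempotent.
    """
    if len(sets) == 1 and isinstance(sets[0], (list, tuple)):
        sets = tuple(sets[0])
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        for iv in s:
            by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    out = []
    for contig in by_contig:
        pairs = sorted(by_contig[contig])
        cur_s, cur_e = pairs[0]
        for s, e in pairs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(Interval(contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(Interval(contig, cur_s, cur_e))
    return IntervalSet(out)


def _intersect_bases(a: np.ndarray, b: np.ndarray) -> int:
    """Total overlap between two sorted disjoint (n,2) interval arrays."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def overlap_counts(pred: IntervalSet, gold: IntervalSet) -> OverlapCounts:
    """Base-level tp/fp/fn between predictions and gold standard.

    Both inputs are reduced to disjoint unions first, so overlapping inputs
    are never double counted.
    """
    pred_u = union_intervals(pred)
    gold_u = union_intervals(gold) if len(gold) else IntervalSet()
    pred_by = pred_u.by_contig()
    gold_by = gold_u.by_contig()
    tp = 0
    for contig in set(pred_by) & set(gold_by):
        tp += _intersect_bases(pred_by[contig], gold_by[contig])
    p_total = pred_u.total_bases()
    g_total = gold_u.total_bases()
    return OverlapCounts(tp=tp, fp=p_total - tp, fn=g_total - tp)


def f_beta(precision: float, recall: float, beta: float = 0.5) -> float:
    """Weighted harmonic mean of precision and recall; 0 when both are 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if precision + recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def run_filter_sweep(
    tagset: ScoredTagSet,
    genome: GenomeSequence,
    gold: IntervalSet,
    params: DensityParams = DensityParams(),
    beta: float = 0.5,
    step: float = 0.5,
    floor: float = -1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Threshold sweep comparing bias filtering against random removal.

    Returns a tidy DataFrame with one row per (threshold, arm):
    ``threshold, arm, n_tags, n_dhs, precision, recall, f_beta`` where arm
    is ``"bias"`` or ``"random"``.  At the top threshold both arms equal the
    unfiltered run.  Thresholds at which an arm retains zero tags score 0.
    """
    if len(gold) == 0:
        raise ValueError("gold standard must be non-empty")
    thresholds = threshold_sequence(tagset.scores, step=step, floor=floor)
    n_total = len(tagset)
    seeds = np.random.SeedSequence(seed).generate_state(len(thresholds)) % (2**31)
    rows = []
    for t_i, thr in enumerate(thresholds):
        arm_a = filter_by_score(tagset, thr)
        k = n_total - len(arm_a)
        arm_b = remove_random(tagset, k, int(seeds[t_i]))
        for arm_name, arm in (("bias", arm_a), ("random", arm_b)):
            dhs = call_dhs(arm.tags, genome, params)
            oc = overlap_counts(dhs, gold)
            rows.append(
                {
                    "threshold": float(thr),
                    "arm": arm_name,
                    "n_tags": len(arm),
                    "n_dhs": len(dhs),
                    "precision": oc.precision,
                    "recall": oc.recall,
                    "f_beta": f_beta(oc.precision, oc.recall, beta),
                }
            )
    return pd.DataFrame(rows)
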