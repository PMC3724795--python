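"""Genome-wide motif-score and cut-depth tracks, and the binned
depth-versus-score profile.

At every position the contig is scored on both strands with a single PWM
(log-odds against the expected frequencies) and the maximum of the two
strand scores is taken as the motif score.  The reverse-strand score at
position p is anchored so that p plays the role of the 5' end of a
hypothetical minus-strand tag.  Cut depth counts tag 5' ends per position,
both strands pooled.  Binning the motif scores (0.5-bit bins) and averaging
depth within each bin exposes whether highly preferred cleavage sequences
attract more reads than chromatin state alone would explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bias_model import PWM
from .io_formats import GenomeSequence, IntervalSet, Tag

__all__ = [
    "ScoreTrack",
    "DepthTrack",
    "scan_scores",
    "cut_depth",
    "bin_depth_by_score",
    "profile_trend",
    "region_score_distribution",
]


@dataclass
class ScoreTrack:
    """Per-position motif score (bits), max over strands; NaN where either
    strand window leaves the contig or covers an N."""

    contig: str
    values: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class DepthTrack:
    """Per-position count of tag 5' ends, both strands pooled."""

    contig: str
    values: np.ndarray


def scan_scores(
    genome: GenomeSequence,
    pwm: PWM,
    b: PWM | None = None,
) -> dict[str, ScoreTrack]:
    """Score every position of every contig with a PWM, max over strands.

    With ``b`` given, positions are scored with the M-minus-B weight
    difference instead of the single-PWM log-odds (a diagnostic variant;
    the default single-PWM score is what the depth profile uses).
    """
    weights = pwm.weights if b is None else pwm.weights - b.weights
    W = pwm.window.width
    offsets = pwm.window.offsets
    tracks = {}
    for contig in genome:
        codes = genome.encoded(contig)
        L = len(codes)
        vals = np.full(L, np.nan)
        if L >= W:
            vals_pos = _strand_scan(codes, weights, offsets, minus=False)
            vals_neg = _strand_scan(codes, weights, offsets, minus=True)
            both = np.fmax(vals_pos, vals_neg)
            # defined only where BOTH strand windows fit and are N-free
            both[np.isnan(vals_pos) | np.isnan(vals_neg)] = np.nan
            vals = both
        tracks[contig] = ScoreTrack(contig, vals)
    return tracks


def _strand_scan(
    codes: np.ndarray, weights: np.ndarray, offsets: np.ndarray, minus: bool
) -> np.ndarray:
    """Score of a hypothetical tag 5'-anchored at each position on one
    strand.  Window element j sits at p + offsets[j] (plus strand) or
    p - offsets[j] (minus strand, read as the complement)."""
    L = len(codes)
    # pad with sentinel N so every gather is in-bounds, then mask
    lut = np.vstack([weights, np.full(weights.shape[1], np.nan)])  # row 4 = N
    if minus:
        comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
        codes_eff = comp[codes]
    else:
        codes_eff = codes
    total = np.zeros(L)
    pos = np.arange(L)
    for j, off in enumerate(offsets):
        shift = -off if minus else off
        p = pos + shift
        inb = (p >= 0) & (p < L)
        col = np.full(L, np.nan)
        col[inb] = lut[codes_eff[p[inb]], j]
        total = total + col
    return total


def cut_depth(tags: list[Tag], genome: GenomeSequence) -> dict[str, DepthTrack]:
    """Per-position tag 5'-end counts for every contig of the genome."""
    per_contig: dict[str, list[int]] = {c: [] for c in genome}
    for t in tags:
        per_contig[t.contig].append(t.five_prime)
    tracks = {}
    for contig in genome:
        L = genome.lengths[contig]
        fp = np.asarray(per_contig[contig], dtype=np.int64)
        vals = np.bincount(fp, minlength=L) if fp.size else np.zeros(L, dtype=np.int64)
        tracks[contig] = DepthTrack(contig, vals.astype(np.int64))
    return tracks


def coverage_depth(tags: list[Tag], genome: GenomeSequence) -> dict[str, DepthTrack]:
    """Full-read base coverage alternative to :func:`cut_depth`."""
    tracks = {}
    per_contig: dict[str, list[Tag]] = {c: [] for c in genome}
    for t in tags:
        per_contig[t.contig].append(t)
    for contig in genome:
        L = genome.lengths[contig]
        diff = np.zeros(L + 1, dtype=np.int64)
        for t in per_contig[contig]:
            start = t.five_prime if t.strand == "+" else t.five_prime - t.length + 1
            lo, hi = max(start, 0), min(start + t.length, L)
            if hi > lo:
                diff[lo] += 1
                diff[hi] -= 1
        tracks[contig] = DepthTrack(contig, np.cumsum(diff[:-1]))
    return tracks


def bin_depth_by_score(
    scores: ScoreTrack | dict[str, ScoreTrack],
    depths: DepthTrack | dict[str, DepthTrack],
    bin_width: float = 0.5,
) -> pd.DataFrame:
    """Mean and standard error of depth within half-open score bins
    [k*w, (k+1)*w).

    Returns a DataFrame with columns ``bin_lo, bin_hi, n_positions,
    mean_depth, se_depth`` (SE is NaN for single-position bins).
    Positions with undefined scores are excluded.
    """
    if isinstance(scores, ScoreTrack):
        scores = {scores.contig: scores}
    if isinstance(depths, DepthTrack):
        depths = {depths.contig: depths}
    svals, dvals = [], []
    for contig, st in scores.items():
        dt = depths[contig]
        if len(st.values) != len(dt.values):
            raise ValueError(f"track length mismatch on {contig}")
        mask = st.defined
        svals.append(st.values[mask])
        dvals.append(dt.values[mask])
    s = np.concatenate(svals) if svals else np.array([])
    d = np.concatenate(dvals) if dvals else np.array([])
    if s.size == 0:
        return pd.DataFrame(
            columns=["bin_lo", "bin_hi", "n_positions", "mean_depth", "se_depth"]
        )
    k = np.floor(s / bin_width).astype(np.int64)
    rows = []
    for kk in np.unique(k):
        sel = k == kk
        n = int(sel.sum())
        dd = d[sel].astype(float)
        mean = dd.mean()
        se = dd.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan
        rows.append((kk * bin_width, (kk + 1) * bin_width, n, mean, se))
    return pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "n_positions", "mean_depth", "se_depth"]
    )


def profile_trend(profile: pd.DataFrame, min_positions: int = 100) -> float:
    """Spearman rank correlation between bin score and mean depth, over bins
    holding at least ``min_positions`` positions.

    A monotone trend needs at least 3 qualifying bins to be detectable; with
    fewer the trend is reported as 0.0 (no evidence of a trend).
    """
    sub = profile[profile["n_positions"] >= min_positions]
    if len(sub) < 3:
        return 0.0
    rho = stats.spearmanr(sub["bin_lo"], sub["mean_depth"]).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def region_score_distribution(
    scores: ScoreTrack | dict[str, ScoreTrack],
    regions: IntervalSet,
    n_random: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Defined per-position scores inside ``regions`` versus inside
    ``n_random`` length-matched, uniformly placed regions (seeded).

    Used to ask whether the cleavage motif is enriched in open chromatin
    itself: near-identical distributions say it is not.
    """
    if isinstance(scores, ScoreTrack):
        scores = {scores.contig: scores}
    rng = np.random.default_rng(seed)
    in_scores = []
    for iv in regions:
        st = scores[iv.contig]
        if iv.end > len(st.values):
            raise ValueError(f"region {iv} outside contig bounds")
        vals = st.values[iv.start : iv.end]
        in_scores.append(vals[~np.isnan(vals)])
    widths = [len(iv) for iv in regions]
    contigs = [iv.contig for iv in regions]
    rand_scores = []
    for i in range(n_random):
        w = widths[i % len(widths)]
        contig = contigs[i % len(contigs)]
        st = scores[contig]
        L = len(st.values)
        if L < w:
            raise ValueError(f"contig {contig} too short to place a {w} bp region")
        start = int(rng.integers(0, L - w + 1))
        vals = st.values[start : start + w]
        rand_scores.append(vals[~np.isnan(vals)])
    cat = lambda xs: np.concatenate(xs) if xs else np.array([])
    return cat(in_scores), cat(rand_scores)
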