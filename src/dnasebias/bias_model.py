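"""Biased (M) and background (B) PWM models around DNase-seq cut sites.

The enzyme's sequence preference spans the 5' end of the tag: the window
runs from offset -5 to +9 in read orientation, with offset 0 the first
sequenced base (so 5 flanking bases upstream of the cut plus the first 10
of the tag).  Two position weight matrices are built:

* ``M`` — from the observed tag windows ("biased" model);
* ``B`` — from the same tags shifted 100 bp in the 5' direction, or from
  uniformly random positions ("background" model).

Each tag's *bias score* is the log2 ratio of its window probability under
M versus B, in bits; positive scores mean the tag looks like a preferred
cleavage site.  Column probabilities are pseudocount-smoothed:

    p[b,i] = (count[b,i] + pseudocount * e[b]) / (N + pseudocount)
    w[b,i] = log2(p[b,i] / e[b])

where ``e`` are expected base frequencies (uniform by default, or measured
from open-chromatin intervals).  The pseudocount mass is distributed
proportionally to ``e`` so that a zero-information column has all-zero
weights for any pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    GenomeSequence,
    IntervalSet,
    Tag,
    decode_sequence,
)

__all__ = [
    "Window",
    "CountMatrix",
    "PWM",
    "extract_window",
    "extract_window_codes",
    "gather_windows",
    "build_count_matrix",
    "counts_to_pwm",
    "build_bias_models",
    "shift_tags",
    "random_tags",
    "bias_score",
    "score_tags",
    "score_windows",
    "position_information",
    "expected_freqs_from_intervals",
    "sample_windows_from_probs",
]


@dataclass(frozen=True)
class Window:
    """Inclusive offset range relative to the tag 5' end (offset 0 = first
    sequenced base, negative offsets upstream of the cut)."""

    start_offset: int = -5
    end_offset: int = 9

    def __post_init__(self):
        if self.end_offset < self.start_offset:
            raise ValueError("end_offset must be >= start_offset")

    @property
    def width(self) -> int:
        return self.end_offset - self.start_offset + 1

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.start_offset, self.end_offset + 1)


@dataclass
class CountMatrix:
    """4 x W base counts over the window (rows A,C,G,T in that order).

    ``n_sequences`` is the number of usable (in-bounds, N-free) windows
    counted; every column sums to it.
    """

    counts: np.ndarray
    n_sequences: int
    window: Window
    n_excluded: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, self.window.width):
            raise ValueError(
                f"counts shape {self.counts.shape} != (4, {self.window.width})"
            )
        colsums = self.counts.sum(axis=0)
        if self.n_sequences and not np.all(colsums == self.n_sequences):
            raise ValueError("column sums do not all equal n_sequences")

    @property
    def frequencies(self) -> np.ndarray:
        """Per-column base frequencies f[b, i]."""
        if self.n_sequences == 0:
            raise ValueError("empty count matrix has no frequencies")
        return self.counts / self.n_sequences


@dataclass
class PWM:
    """Log-odds weight matrix in bits.

    Invariant: each column satisfies sum_b 2**w[b] * e[b] == 1, i.e. the
    weights are log-odds of a proper probability column against ``e``.
    """

    weights: np.ndarray
    expected_freqs: np.ndarray
    pseudocount: float
    window: Window

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.expected_freqs = np.asarray(self.expected_freqs, dtype=float)
        if self.weights.shape != (4, self.window.width):
            raise ValueError(
                f"weights shape {self.weights.shape} != (4, {self.window.width})"
            )
        if self.expected_freqs.shape != (4,):
            raise ValueError("expected_freqs must have 4 entries")

    @property
    def probabilities(self) -> np.ndarray:
        """Per-column probability matrix p[b, i] = 2**w * e."""
        return np.exp2(self.weights) * self.expected_freqs[:, None]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PWM)
            and self.window == other.window
            and self.pseudocount == other.pseudocount
            and np.array_equal(self.weights, other.weights)
            and np.array_equal(self.expected_freqs, other.expected_freqs)
        )


# ---------------------------------------------------------------------------
# window extraction


def extract_window_codes(
    tag: Tag, genome: GenomeSequence, window: Window = Window()
) -> np.ndarray | None:
    """Integer-coded window for one tag, or None if it overruns the contig
    or contains N.  For a - strand tag the window is read on the reverse
    complement so that offset 0 is again the first sequenced base."""
    codes = genome.encoded(tag.contig)
    L = len(codes)
    if tag.strand == "+":
        lo = tag.five_prime + window.start_offset
        hi = tag.five_prime + window.end_offset + 1
        if lo < 0 or hi > L:
            return None
        win = codes[lo:hi]
    else:
        lo = tag.five_prime - window.end_offset
        hi = tag.five_prime - window.start_offset + 1
        if lo < 0 or hi > L:
            return None
        win = (3 - codes[lo:hi].astype(np.int8))[::-1]  # revcomp; N (4) -> -1
        if np.any(win < 0):
            return None
        win = win.astype(np.uint8)
    if np.any(win == 4):
        return None
    return win


def extract_window(
    tag: Tag, genome: GenomeSequence, window: Window = Window()
) -> str | None:
    """Window base string in read orientation, or None (edge / N)."""
    codes = extract_window_codes(tag, genome, window)
    return None if codes is None else decode_sequence(codes)


def gather_windows(
    tags: Sequence[Tag], genome: GenomeSequence, window: Window = Window()
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized window extraction for a tag list.

    Returns ``(codes, valid)`` where ``codes`` is an (n_tags, W) uint8 array
    (rows for invalid windows are arbitrary) and ``valid`` is a boolean mask
    of tags whose window is in-bounds and N-free.
    """
    W = window.width
    n = len(tags)
    out = np.zeros((n, W), dtype=np.uint8)
    valid = np.zeros(n, dtype=bool)
    by_contig: dict[str, list[int]] = {}
    for i, t in enumerate(tags):
        by_contig.setdefault(t.contig, []).append(i)
    offsets = window.offsets
    for contig, idx in by_contig.items():
        codes = genome.encoded(contig)  # raises KeyError for unknown contig
        L = len(codes)
        idx = np.asarray(idx)
        fp = np.array([tags[i].five_prime for i in idx])
        minus = np.array([tags[i].strand == "-" for i in idx])
        # position of window element j: fp + offsets[j] on +, fp - offsets[j] on -
        sign = np.where(minus, -1, 1)[:, None]
        pos = fp[:, None] + sign * offsets[None, :]
        ok = (pos >= 0) & (pos < L)
        row_ok = ok.all(axis=1)
        pos_safe = np.clip(pos, 0, L - 1)
        win = codes[pos_safe]
        # complement on the minus strand (N=4 maps to 4 via lookup)
        comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
        win[minus] = comp[win[minus]]
        row_ok &= ~(win == 4).any(axis=1)
        out[idx] = win
        valid[idx] = row_ok
    return out, valid


# ---------------------------------------------------------------------------
# model building


def build_count_matrix(
    tags: Sequence[Tag], genome: GenomeSequence, window: Window = Window()
) -> CountMatrix:
    """Count window bases over all usable tags.

    Tags whose window overruns the contig or contains N are excluded and
    tallied in ``n_excluded``.  Raises ``ValueError`` when no usable window
    remains (an empty model is meaningless).
    """
    if len(tags) == 0:
        raise ValueError("cannot build a count matrix from zero tags")
    codes, valid = gather_windows(tags, genome, window)
    used = codes[valid]
    n = used.shape[0]
    if n == 0:
        raise ValueError("no usable windows (all at contig edges or N-containing)")
    W = window.width
    counts = np.zeros((4, W), dtype=np.int64)
    for j in range(W):
        counts[:, j] = np.bincount(used[:, j], minlength=4)[:4]
    return CountMatrix(counts, n, window, n_excluded=len(tags) - n)


def counts_to_pwm(
    counts: CountMatrix,
    expected_freqs: Sequence[float] | np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> PWM:
    """Turn counts into a log2-odds PWM with pseudocount smoothing.

    ``p[b,i] = (count[b,i] + pseudocount * e[b]) / (N + pseudocount)``,
    ``w = log2(p / e)``.  ``expected_freqs`` defaults to uniform 0.25.
    """
    e = _check_expected(expected_freqs)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    N = counts.n_sequences
    if N + pseudocount == 0:
        raise ValueError("degenerate model: N + pseudocount == 0")
    p = (counts.counts + pseudocount * e[:, None]) / (N + pseudocount)
    if np.any(p == 0):
        raise ValueError(
            "zero-probability cell; use a positive pseudocount with sparse counts"
        )
    weights = np.log2(p / e[:, None])
    return PWM(weights, e, float(pseudocount), counts.window)


def _check_expected(expected_freqs) -> np.ndarray:
    if expected_freqs is None:
        return np.full(4, 0.25)
    e = np.asarray(expected_freqs, dtype=float)
    if e.shape != (4,) or np.any(e <= 0) or abs(e.sum() - 1.0) > 1e-9:
        raise ValueError("expected_freqs must be 4 positive values summing to 1")
    return e


def expected_freqs_from_intervals(
    genome: GenomeSequence, intervals: IntervalSet
) -> np.ndarray:
    """Base frequencies (A,C,G,T) within a set of intervals, N excluded.

    Used to anchor the expected frequencies to open-chromatin composition
    when a DHS/gold interval set is available.
    """
    counts = np.zeros(4, dtype=np.int64)
    for iv in intervals:
        codes = genome.encoded(iv.contig)[iv.start : iv.end]
        c = np.bincount(codes, minlength=5)
        counts += c[:4]
    total = counts.sum()
    if total == 0:
        raise ValueError("intervals contain no ACGT bases")
    return counts / total


def shift_tags(tags: Iterable[Tag], genome: GenomeSequence, shift: int = 100) -> list[Tag]:
    """Shift every tag ``shift`` bp in its 5' direction (upstream of read
    orientation): + strand five_prime decreases, - strand increases.  Tags
    shifted off their contig are dropped."""
    if shift < 1:
        raise ValueError("shift must be >= 1")
    out = []
    for t in tags:
        L = genome.lengths[t.contig]
        fp = t.five_prime - shift if t.strand == "+" else t.five_prime + shift
        if 0 <= fp < L:
            out.append(Tag(t.contig, fp, t.strand, t.length))
    return out


def random_tags(
    tags: Sequence[Tag], genome: GenomeSequence, seed: int | np.random.Generator
) -> list[Tag]:
    """Background tag set at uniformly random positions, matching the input
    per-contig tag counts and strand balance (an alternative to shifting)."""
    rng = np.random.default_rng(seed)
    out = []
    by_contig: dict[str, list[Tag]] = {}
    for t in tags:
        by_contig.setdefault(t.contig, []).append(t)
    for contig, group in by_contig.items():
        L = genome.lengths[contig]
        pos = rng.integers(0, L, size=len(group))
        for t, p in zip(group, pos):
            out.append(Tag(contig, int(p), t.strand, t.length))
    return out


def build_bias_models(
    tags: Sequence[Tag],
    genome: GenomeSequence,
    window: Window = Window(),
    expected_freqs=None,
    pseudocount: float = 1.0,
    background: str = "shift",
    shift: int = 100,
    seed: int = 0,
) -> tuple[PWM, PWM]:
    """Build the biased (M) and background (B) PWM pair from one tag set.

    ``background`` selects the B construction: ``"shift"`` (tags moved
    ``shift`` bp in the 5' direction; keeps the chromosomal distribution of
    real tags) or ``"random"`` (uniform positions, per-contig counts
    matched).
    """
    m_counts = build_count_matrix(tags, genome, window)
    if background == "shift":
        btags = shift_tags(tags, genome, shift)
    elif background == "random":
        btags = random_tags(tags, genome, seed)
    else:
        raise ValueError(f"unknown background {background!r}")
    b_counts = build_count_matrix(btags, genome, window)
    m = counts_to_pwm(m_counts, expected_freqs, pseudocount)
    b = counts_to_pwm(b_counts, expected_freqs, pseudocount)
    return m, b


# ---------------------------------------------------------------------------
# scoring


def _check_pair(m: PWM, b: PWM) -> None:
    if m.window != b.window:
        raise ValueError("M and B PWMs must share the same window")
    if not np.allclose(m.expected_freqs, b.expected_freqs):
        raise ValueError("M and B PWMs must share expected_freqs")


def score_windows(codes: np.ndarray, m: PWM, b: PWM) -> np.ndarray:
    """Bias scores for pre-extracted (n, W) window codes: the per-column
    weight difference summed over the window.  Equals log2(P_M / P_B)
    because the shared expected frequencies cancel."""
    _check_pair(m, b)
    diff = m.weights - b.weights
    cols = np.arange(codes.shape[1])
    return diff[codes, cols].sum(axis=1)


def bias_score(tag: Tag, m: PWM, b: PWM, genome: GenomeSequence) -> float | None:
    """Bias score of one tag in bits, or None for edge/N windows."""
    _check_pair(m, b)
    codes = extract_window_codes(tag, genome, m.window)
    if codes is None:
        return None
    return float(score_windows(codes[None, :], m, b)[0])


def score_tags(
    tags: Sequence[Tag], m: PWM, b: PWM, genome: GenomeSequence
) -> np.ndarray:
    """Bias scores for a tag list (float array; NaN for edge/N windows)."""
    _check_pair(m, b)
    codes, valid = gather_windows(tags, genome, m.window)
    scores = np.full(len(tags), np.nan)
    if valid.any():
        scores[valid] = score_windows(codes[valid], m, b)
    return scores


# ---------------------------------------------------------------------------
# diagnostics & sampling


def position_information(
    counts: CountMatrix, expected_freqs=None
) -> np.ndarray:
    """Per-column information content in bits: the relative entropy of the
    observed column frequencies against the expected frequencies (0*log 0
    taken as 0).  This is what a sequence logo displays."""
    e = _check_expected(expected_freqs)
    f = counts.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / e[:, None]), 0.0)
    return terms.sum(axis=0)


def mean_score_background_se(
    window_freqs: np.ndarray, b_counts: CountMatrix, pseudocount: float = 1.0
) -> float:
    """Delta-method standard error of a mean bias score attributable to
    background-PWM estimation noise.

    ``window_freqs`` are the empirical base frequencies (4, W) of the scored
    windows; ``b_counts`` the counts behind the background model.  The mean
    score is linear in the background weights, and each weight carries
    binomial sampling noise Var(w) ~ (1-p)/(p N ln2^2); covariances between
    bases within a column are negative and ignored, so this is a slight
    overestimate.  Used to set the Monte-Carlo tolerance when comparing
    score means across background constructions (shift lengths, random
    placement).
    """
    e = b_counts  # alias for brevity
    N = e.n_sequences
    p = (e.counts + pseudocount * 0.25) / (N + pseudocount)
    f = np.asarray(window_freqs, dtype=float)
    var = (f**2 * (1 - p) / (p * N)).sum() / np.log(2) ** 2
    return float(np.sqrt(var))


def sample_windows_from_probs(
    probs: np.ndarray, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample n window code rows column-independently from a (4, W)
    probability matrix.  Used for Monte-Carlo checks of the score law."""
    rng = np.random.default_rng(seed)
    probs = np.asarray(probs, dtype=float)
    W = probs.shape[1]
    out = np.empty((n, W), dtype=np.uint8)
    for j in range(W):
        out[:, j] = rng.choice(4, size=n, p=probs[:, j] / probs[:, j].sum())
    return out
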