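# Methods

## Scope and model

`dnasebias` treats a DNase-seq experiment as a point process of cut sites:
each mapped tag is reduced to the 0-based coordinate of its first sequenced
base (the cut), a strand and a length. Two multinomial sequence models are
estimated over the window spanning the cut, offsets −5..+9 in read
orientation (15 columns; offset 0 is the first sequenced base, negative
offsets are genomic flank upstream of the cut):

* the **biased model M**, from the windows of the observed tags;
* the **background model B**, from the same tags shifted a fixed distance
  in the 5′ direction. Shifting keeps the chromosomal distribution of the
  background windows matched to the foreground (same open regions, same
  local composition); a uniform-random-position background is available and
  gives indistinguishable score distributions on unbiased data.

Both models are column-independent (zeroth-order per position). Column
probabilities are smoothed with a pseudocount κ distributed proportionally
to the expected base frequencies e:

    p[b,i] = (count[b,i] + κ·e[b]) / (N + κ),   w[b,i] = log2(p[b,i]/e[b]).

Distributing κ proportionally to e (rather than adding κ/4 per base) makes
the smoothing neutral: a column whose counts match e has exactly zero
weights for any κ, and every column satisfies Σ_b 2^w[b]·e[b] = 1, so the
weights are always log-odds of a proper distribution. The bias score of a
tag is the sum over the window of the M−B weight differences, which equals
log2(P_M(s)/P_B(s)) because the shared e cancels; scores are in bits
throughout (thresholds and bins are specified in half-bit steps, which
makes natural log inconvenient).

Windows that overrun the contig or contain N are excluded from counting and
carry no score (NaN); filtering retains them, since an unscorable tag is
not evidence of bias. Duplicate tags are retained: cut-count statistics
need multiplicity, and deduplication would distort exactly the
over-representation being measured.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| window | −5..+9 | offsets | spans the observed constraint around the cut |
| pseudocount κ | 1.0 | pseudo-observations | negligible at N≈50k; prevents −∞ weights |
| expected freqs e | uniform 0.25 | probability | optionally measured from supplied open-chromatin intervals |
| background shift | 100 | bp | any of 40–200 bp gives the same score distribution (tested) |
| filter rule | score ≤ t kept | bits | ties kept; removing "above threshold" fixes the direction |
| threshold ladder | max → −1, step 0.5 | bits | below −1 too few tags survive to call peaks from |
| F-score β | 0.5 | — | precision-weighted; recall against a finite gold panel is conservative |
| caller bandwidth | 200 | bp (Gaussian σ) | order of a DHS width |
| caller threshold | mean + 4·sd | density | over all positions of tag-bearing contigs |
| caller min length / merge gap | 50 / 0 | bp | suppress sub-nucleosomal calls |

## DHS caller

The caller convolves per-position cut counts with a Gaussian kernel
truncated at ±4σ (FFT convolution; negative ringing on the order of 1e−20
is clipped to zero), thresholds at mean + 4·sd of the density computed over
all positions of contigs carrying at least one tag, bridges sub-threshold
gaps up to `merge_gap`, and emits maximal runs of at least `min_length`
bases. It is deterministic and invariant under tag order. Published
kernel-density callers differ in background normalisation and parameter
conventions; results here should be read as internal to this caller, and
any external caller can be substituted wherever a BED interval set is
accepted (every evaluation function consumes plain intervals).

## Genome scan and depth profile

The per-position motif score is the maximum over the two strands of the
single-model log-odds score, with the reverse-strand window anchored so the
position plays the role of a minus-strand tag's 5′ end (the anchor choice is
covered by a strand-symmetry test: reverse-complementing the genome and
mirroring all tags leaves every score unchanged). A position is defined
only where both strand windows fit inside the contig and contain no N.
Depth is the count of tag 5′ ends at the position, both strands pooled —
the analysis concerns cleavage, not read bodies — with full-read coverage
available as an option. Scores are binned at 0.5-bit width and the per-bin
mean and standard error of depth reported.

The profile's monotone trend is summarised by the Spearman rank correlation
between bin score and mean depth over bins holding ≥ 100 positions. A rank
correlation over fewer than 3 points is meaningless, so `profile_trend`
reports 0.0 (no detectable trend) in that degenerate case; this arises
naturally for near-information-free models, whose score range is narrower
than a single bin.

## Synthetic data generator

The generator emulates the structure the analysis assumes: cut probability
factorizes into chromatin openness and local sequence preference. A tag's
5′ position on a uniformly chosen strand is drawn with weight
`openness(p) · pref(p)`, where openness is `open_enrichment` inside planted
open regions and 1 elsewhere, and pref is the likelihood ratio of the
strand-appropriate window under the injected probability columns q versus
the genome composition e (product over independent columns; 1 where the
window leaves the contig). Because the genome is i.i.d. with base
distribution e, the window sequences of sampled tags are distributed as
Π q_i, so model building should recover q directly — the basis of the
recovery test.

Defaults are the canonical study conditions used by the tests and the
acceptance script: 1 Mb single-contig genome at GC 0.5; 40 non-overlapping
open regions of 1000 ± 200 bp (≈4% of the genome open), each containing a
centred gold peak of half its width; 50,000 tags of length 36 (49 available
to mirror longer-tag protocols); five-fold open-region enrichment; an
injected preference of 6 bits total relative entropy (a fixed 15-base
consensus with a concentration profile peaking at the cut, globally scaled
by bisection to the requested total). These magnitudes are of the order
seen in real chromosome-scale DNase data — a few percent open chromatin,
strong but not deterministic cleavage preference — while keeping a full
pipeline run under a minute.

What the generator deliberately does **not** model: fragment size selection
and the second cut of each fragment (tags are independent cuts), sequencing
error, mappability, PCR duplication structure, GC amplification bias, and
any higher-order (dinucleotide) cleavage preference. Passing tests
therefore show the pipeline's internal consistency — models are recovered,
scores obey their laws, filtering beats matched random removal when the
injected bias is real — not that a particular real library is bias-free.

Position sampling is with replacement, so strongly preferred sites are
drawn repeatedly; model-recovery error is consequently dominated by this
position reuse rather than by plain multinomial noise, and varies a few
hundredths across seeds at the default conditions.

## Numerical and design choices

* Coordinates are 0-based half-open (BED native) everywhere; a − strand
  BED record's 5′ end is `end − 1`.
* The depth profile scans with the single M model rather than the M−B
  difference (the background expectation is provided by a scan with a
  random-tag model instead); an M−B scan is available behind a flag.
* Zero-denominator conventions: precision := 0 with no predicted bases,
  F := 0 when P = R = 0; an empty gold standard is rejected rather than
  scored.
* The random-removal arm re-seeds per threshold from a spawned seed
  sequence, so arms are reproducible and independent across thresholds.
* Monte-Carlo tolerances in tests are stated in standard errors; where a
  comparison is dominated by model-estimation rather than scoring noise
  (background-shift robustness), the tolerance propagates the binomial
  variance of the background weights by the delta method
  (`mean_score_background_se`), slightly overestimating by ignoring
  negative within-column covariances.

## Limitations

Single-PWM, column-independent models cannot represent protocols whose tag
boundaries reflect two nucleases with interacting preferences; for such
data the bias score loses discriminative power and filtering is not
expected to help. The caller's global mean+sd threshold assumes a broadly
stationary background within tag-bearing contigs; strong large-scale
coverage gradients would call for local background correction, which is out
of scope. Genome scanning is plain numpy per contig — adequate to tens of
megabases, not engineered for whole-genome scans.
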