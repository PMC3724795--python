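# dnasebias

DNase-seq infers open chromatin from the genomic density of DNase I cut
sites, but the enzyme itself is sequence-specific: the bases spanning the
cut (window −5..+9 relative to the tag 5′ end) are far from random, so some
reads are over-represented purely because they sit on preferred cleavage
sequences. `dnasebias` is a toolkit for measuring that read-level sequence
bias, filtering biased tags, and quantifying what the filtering buys at the
level of DNase-hypersensitive-site (DHS) calls. It is aimed at people
analysing chromatin-accessibility sequencing data who want to measure or
correct cut-site composition bias, and it ships a synthetic-data generator
with a known injected cleavage preference so the whole pipeline is testable
end to end without any external downloads.

## The model

Two position weight matrices are built over the 15-base window spanning
each tag's cut site (offsets −5..+9 in read orientation, offset 0 = first
sequenced base):

* **M** (biased model) from the observed tag windows;
* **B** (background model) from the same tags shifted 100 bp in the 5′
  direction (or, optionally, from uniformly random positions — the two give
  near-identical score distributions).

Column probabilities are pseudocount-smoothed log-odds against expected
base frequencies *e<sub>b</sub>*:

    p_{b,i} = (f_{b,i} N + κ e_b) / (N + κ),      w_{b,i} = log2(p_{b,i} / e_b)

with κ = 1 by default and *e* either uniform or measured from
open-chromatin intervals. Each tag *T* with window sequence *s* gets a
**bias score** in bits,

    score(T) = log2( P_M(s) / P_B(s) ) = Σ_i ( w^M_{s_i,i} − w^B_{s_i,i} ),

positive when the tag looks like a preferred cleavage site. Filtering
removes tags scoring above a threshold; a matched control removes the same
number of tags at random. Each filtered set goes through a Gaussian
kernel-density DHS caller, and calls are compared with a gold-standard
interval set at base-level precision *P* and recall *R*, summarised by

    F_β = (1 + β²) P R / (β² P + R),   β = 0.5

(precision-weighted, because a finite gold-standard panel makes recall a
conservative estimate).

## Worked example

```python
import numpy as np
from dnasebias import synthetic_data as sd, bias_model as bm
from dnasebias.filtering import ScoredTagSet
from dnasebias.evaluation import run_filter_sweep

# 1 Mb genome, 50,000 tags cut with a 6-bit sequence preference,
# five-fold enriched in 40 planted open regions
truth = sd.simulate(sd.SimulationConfig(seed=42))

m, b = bm.build_bias_models(truth.tags, truth.genome)
scores = bm.score_tags(truth.tags, m, b, truth.genome)
print(f"mean bias score: {np.nanmean(scores):.2f} bits "
      f"(range {np.nanmin(scores):.1f} .. {np.nanmax(scores):.1f})")

sweep = run_filter_sweep(ScoredTagSet(truth.tags, scores),
                         truth.genome, truth.gold_peaks, seed=0)
wide = sweep.pivot(index="threshold", columns="arm", values="f_beta")
best = wide["bias"].idxmax()
print(f"unfiltered F_0.5: {wide.loc[wide.index.max(), 'bias']:.3f}")
print(f"best bias-filtered F_0.5: {wide.loc[best, 'bias']:.3f} at threshold {best:.1f}")
print(f"random-removal F_0.5 at that threshold: {wide.loc[best, 'random']:.3f}")
```

Output:

```
mean bias score: 6.33 bits (range -12.8 .. 14.2)
unfiltered F_0.5: 0.283
best bias-filtered F_0.5: 0.715 at threshold 4.7
random-removal F_0.5 at that threshold: 0.294
```

Tags drawn with the injected preference score strongly positive on average
(the tag set *is* enriched for preferred cleavage sequences). Removing the
highest-scoring tags more than doubles the discriminant score of the DHS
calls against the planted gold peaks, while removing the same number of
tags at random leaves it essentially unchanged — so the gain comes from
*which* tags were removed, not how many.

## Command line

The same pipeline is available as `dnase-bias` subcommands, reading and
writing standard formats (FASTA genome, BED6 tags, BED3/narrowPeak
intervals, JSON PWMs):

```bash
dnase-bias simulate --n-tags 50000 --seed 1 --outdir sim/
dnase-bias build-pwm --tags sim/tags.bed --genome sim/genome.fa --out m.pwm b.pwm
dnase-bias score    --tags sim/tags.bed --genome sim/genome.fa --m m.pwm --b b.pwm --out scores.tsv
dnase-bias filter   --scores scores.tsv --threshold 2.0 --out filtered.bed
dnase-bias call     --tags filtered.bed --genome sim/genome.fa --out dhs.bed
dnase-bias evaluate --dhs dhs.bed --gold sim/gold_peaks.bed
dnase-bias sweep    --scores scores.tsv --genome sim/genome.fa --gold sim/gold_peaks.bed --out sweep.tsv
```

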