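# Methods

## The generative model of the fractionation experiment

Each transcript *i* carries a population of molecules whose poly(A) tail
lengths follow a gamma law with fixed shape *s* (default 2) and mean *m*
(default 75 nt). A gamma was chosen because measured tail-length
distributions are non-negative and right-skewed; the shape parameter
controls spread without affecting the mean. In the WT condition, target
transcripts have mean *m + δ·e_i*, where δ (default 150 nt, 300 nt in the
high-power scenarios) is the population-mean tail extension and *e_i* is a
per-target effect multiplier drawn from a gamma with mean 1 and CV 0.35
(`TailModel.delta_cv`). Heterogeneous substrate response matters for two
reasons: real enzymes extend different substrates to different degrees, and
the polyadenylation–expression coupling analysis is only informative when
effect sizes vary — with one common effect, every hit shares one true ratio
and one true fold change and the rank correlation would estimate nothing.
The optional stability coupling multiplies each target's WT abundance by
`1 + stability_coupling · e_i`, tying the expression gain to the realized
tail extension.

The stepwise elution is modelled as a soft ordered partition: a molecule
with tail length L elutes in fraction j with probability given by
successive differences of logistic CDFs centred at fixed breakpoints
(defaults 30/60/100/150/220 nt, logistic scale 10 nt). Only the ordering of
the breakpoints matters to the downstream statistic; softness models the
imperfect separation of a salt gradient. Per-transcript expected fraction
profiles are the integral of these probabilities against the gamma tail
law, computed by 200-node Gauss–Legendre quadrature in quantile space —
the infinite-molecule limit of per-molecule assignment. Tests verify this
against a Monte-Carlo oracle that samples 10⁴ molecules per transcript.

Sequencing is compositional: each (condition, fraction, replicate) library
splits its depth (default 10⁶ reads, log-normal jitter with sdlog 0.15)
across the molecules present in that fraction's pool plus the spike-ins,
then perturbs the expected counts with gamma–Poisson (negative binomial)
noise at a single dispersion (default 0.05, a typical bulk RNA-seq value).
Spike-ins (default 92, log-spaced over four orders like an ERCC mix, ~5% of
library mass) are added in equal expected amounts to every library — they
are the only fraction-independent anchor, which is exactly why they drive
normalization. Per-transcript relative abundance is log-normal with sdlog
0.8, the spread of an expressed-transcript population after the usual
high-expression filtering. One RNG sub-stream per library (spawned from a
single master seed) makes every output byte-reproducible.

Transcript annotation: mRNA lengths log-normal (median 2 kb), 3′-UTR
lengths log-normal (median 600 nt), UTR sequences i.i.d. uniform ACGT.
`utr_length_bias` scales target UTR lengths (0.5 halves them);
`planted_motif` overwrites random UTR positions of targets with copies of
a motif (about one copy per 150 nt). What the generator does **not**
emulate: transcript-specific GC/mappability biases, isoform structure,
positional coverage, batch effects, and correlated dispersion — so a
passing benchmark shows the statistical machinery is correct and
calibrated under its stated noise model, not that every real-data artefact
is handled.

## The shift statistic and its null

Size factors are per-library sums over spike-in rows (or all rows in
`total` mode), rescaled to geometric mean 1. Replicates are averaged
(arithmetic mean of normalized counts) before the ratio; the default
pseudocount α = 0.5 keeps every ratio finite (with α = 0 a zero denominator
yields NaN, flagged rather than fatal). The statistic is computed as a
difference of log2 terms rather than a log of a quotient so that swapping
the WT/mut labels negates every value bit-exactly.

The null over log-ratios is fitted with median location and 1.4826 × MAD
scale. Two facts motivate this. First, the substrate population is a
right-tail contamination which would inflate a plain mean/SD fit; the
robust fit keeps an O(ε) bias only (for 5% contamination at +5σ the median
shifts by Φ⁻¹(0.5/0.95) ≈ 0.066σ, versus +0.25σ for the mean). Second, the
null's *location* genuinely varies from run to run: all transcripts share
the same handful of libraries, so residual size-factor error is a
library-level random effect that shifts the whole histogram by up to a few
tenths of a log2 unit. Referencing z-scores to the fitted null rather than
to zero absorbs this — which is why the hit rate stays calibrated even
though per-run μ is not centred at 0 more tightly than that effect allows.

Hits: one-sided right-tail normal p, BH within each long fraction,
q ≤ 0.05 by default, required in **both** fractions 5 and 6, plus a
minimum mean normalized fraction-1 count of 10 across conditions
(degenerate edge: when every z is 0, p = q = 0.5, so thresholds at or
above 0.5 are outside the meaningful range of the FDR cutoff).

## Downstream analyses

- **Concordance**: exact overlap counts; hypergeometric upper-tail p for
  the overlap given |A|, |B| and the universe.
- **Length bias**: median(hits) − median(non-hits) for UTR or mRNA length;
  left-tail permutation p over same-size random hit sets with +1 smoothing
  (p ≥ 1/(n_perm+1); default n_perm = 1000).
- **k-mer enrichment**: overlapping occurrence frequencies pooled per set
  with +0.5 occurrence smoothing; one-sided p by permuting sequence labels
  between foreground (hit UTRs) and background (UTRs of all
  expression-passing transcripts); BH over all 4^k k-mers; reported as RNA
  (U for T). Exhaustive k-mer statistics stand in for de-novo motif
  discovery because the biological signal of interest is dinucleotide
  composition (GU/CU-richness), which k-mers capture directly.
- **Expression coupling**: Spearman ρ between the combined hits' mean long-
  fraction log2 ratio and their total-expression log2 fold change (summed
  normalized counts across fractions, WT vs mut). Because the fold change
  reuses the same libraries as the ratio, shared noise adds a small
  positive baseline (|ρ| ≲ 0.1–0.2 at zero true coupling); results with
  fewer than 10 hits are flagged unreliable.
- **Label enrichment**: a generic hypergeometric test of any boolean
  transcript label among hits, standing in for web-service functional
  annotation clustering.

## Co-IP LFQ scoring

Abundance = mean bait LFQ / molecular weight (kDa); specificity = mean
bait LFQ / background, where background is the mean control LFQ or a floor
of 1 raw LFQ unit when the protein is never detected in the control.
Replicate runs are reduced by the arithmetic mean per arm, LFQ = 0 means
undetected, proteins undetected in every bait run are dropped, and
contaminant-flagged proteins stay in the scored table but are excluded
from plot export. Scaling every intensity by c scales abundance by c and
leaves specificity unchanged for control-detected proteins (floored
proteins scale, since their background is absolute).

## Numerical and design choices

- Benjamini–Hochberg via `statsmodels.stats.multitest`; an independent
  step-up oracle backs it in the tests.
- Hypergeometric tail via `scipy.stats.hypergeom`, checked against full
  enumeration on a 10-element universe.
- Quadrature: 200 Gauss–Legendre nodes; allocation probabilities
  renormalised to machine precision (they sum to 1 analytically).
- Degenerate inputs: constant log-ratios raise a degenerate-null error;
  fewer than 3 finite ratios refuse to fit; empty or exhaustive hit sets
  refuse the permutation test.
- Problem sizes in the shipped benchmark runs: 5,000 transcripts × 20 seeds
  for null calibration, 2,000 transcripts at δ = 300 nt and 10⁶
  reads/library for recovery and concordance, 600 transcripts for motif
  planting — sizes at which every reported quantity is stable to the
  stated tolerances while a full run stays fast on a laptop.
- Provenance: every TSV carries a `# polyafrac=<version> seed=…
  config_sha=…` first line; the hash covers the analysis-determining
  config fields only (not output location or verbosity), so identical
  analyses produce identical bytes.

## Known limitations

Single-replicate designs (the default, mirroring one library per
condition-fraction) give the ratio no within-condition variance estimate —
significance rests entirely on the cross-transcript null, as in the
original analysis style this implements. The expression-coupling estimate
shares libraries with the ratio (above). The generator's UTR background is
compositionally uniform, so k-mer q-values on real UTRs (which are AU-rich
and repeat-laden) should be interpreted against the matched expressed
background, never against the uniform model.
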