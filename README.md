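# polyafrac

Analysis toolkit for **poly(A) tail-length fractionation RNA-seq**: find the
transcripts that a non-canonical poly(A) polymerase actually polyadenylates,
characterise their 3′-UTRs, and score the enzyme's protein interactors from
Co-IP label-free proteomics.

## Who this is for

In a fractionation experiment, total mRNA is bound to oligo-dT beads and
eluted stepwise at decreasing salt, partitioning molecules into ordered
fractions by poly(A) tail length (fraction 1 = shortest tails, fraction 6 =
longest). Each fraction of each condition — cells expressing the active
enzyme (WT) versus its catalytic mutant (mut) — is sequenced as one library,
with ERCC-style spike-ins anchoring between-library normalization. The
question is which transcripts *shift* into the long-tail fractions when the
enzyme is active.

## The statistic

For each transcript and each long fraction k ∈ {5, 6}, with
replicate-averaged spike-normalized counts n and pseudocount α:

```
log2 R_k  =  log2 [ (n_k + α)/(n_1 + α) ]_WT  −  log2 [ (n_k + α)/(n_1 + α) ]_mut
```

Most transcripts are unaffected and scatter around the centre of the
distribution; substrates form a right-tail outlier population. The null is
therefore fitted **robustly** — μ = median, σ = 1.4826 × MAD — so outliers do
not inflate it. One-sided right-tail p-values from N(μ, σ²) are
Benjamini–Hochberg adjusted within each fraction; a **combined hit** must be
significant (q ≤ 0.05 by default) in *both* long fractions and pass a
minimum-expression filter on its short-fraction abundance.

Downstream, the package compares hit sets between experiments
(hypergeometric overlap), tests hits for shorter 3′-UTRs/mRNAs (permutation
test), runs exhaustive k-mer enrichment of hit UTRs against all expressed
transcripts (label permutation, reported in the RNA alphabet — e.g. GU/CU
dinucleotides), and correlates polyadenylation with steady-state expression
change (Spearman). The Co-IP module scores each protein by *abundance*
(mean bait LFQ / molecular weight) and *specificity* (mean bait LFQ /
control background, floored at 1 for control-undetected proteins).

A fully parameterised generator simulates the whole experiment — gamma
tail-length laws, soft logistic elution boundaries, negative-binomial
sequencing noise, constant spike-ins, and a target subpopulation with
elongated tails, optional shorter/motif-planted UTRs and tail-coupled
abundance gain — with ground-truth labels for benchmarking.

## Worked example

```python
from polyafrac import (SimConfig, TailModel, simulate_experiment,
                       PolyadenylationShiftModel)
from polyafrac.downstream import length_bias_test, expression_coupling

cfg = SimConfig(n_transcripts=2000, target_fraction=0.1, seed=1,
                tail_model=TailModel(delta=300.0, stability_coupling=1.0),
                utr_length_bias=0.5)
exp = simulate_experiment(cfg)
res = PolyadenylationShiftModel(exp.counts).fit()
print(res.summary())
```

```
Polyadenylation shift analysis
==============================================
transcripts analysed : 2000
normalization        : spikein
pseudocount          : 0.5
q threshold (BH)     : 0.05
min expression (f1)  : 10.0
fraction 5 null      : mu=+0.0000 sigma=0.8171 (n=2000); hits=203
fraction 6 null      : mu=-0.0511 sigma=0.8282 (n=2000); hits=204
combined hits        : 199
```

199 of the 200 planted targets are recovered as combined hits
(sensitivity 0.995) with no false positives. Continuing:

```python
annot = exp.transcripts[~exp.transcripts.is_spikein]
bias = length_bias_test(res.hits, annot, "utr3_length", n_perm=1000, seed=1)
# bias.median_difference = -314.0, bias.p_value = 0.000999  (hits have
# much shorter 3'-UTRs, as planted with utr_length_bias=0.5)

coupling = expression_coupling(res.ratio_table, res.expression_log2fc())
# coupling.rho = 0.487, p = 2.9e-13 over 199 hits: transcripts that gain
# more tail also gain more steady-state abundance (stability_coupling=1)
```

`res.plot_ratio_histogram(5)` draws the log-ratio histogram with the fitted
normal null overlaid, the standard visualisation of the outlying substrate
population.

### Command line

```
polyafrac simulate --out sim/ --seed 1
polyafrac ratio --counts sim/counts.tsv --samples sim/samples.tsv \
    --annotation sim/annotation.tsv --q 0.05 --out fit/
polyafrac features --ratio-table fit/ratio_table.tsv \
    --annotation sim/annotation.tsv --utrs sim/utrs.fasta --k 2 --out feat/
polyafrac coip --lfq lfq.tsv --runs runs.tsv --out coip/
polyafrac run-all --config config.yaml --out out/ --seed 1
```

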