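# Methods

This note records the models, default parameters and numerical choices
behind each module, in enough detail to re-derive every constant that
appears in the code and tests.

## Consensus-to-profile conversion and mismatch thresholds

An IUPAC consensus of length L becomes an L×4 probability matrix: each
position places a total mass of 0.85 uniformly on the bases allowed by
its IUPAC code and the remaining 0.15 uniformly on the disallowed bases.
`N` positions get a uniform 0.25 row. Scores are log-odds (base 2)
against a uniform 0.25 background, so the consensus score is the sum of
per-position row maxima.

The acceptance threshold admits exactly the Hamming ball of radius *k*
around the consensus. Each position has a fixed score *drop* between its
best and worst allowed outcome; the worst sequence still within *k*
mismatches loses the *k* largest drops, so

```
threshold = consensus_score − sum of the k largest per-position drops.
```

Because `N` rows are flat their drop is zero and they never count as
mismatches. For `AGAACA` with k = 2 this admits exactly
1 + 18 + 135 = 154 of the 4096 hexamers, verified exhaustively in the
test suite. Score comparisons carry a slack of 1e-9 to absorb float
summation order.

Assembly operations:

- **Palindrome**: half-site + `N`×spacer + reverse complement of the
  half-site. With the hexamer `AGAACA` and a 3-nt spacer this yields the
  canonical 15-bp ARE `AGAACANNNTGTTCT`, which is its own reverse
  complement.
- **Chimeras**: two distinct elements joined with `N`×spacer for every
  spacer length in a range, in both orders. The default range 0–8
  produces 18 composite motifs per element pair.

Scanning is vectorized: sequences are byte-encoded and window scores
computed from an L×5 lookup table (the fifth column holds the row
minimum, the score assigned to ambiguous bases). The minus strand is
scanned with the reversed, complement-permuted matrix, which is exactly
the score of the reverse-complement window. When both strands of a
palindromic profile pass at the same position, only the + strand hit is
kept.

## Motif enrichment

Enrichment is computed on per-peak presence (a peak either contains at
least one passing window or it does not). With t target peaks
(t_with positive) and b background peaks (b_with positive), the p-value
is the hypergeometric tail over the pooled population: the probability
of drawing at least t_with positives when t peaks are drawn from
t + b peaks of which t_with + b_with are positive. The implementation
uses `scipy.stats.hypergeom.sf(t_with − 1, …)`; the test suite pins it
against an independent exact-rational summation (`fractions.Fraction`)
to 1e-9 relative error, and against a 10,000-draw permutation estimate
within 3 Monte-Carlo standard errors.

Fold change is the ratio of positive fractions,
`(t_with/t) / (b_with/b)`; a pseudocount of one background positive is
applied only when b_with = 0, so exact ratios (e.g. the 8.0 of the
planted 40%-vs-5% design) are never perturbed.

When no background cistrome is supplied, one is sampled GC-matched to
the target: target peaks are binned by GC fraction, and candidate
intervals of the same widths are drawn from the genome under a quota per
bin, rejecting candidates that overlap the target set or one another
(bisection over a sorted occupied-span list keeps this near-linear). A
budget of 500 attempts per requested interval bounds the runtime; an
infeasible request raises an error reporting the achieved count.

Proximity co-occurrence counts anchor hits having a partner-motif hit in
the same peak with edge-to-edge distance ≤ the window (default 25 bp;
overlap counts as distance 0).

## Interval conventions

All intervals are 0-based, half-open (BED convention). "Within G bp" is
an edge-gap test: two peaks whose gap is exactly G merge, gap G + 1 does
not (the suite bisects this at the 500-bp default). Overlap
classification first merges each cistrome with the same gap, then
labels merged units as shared or exclusive; shared clusters are counted
once per connected component. Annotation takes the peak midpoint with
priority promoter (TSS ± 1 kb) > exon > intron > intergenic.

Coverage from bedGraph intervals is held with prefix integrals so that
the integral over any span — the quantity used for domain signal and
heatmap bins — is an O(log n) lookup.

## Super-enhancer calling

Peaks with edge gap ≤ 12,500 bp are stitched into domains. Each domain's
signal is the coverage integral over the stitched span. Domains are
ranked ascending by signal; both axes are normalized
(x = rank/n, y = signal/max). Local slopes come from central differences
(one-sided at the ends). The cutoff is the first index whose slope
reaches the threshold (default 1.0, the scale on which the diagonal has
slope 1 after normalization); every domain strictly above that index is
a super-enhancer. Degenerate curves — all-zero signal or constant slope
— call nothing (all-zero also warns). On strictly convex curves this
rule coincides with the independent "diagonal tangent" oracle
(argmin of y − x), which the suite verifies on analytic curves and on
the synthetic track.

Wild-type/knockout comparison matches called domains by span on the same
chromosome; lost fraction is the share of wild-type super-enhancers with
no matching knockout super-enhancer.

## Screen ranking and synergy

Counts are CPM-normalized per arm; the per-guide statistic is
`log2((cpm_LOW + 0.5) / (cpm_HIGH + 0.5))`, ranked descending (guides
disabling a coactivator enrich in the LOW gate). Gene scores aggregate
guides by mean (median optional) and also report the second-best guide.
Bliss synergy is the excess of observed combined inhibition over
`a + b − a·b`, elementwise over scalars or arrays.

## Synthetic data generators

The generators' defaults are the study conditions, not tuned values.

- **Genome**: i.i.d. bases at a given GC fraction (default 0.5),
  seeded.
- **Planted peaks**: fixed-width peaks (default 200 bp) placed without
  overlap (minimum edge gap 600 bp so that downstream 500-bp merging
  never fuses distinct peaks); a chosen fraction receives one exact
  instance of the motif (IUPAC letters resolved uniformly at random) at
  a random offset. The ground-truth table records placement, offset and
  instance. With fraction 0 the per-peak hit rate of a k = 0 profile
  matches the closed-form Hamming-ball window probability, which the
  suite checks within 3 binomial standard errors.
- **Signal track**: typical enhancers (default 90) get
  base × lognormal(σ = 0.25) coverage over 1-kb spans; amplified
  clusters (default 10) each span 20 kb with 4 constituent 1-kb spans
  whose coverage is amplification × (1 + 0.25·j) × base for cluster j —
  a deterministic amplification ladder. The ladder guarantees, for any
  seed, that cluster signals are well separated from the lognormal
  typical range, so cluster recovery and the reported minimum
  super-enhancer slope are seed-independent. Spacing (minimum gap
  13.5 kb) keeps distinct generated units from stitching together at
  the 12.5-kb default.
- **Knockout track**: a chosen fraction of clusters drops to a residual
  of base/constituents coverage, returning the deleted cluster's total
  signal to that of one typical enhancer — complete off-loading of
  amplified binding over ordinary background.
- **Screen counts**: negative-binomial with
  variance μ + α·μ² (`rng.negative_binomial(1/α, (1/α)/(1/α + μ))`),
  degenerating to Poisson at α = 0; planted genes multiply the LOW-arm
  mean by 2^δ. Note that CPM normalization attenuates measured effects
  by log2 of the total-count inflation the planted genes cause; the
  tests account for this closed form rather than ignoring it.

## Pipeline

`neocistrome run` executes the stages in order — motif assembly, peak
simulation and planting, enrichment against the planted background,
proximity, overlap/annotation, super-enhancer calling with a knockout
comparison, and screen scoring — logging stage timings to stderr and
`run.log`, and writing every artifact plus the resolved YAML config to
the output directory. All stages are deterministic given the config;
rerunning a config reproduces byte-identical data artifacts.

## Limitations

- The simulators are calibration tools, not realistic genome models: no
  repeat structure, no copy-number variation, no read-level noise, and
  enhancer coverage is piecewise-constant rather than peak-shaped.
- Per-peak presence discards multiplicity; motifs occurring many times
  in one peak count once.
- The hypergeometric test assumes peaks are exchangeable between target
  and background; supplying a biased background biases the test.
- Super-enhancer calling assumes a single signal track on one scale;
  cross-sample comparisons require prior normalization.
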