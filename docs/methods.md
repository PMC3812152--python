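# Methods

## Model and procedure

The working assumption is that local co-occurrence of ChIP-seq binding loci
for many transcription factors marks regulatory sequence, so point variants
inside such regions are more likely than average to perturb transcription
regulation. The pipeline formalizes this in four steps: interval clustering,
density-based trimming, an enrichment statistic with bootstrap uncertainty,
and allele-specific motif scoring.

### Coordinates

All internal coordinates are 0-based, half-open (BED convention). 1-based
sources — VCF positions and `chrom:start-end` region strings (1-based,
inclusive, commas tolerated) — are converted at the parsing boundary and
nowhere else. Abutting intervals (`end == start`) do **not** overlap; this
is a deliberate consequence of half-open arithmetic and is tested.

### OTFR construction

Peaks are grouped per chromosome by single-linkage transitive overlap
(≥ 1 bp shared). "*i* overlapping TF binding loci" is counted as the
**total member peaks of a cluster**, not the pointwise stack depth: the
per-SNP annotation reports both numbers (depth at the position / cluster
peak count), and the cluster-level count is what thresholds the OTFR set.
Duplicate peak records, and several peaks of the same factor, each count
once per record; deduplication is intentionally not the default because the
input track reports peaks, not unique factors.

Since the union of an overlap-connected cluster is one contiguous interval,
its coverage depth is a piecewise-constant profile computed by a sweep line
over start/end events. Trimming fits a Gaussian to that profile by weighted
moments: each covered base *b* contributes weight depth(*b*) at its center
*b* + 0.5, with segment sums evaluated in closed form
(Σ(b+½) = (e²−s²)/2, Σ(b+½)² = (e³−s³)/3 − (e−s)/12 per constant-depth
segment [s,e)). The trimmed region is
[⌊μ − kσ⌋, ⌈μ + kσ⌉) ∩ extent with k = 2 by default (the central ≈95% of
binding mass). Degenerate cases — σ = 0 (single-base cluster) or an empty
intersection — fall back to the untrimmed extent. Trimming depends only on
the cluster, never on the threshold *i*, which makes OTFR sets nested
across thresholds: OTFR(*i*+1) regions are exactly the OTFR(*i*) regions of
the clusters that survive the higher threshold.

The threshold contract is *i* ≥ 2 (a region needs at least two overlapping
loci to be a co-binding signal); the candidate shortlist default is
*i* = 7, where dense co-binding is well above what random placement of the
track produces.

### Enrichment

E = (n_in/n_total)·G/L, computed exactly as the ratio of observed to
expected in-region probability. G defaults to 3×10⁹ bp (human genome scale)
and is overridden by the sum of a chrom.sizes file when one is supplied.
E is deliberately *undefined* (an error, not 0 or NaN) for empty SNP
samples or zero-length region sets.

The bootstrap resamples both sides at preserved size, honoring multiplicity
on both: an iteration's total length L\* counts a region drawn twice twice,
and a SNP drawn twice inside such a region contributes 4 to n_in\*. This
accounting keeps E\* unbiased under the null (verified by the calibration
test: uniform SNPs give |E − 1| within 3 bootstrap SDs across thresholds).
Summary statistics are the mean, the population SD of the B values, and a
normal-approximation CI (mean ± z·sd); a percentile CI is available via
`ci_method="percentile"`. The symmetric normal CI is the default because
the bootstrap distribution of E\* is approximately Gaussian for healthy
sample sizes, which the Pearson χ² check quantifies.

The χ² normality check fits N(mean, sd) with the MLE (ddof = 0) sd, bins
into k = 10 equiprobable bins under the fit, and uses df = k − 3. Two
caveats, both deliberate: (1) with parameters estimated from the ungrouped
data the statistic is stochastically slightly larger than χ²(k−3)
(Chernoff–Lehmann), so the test is mildly anticonservative — its measured
rejection rate at nominal 5% is below 10% in the calibration test; (2) the
check needs ≥ 50 values and positive spread, so bootstrap summaries report
NaN for the χ² fields when B < 50 or the bootstrap distribution is
degenerate.

Association filters use strict inequalities (p < p_max; OR > or_high or
OR < or_low), matching how significance cut-offs are conventionally quoted;
records lacking a filtered field are dropped with a logged count rather
than silently passed.

### Motif impact

Count matrices become log₂-odds matrices with a background-distributed
pseudocount (default 0.8, uniform background); scores are rescaled to
relative scores in [0, 1] between the matrix minimum and maximum, so
thresholds are matrix-independent. Every window overlapping the variant
base is scored on both strands (minus strand = score of the reverse
complement of the same + strand window; offsets always reported in +
coordinates). Per (motif, strand, offset):

- created: alt ≥ threshold > ref;
- disrupted: ref ≥ threshold > alt;
- strengthened / weakened: both ≥ threshold and |Δ| > delta;
- unchanged: emitted for the remaining pairs **unless** both alleles are
  below threshold and |Δ| ≤ delta, which is the only omitted case. A
  sub-threshold pair with a large score shift is therefore still visible in
  the output (as "unchanged") because the >5% shift may matter even when
  neither allele clears the site threshold.

Defaults: threshold 0.80, delta 0.05, flank = max motif width − 1 (the
minimal window that lets every motif placement overlap the variant).
Only substitutions are scored; multi-allelic records expand to one
comparison per alternate allele. The 5% rule compares the same
(motif, strand, offset) in the two alleles; shifted occurrences of the same
motif are separate calls.

Note that the number of created+disrupted calls is **not** monotone in the
threshold in general — a window whose two allele scores straddle a raised
threshold flips from strengthened/weakened to created/disrupted. It is
monotone once the threshold exceeds every window's lower score, the regime
the 80% cutoff operates in.

## Synthetic data

The generator emulates the one property of real clustered TF-binding
tracks the method depends on: **hotspot clustering**. Peak centers are
drawn around uniformly placed hotspots (Gaussian displacement) with
probability ρ, else uniformly; lengths are Gaussian, clipped to ≥ 1 bp.
Defaults — 10 Mb genome, one chromosome, 5,000 peaks of length
~N(300, 100) bp, 150 hotspots with 400 bp spread, ρ = 0.7, 20 factor
labels — give a peak density (~0.5/kb) of the same order as a genome-wide
clustered track (~0.9/kb) and cluster sizes spanning the full 2–40
threshold range, while keeping every test and the acceptance script at
seconds of runtime. Gaussian hotspot displacement (rather than uniform
blocks) makes depth profiles unimodal, so the Gaussian trim is exercised
meaningfully.

SNPs are placed **conditionally on the final OTFR union**: inside it with
probability q (uniform over the union), else uniform over the complement.
This makes the ground-truth enrichment q·G/L exact by construction, which
is what the calibration (q = L/G ⇒ E = 1) and recovery (q = 4L/G ⇒ E = 4)
tests rely on.

What the simulator does **not** emulate: linkage disequilibrium between
SNPs, cell-line-specific binding, chromatin state, factor-specific peak
width distributions, and mappability artifacts. Passing tests therefore
demonstrate the correctness and calibration of the interval machinery and
the statistic — not that any particular real SNP set is enriched.

## Problem sizes used in tests

Oracle-equivalence checks run 200 random toy genomes (≤ 2 kb, ≤ 100 peaks)
against explicit per-base arrays. Null calibration uses 20,000 uniform SNPs
× 20 seeds with B = 200; CI recovery uses 5,000 planted SNPs × 50
replicates with B = 500. The exhaustive bootstrap oracle enumerates all
5⁵ SNP-side resamples of a 5-SNP sample with the region side held fixed
(the `resample_regions=False` option exists precisely to make that
comparison well-posed).

## Known limitations

- The Gaussian trim is a moment fit, not a maximum-likelihood fit of a
  truncated Gaussian; for strongly skewed depth profiles the 2σ window is
  asymmetric in mass. It can be disabled (`TrimParams(enabled=False)`).
- The enrichment null model is uniform placement over a single effective
  genome length; it does not condition on SNP ascertainment density.
- The normal-approximation CI inherits bootstrap skew for very small
  samples; use the percentile option there.
- VCF parsing is sites-only; genotypes are ignored by design.
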