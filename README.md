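# otfrscan

Prioritization of candidate **regulatory SNPs (rSNPs)** from clustered
ChIP-seq peak tracks.

Most trait-associated variants are non-coding, and deciding which of them
plausibly act through gene regulation is hard because regulatory sequence is
poorly annotated. `otfrscan` implements a simple, aggregate signal: a genomic
region where ChIP-seq binding loci for **many different transcription
factors** pile up is likely regulatory, so a SNP inside such a region is a
candidate rSNP. The package is aimed at people working with ENCODE-style
TF-binding tracks (e.g. the UCSC "Txn Factor ChIP" clustered track) and SNP
sets from dbSNP, clinical catalogs, or GWAS summary tables.

## The method

1. **OTFR construction.** Peaks that share at least 1 bp are merged
   transitively (single-linkage) into clusters. A cluster with *i* or more
   member peaks defines an **overlapping TF-binding region, OTFR(i)**. The
   cluster's stacked coverage depth is treated as a density; a Gaussian is
   fitted to it by depth-weighted moments and the region is trimmed to
   μ ± 2σ (the central ~95% of binding mass), clipped to the cluster span.

2. **Enrichment statistic.** For a SNP sample of size *n* with *n*<sub>in</sub>
   members inside OTFRs of total length *L*, on a genome of length *G*
   (default 3×10⁹ bp):

   *E*(*i*) = *P*\*/*P*, with *P*\* = *n*<sub>in</sub>/*n* and *P* = *L*/*G*.

   *E* ≈ 1 means the SNPs look uniformly placed; *E* > 1 means the sample is
   enriched in dense TF-binding regions. Uncertainty comes from a bootstrap
   (default *B* = 500) that resamples **both** the SNP list and the OTFR
   region list with replacement at preserved size, and reports the mean, SD,
   a normal-approximation 99% CI, and a Pearson χ² check that the bootstrap
   distribution is close to normal.

3. **Candidate ranking and filters.** SNPs inside OTFR(*i* ≥ 7) are the
   candidate shortlist, ranked by the number of peaks covering the exact
   position. GWAS tables can be pre-filtered by association strength
   (*p* < 10⁻⁷, OR > 3 or OR < 0.33, or both), and a blacklist (e.g. the
   chr6 MHC region chr6:29,909,708-31,325,212, which is over-genotyped)
   can be subtracted.

4. **Motif impact.** Each candidate's two alleles are scanned against
   JASPAR-style matrices on both strands. With relative scores in [0, 1]
   (raw PWM score rescaled between the matrix minimum and maximum), a site
   present in only one allele at the 80% threshold is called
   *created*/*disrupted*; sites present in both with a score difference
   above 5% are *strengthened*/*weakened*.

## Worked example

Everything below runs on synthetic data generated by the package itself
(no downloads). The simulator places 5,000 peaks on a 10 Mb genome, 70% of
them around 150 hotspots, then plants SNPs with a known probability *q* of
landing inside the OTFR union so the true enrichment *q·G/L* is exact by
construction.

```bash
otfrscan simulate peaks --seed 1 --out peaks.bed
otfrscan build-otfr --peaks peaks.bed --i-min 7 --out otfr.bed
# -> 150 OTFRs, total length 215810 bp -> otfr.bed

otfrscan simulate snps --peaks peaks.bed --i-min 7 --genome-size 10000000 \
    --q 0.0863 --n 5000 --seed 2 --out snps.bed   # q = 4 L/G, true E = 4
otfrscan enrich --snps snps.bed --peaks peaks.bed --i-min 7 \
    --genome-size 10000000 --bootstrap 500 --seed 3 --out enrich.tsv
# -> E(7) = 3.753 [2.921, 4.603] -> enrich.tsv
```

The point estimate 3.75 and the 99% bootstrap CI [2.92, 4.60] recover the
planted enrichment of 4: about four times as many SNPs fall into dense
TF-binding regions as uniform placement would give. The same `run`
subcommand chains all stages (OTFR BED, per-SNP annotation, enrichment
curve, ranked candidate list, optional motif-impact table) from one seed.

In Python the same computation is three calls:

```python
import otfrscan as o

peaks = o.simulate_peaks(o.PeakSimConfig(seed=1))
otfrs = o.build_otfr(peaks, i_min=7)
snps  = o.simulate_snps(o.SnpSimConfig(n_snps=5000, q=0.0863, seed=2),
                        otfrs, genome_length=10_000_000)
boot  = o.bootstrap_enrichment(snps, otfrs, B=500, seed=3,
                               genome_length=10_000_000)
print(boot.mean, boot.sd)   # 3.762 0.326
```

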