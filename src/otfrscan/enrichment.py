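"""Enrichment of SNP sets in OTFRs, with bootstrap uncertainty.

The statistic is E(i) = P*/P where P* = n_in/n_total is the observed
fraction of SNPs inside OTFR(i) regions and P = L/G is the fraction
expected under a uniform placement over a genome of length G (default
3e9 bp), L being the total OTFR length. E ~ 1 means no enrichment.

Uncertainty is estimated by resampling both the SNP list and the OTFR
region list with replacement at preserved size (B iterations, default
500); a Pearson chi-squared test against the fitted normal checks that the
bootstrap distribution of E* is approximately Gaussian, which justifies
the symmetric mean +/- z*sd confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .formats import SNPRecord
from .otfr import OTFR, PeakCluster, TrimParams, otfrs_from_clusters, total_otfr_length

log = logging.getLogger(__name__)

GENOME_LENGTH_DEFAULT = 3_000_000_000  # human genome, bp


class UndefinedStatisticError(ValueError):
    """E is undefined (empty sample or zero-length region set)."""


class DegenerateDistributionError(ValueError):
    """The values have zero spread; a normality test is meaningless."""


@dataclass(frozen=True)
class EnrichmentResult:
    i_min: int
    n_in: int
    n_total: int
    otfr_total_length: int
    genome_length: int
    p_star: float
    p_exp: float
    e_value: float


@dataclass(frozen=True)
class BootstrapSummary:
    n_iterations: int
    seed: int
    mean: float
    sd: float
    ci_level: float
    ci_low: float
    ci_high: float
    chi2_stat: float
    chi2_df: int
    chi2_p: float


@dataclass(frozen=True)
class AssociationFilter:
    """GWAS-style significance filter on p-value and/or odds ratio.

    ``p_only`` keeps p_value < p_max; ``or_only`` keeps odds_ratio > or_high
    OR odds_ratio < or_low; ``both`` is the intersection. All comparisons are
    strict.
    """

    p_max: Optional[float] = None
    or_high: Optional[float] = None
    or_low: Optional[float] = None
    combine: Literal["p_only", "or_only", "both"] = "p_only"

    def __post_init__(self) -> None:
        if self.or_high is not None and self.or_low is not None:
            if not (self.or_low < 1 < self.or_high):
                raise ValueError("need or_low < 1 < or_high")
        if self.combine in ("p_only", "both") and self.p_max is None:
            raise ValueError(f"combine={self.combine!r} requires p_max")
        if self.combine in ("or_only", "both") and (self.or_high is None or self.or_low is None):
            raise ValueError(f"combine={self.combine!r} requires or_high and or_low")


def enrichment(
    n_in: int,
    n_total: int,
    otfr_total_length: int,
    genome_length: int = GENOME_LENGTH_DEFAULT,
    i_min: int = 2,
) -> EnrichmentResult:
    """E = (n_in/n_total) / (L/G)."""
    if n_total <= 0:
        raise UndefinedStatisticError("n_total must be > 0")
    if not (0 < otfr_total_length <= genome_length):
        raise UndefinedStatisticError(
            f"need 0 < L <= G, got L={otfr_total_length}, G={genome_length}"
        )
    if not (0 <= n_in <= n_total):
        raise ValueError("need 0 <= n_in <= n_total")
    p_star = n_in / n_total
    p_exp = otfr_total_length / genome_length
    return EnrichmentResult(
        i_min=i_min,
        n_in=n_in,
        n_total=n_total,
        otfr_total_length=otfr_total_length,
        genome_length=genome_length,
        p_star=p_star,
        p_exp=p_exp,
        e_value=p_star / p_exp,
    )


def _region_arrays(otfrs: Sequence[OTFR]):
    """Region bounds grouped by chromosome, plus flat per-region arrays."""
    chroms = np.array([o.region.chrom for o in otfrs])
    starts = np.array([o.region.start for o in otfrs], dtype=np.int64)
    ends = np.array([o.region.end for o in otfrs], dtype=np.int64)
    return chroms, starts, ends


def count_snps_in_regions(snps: Sequence[SNPRecord], otfrs: Sequence[OTFR]) -> int:
    """Number of SNPs falling inside any OTFR region (regions disjoint)."""
    return int(_membership_counts(snps, otfrs).sum())


def _membership_counts(snps: Sequence[SNPRecord], otfrs: Sequence[OTFR]) -> np.ndarray:
    """Per-region SNP counts: counts[j] = #SNPs inside otfrs[j]."""
    counts = np.zeros(len(otfrs), dtype=np.int64)
    by_chrom_pos: dict[str, list[int]] = {}
    for s in snps:
        by_chrom_pos.setdefault(s.chrom, []).append(s.pos)
    sorted_pos = {c: np.sort(np.array(p, dtype=np.int64)) for c, p in by_chrom_pos.items()}
    for j, o in enumerate(otfrs):
        pos = sorted_pos.get(o.region.chrom)
        if pos is None:
            continue
        counts[j] = np.searchsorted(pos, o.region.end, side="left") - np.searchsorted(
            pos, o.region.start, side="left"
        )
    return counts


def enrichment_curve(
    snps: Sequence[SNPRecord],
    clusters: Sequence[PeakCluster],
    i_values: Sequence[int],
    trim_params: TrimParams = TrimParams(),
    genome_length: int = GENOME_LENGTH_DEFAULT,
) -> list[EnrichmentResult]:
    """E(i) across thresholds, from a single clustering pass.

    Each cluster is trimmed once (the trim depends only on the cluster), so
    the OTFR sets for successive i are nested and n_total stays constant.
    """
    trim_cache: dict = {}
    out: list[EnrichmentResult] = []
    for i in i_values:
        otfrs = otfrs_from_clusters(clusters, i, trim_params, _trim_cache=trim_cache)
        n_in = count_snps_in_regions(snps, otfrs)
        out.append(
            enrichment(
                n_in=n_in,
                n_total=len(snps),
                otfr_total_length=total_otfr_length(otfrs),
                genome_length=genome_length,
                i_min=i,
            )
        )
    return out


def bootstrap_enrichment(
    snps: Sequence[SNPRecord],
    otfrs: Sequence[OTFR],
    B: int = 500,
    seed: int = 0,
    ci_level: float = 0.99,
    genome_length: int = GENOME_LENGTH_DEFAULT,
    ci_method: Literal["normal", "percentile"] = "normal",
    resample_regions: bool = True,
) -> BootstrapSummary:
    """Bootstrap the enrichment statistic.

    Each iteration resamples the SNP list with replacement (size preserved)
    and, when ``resample_regions``, the OTFR region list with replacement
    (size preserved). Multiplicity is honored on both sides: the resampled
    total length L* counts duplicated regions multiply, and a SNP drawn
    twice that lies in a region drawn twice contributes 4 to n_in*. This
    keeps E* unbiased under the null. The normality chi-squared fields are
    NaN when B < 50 or the bootstrap distribution is degenerate.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if not snps or not otfrs:
        raise UndefinedStatisticError("need non-empty SNP and OTFR samples")
    rng = np.random.default_rng(seed)
    n = len(snps)
    R = len(otfrs)

    # group SNP positions and region bounds per chromosome; region j gets a
    # flat index so multiplicities vectorize
    chrom_of = {c: k for k, c in enumerate(sorted({o.region.chrom for o in otfrs} | {s.chrom for s in snps}))}
    # encode genome-wide by offsetting each chromosome far apart
    OFFSET = max(
        [o.region.end for o in otfrs] + [s.pos + 1 for s in snps]
    ) + 1
    snp_pos = np.array([chrom_of[s.chrom] * OFFSET + s.pos for s in snps], dtype=np.int64)
    r_start = np.array([chrom_of[o.region.chrom] * OFFSET + o.region.start for o in otfrs], dtype=np.int64)
    r_end = np.array([chrom_of[o.region.chrom] * OFFSET + o.region.end for o in otfrs], dtype=np.int64)
    r_len = np.array([o.region.length for o in otfrs], dtype=np.int64)

    e_star = np.empty(B)
    for b in range(B):
        ps = np.sort(rng.choice(snp_pos, size=n, replace=True))
        if resample_regions:
            ridx = rng.integers(0, R, size=R)
            mult = np.bincount(ridx, minlength=R)
        else:
            mult = np.ones(R, dtype=np.int64)
        l_star = int(mult @ r_len)
        per_region = np.searchsorted(ps, r_end, side="left") - np.searchsorted(ps, r_start, side="left")
        n_in_star = int(mult @ per_region)
        e_star[b] = (n_in_star / n) * genome_length / l_star

    mean = float(e_star.mean())
    sd = float(e_star.std(ddof=0))
    if ci_method == "percentile":
        alpha = 1 - ci_level
        ci_low, ci_high = (float(x) for x in np.quantile(e_star, [alpha / 2, 1 - alpha / 2]))
    else:
        z = stats.norm.ppf(0.5 + ci_level / 2)
        ci_low, ci_high = mean - z * sd, mean + z * sd
    if B >= 50 and sd > 0:
        chi2_stat, chi2_df, chi2_p = normality_chi2(e_star)
    else:
        chi2_stat, chi2_df, chi2_p = float("nan"), 0, float("nan")
    return BootstrapSummary(
        n_iterations=B,
        seed=seed,
        mean=mean,
        sd=sd,
        ci_level=ci_level,
        ci_low=ci_low,
        ci_high=ci_high,
        chi2_stat=chi2_stat,
        chi2_df=chi2_df,
        chi2_p=chi2_p,
    )


def normality_chi2(values: Sequence[float], k: int = 10) -> tuple[float, int, float]:
    """Pearson chi-squared goodness-of-fit of values to a fitted normal.

    Fits N(mean, sd) (MLE sd), bins into k equiprobable bins under the fit,
    and compares observed counts to n/k. df = k - 3 (k bins, 2 fitted
    parameters). Returns (stat, df, upper-tail p).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 50:
        raise ValueError(f"need >= 50 values, got {x.size}")
    mean, sd = float(x.mean()), float(x.std(ddof=0))
    if sd == 0:
        raise DegenerateDistributionError("constant values: sd = 0")
    edges = stats.norm.ppf(np.arange(1, k) / k, loc=mean, scale=sd)
    observed = np.histogram(x, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
    expected = x.size / k
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = k - 3
    return stat, df, float(stats.chi2.sf(stat, df))


def filter_association(
    snps: Sequence[SNPRecord], filt: AssociationFilter
) -> list[SNPRecord]:
    """Apply a significance filter; records lacking a filtered field are dropped."""
    need_p = filt.combine in ("p_only", "both")
    need_or = filt.combine in ("or_only", "both")
    missing = 0
    kept: list[SNPRecord] = []
    for s in snps:
        if (need_p and s.p_value is None) or (need_or and s.odds_ratio is None):
            missing += 1
            continue
        ok = True
        if need_p:
            ok = ok and s.p_value < filt.p_max
        if need_or:
            ok = ok and (s.odds_ratio > filt.or_high or s.odds_ratio < filt.or_low)
        if ok:
            kept.append(s)
    if missing:
        log.info("dropped %d records lacking the filtered field(s)", missing)
    return kept
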