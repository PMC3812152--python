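"""Enrichment statistic, bootstrap, normality check and association filters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_peak, snp
from otfrscan.enrichment import (
    AssociationFilter,
    DegenerateDistributionError,
    UndefinedStatisticError,
    bootstrap_enrichment,
    count_snps_in_regions,
    enrichment,
    enrichment_curve,
    filter_association,
    normality_chi2,
)
from otfrscan.formats import GenomicInterval
from otfrscan.otfr import OTFR, TrimParams, cluster_peaks, otfrs_from_clusters, total_otfr_length


def region(chrom, start, end, cid=1, count=5):
    return OTFR(cluster_id=cid, chrom=chrom, region=GenomicInterval(chrom, start, end),
                peak_count=count, trimmed=False)


class TestEnrichmentFormula:
    def test_direct_evaluation(self):
        res = enrichment(n_in=10, n_total=50, otfr_total_length=100, genome_length=1000)
        assert res.e_value == pytest.approx(2.0)
        assert res.p_star == pytest.approx(0.2) and res.p_exp == pytest.approx(0.1)

    def test_zero_hits(self):
        assert enrichment(0, 50, 100, 1000).e_value == 0.0

    def test_regions_tiling_genome(self):
        res = enrichment(n_in=50, n_total=50, otfr_total_length=1000, genome_length=1000)
        assert res.e_value == pytest.approx(1.0)

    def test_undefined_cases(self):
        with pytest.raises(UndefinedStatisticError):
            enrichment(0, 0, 100, 1000)
        with pytest.raises(UndefinedStatisticError):
            enrichment(0, 10, 0, 1000)

    @settings(deadline=None, derandomize=True)
    @given(
        n_in=st.integers(0, 100),
        extra=st.integers(1, 100),
        L=st.integers(1, 10_000),
        G_mult=st.integers(1, 100),
        scale=st.integers(1, 1000),
    )
    def test_scale_invariance(self, n_in, extra, L, G_mult, scale):
        """Multiplying all lengths by a constant leaves E unchanged."""
        n_total = n_in + extra
        G = L * G_mult
        e1 = enrichment(n_in, n_total, L, G).e_value
        e2 = enrichment(n_in, n_total, L * scale, G * scale).e_value
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestEnrichmentCurve:
    def test_full_coverage_gives_unit_enrichment(self):
        # overlapping peaks tiling the whole toy genome; no trimming
        peaks = [make_peak("chr1", 0, 60), make_peak("chr1", 50, 100)]
        clusters = cluster_peaks(peaks)
        snps = [snp(f"s{k}", "chr1", 10 * k) for k in range(10)]
        (res,) = enrichment_curve(snps, clusters, [2], TrimParams(enabled=False), genome_length=100)
        assert res.e_value == pytest.approx(1.0)
        assert res.n_in == res.n_total == 10

    def test_monotone_when_snps_sit_in_deep_clusters(self, fixture_peaks, fixture_config):
        """SNPs placed only inside OTFR(10): E(i) rises as i grows to 10.

        n_in stays constant while L(i) shrinks, so the ratio is exactly
        non-decreasing over i = 2..10.
        """
        clusters = cluster_peaks(fixture_peaks)
        deep = otfrs_from_clusters(clusters, 10)
        rng = np.random.default_rng(0)
        snps = []
        for k in range(500):
            o = deep[int(rng.integers(0, len(deep)))]
            snps.append(snp(f"s{k}", o.chrom, int(rng.integers(o.region.start, o.region.end))))
        curve = enrichment_curve(snps, clusters, list(range(2, 11)),
                                 genome_length=fixture_config.genome_length)
        evals = [r.e_value for r in curve]
        assert all(b >= a for a, b in zip(evals, evals[1:]))
        assert all(r.n_in == 500 for r in curve)


class TestBootstrap:
    def test_size_one_sample_has_zero_spread(self):
        snps = [snp("s1", "chr1", 5)]
        summary = bootstrap_enrichment(snps, [region("chr1", 0, 10)], B=50, seed=0,
                                       genome_length=100)
        assert summary.sd == 0.0
        assert summary.ci_low == summary.ci_high == summary.mean

    def test_fixed_seed_reproduces_summary(self):
        snps = [snp(f"s{k}", "chr1", k * 7) for k in range(40)]
        otfrs = [region("chr1", 0, 50, 1), region("chr1", 100, 180, 2)]
        a = bootstrap_enrichment(snps, otfrs, B=200, seed=9, genome_length=1000)
        b = bootstrap_enrichment(snps, otfrs, B=200, seed=9, genome_length=1000)
        assert a == b

    def test_mean_matches_exhaustive_enumeration(self):
        """SNP-side bootstrap mean vs enumeration of all 5^5 resamples
        (region side held fixed)."""
        G = 1000
        otfrs = [region("chr1", 0, 50, 1), region("chr1", 100, 150, 2)]
        positions = [10, 40, 120, 500, 700]  # 3 of 5 inside the regions
        snps = [snp(f"s{k}", "chr1", p) for k, p in enumerate(positions)]
        L = total_otfr_length(otfrs)
        inside = [1 if any(o.region.contains("chr1", p) for o in otfrs) else 0 for p in positions]
        outcomes = []
        for draw in itertools.product(range(5), repeat=5):
            n_in = sum(inside[j] for j in draw)
            outcomes.append((n_in / 5) * G / L)
        exact_mean = float(np.mean(outcomes))
        exact_sd = float(np.std(outcomes))
        B = 4000
        summary = bootstrap_enrichment(snps, otfrs, B=B, seed=1, genome_length=G,
                                       resample_regions=False)
        assert summary.mean == pytest.approx(exact_mean, abs=4 * exact_sd / np.sqrt(B))

    def test_mean_near_point_estimate_for_large_samples(self):
        rng = np.random.default_rng(2)
        otfrs = [region("chr1", k * 1000, k * 1000 + 300, cid=k + 1) for k in range(10)]
        snps = [snp(f"s{k}", "chr1", int(p)) for k, p in enumerate(rng.integers(0, 10_000, 500))]
        G = 100_000
        L = total_otfr_length(otfrs)
        point = enrichment(count_snps_in_regions(snps, otfrs), len(snps), L, G).e_value
        summary = bootstrap_enrichment(snps, otfrs, B=500, seed=3, genome_length=G)
        assert abs(summary.mean - point) <= 3 * summary.sd / np.sqrt(500) * 10
        # the bootstrap distribution of E* is close to normal here
        assert summary.chi2_p > 1e-4

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            bootstrap_enrichment([], [region("chr1", 0, 10)], B=10, genome_length=100)
        with pytest.raises(ValueError):
            bootstrap_enrichment([snp("s", "chr1", 1)], [region("chr1", 0, 10)], B=1,
                                 genome_length=100)


class TestNormalityChi2:
    def test_calibration_on_normal_draws(self):
        """Fitted-normal chi-squared p-value exceeds 0.05 for nearly all
        normal samples.

        With mean and sd estimated from the ungrouped data, the Pearson
        statistic is stochastically a bit larger than chi2(k-3)
        (Chernoff-Lehmann), so the nominal 5% rejection rate inflates
        slightly; the observed rate stays below 10%.
        """
        ok = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, size=500)
            _, df, p = normality_chi2(x)
            assert df == 7
            ok += p > 0.05
        assert ok >= 90

    def test_power_against_bimodal_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-4, 0.3, 250), rng.normal(4, 0.3, 250)])
        _, _, p = normality_chi2(x)
        assert p < 0.01

    def test_constant_values_are_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            normality_chi2(np.ones(100))

    def test_requires_enough_values(self):
        with pytest.raises(ValueError, match="50"):
            normality_chi2(np.random.default_rng(0).normal(size=20))


class TestAssociationFilter:
    @pytest.fixture
    def table(self):
        return [
            snp("a", "chr1", 1, p_value=1e-8, odds_ratio=3.5),
            snp("b", "chr1", 2, p_value=1e-8, odds_ratio=2.0),
            snp("c", "chr1", 3, p_value=1e-6, odds_ratio=4.0),
            snp("d", "chr1", 4, p_value=1e-6, odds_ratio=0.2),
            snp("e", "chr1", 5, p_value=1e-9, odds_ratio=0.2),
            snp("f", "chr1", 6, p_value=None, odds_ratio=5.0),
        ]

    def test_p_value_criterion(self, table):
        kept = filter_association(table, AssociationFilter(p_max=1e-7, combine="p_only"))
        assert [s.id for s in kept] == ["a", "b", "e"]

    def test_odds_ratio_criterion(self, table):
        kept = filter_association(
            table, AssociationFilter(or_high=3, or_low=0.33, combine="or_only")
        )
        assert [s.id for s in kept] == ["a", "c", "d", "e", "f"]

    def test_intersection(self, table):
        kept = filter_association(
            table, AssociationFilter(p_max=1e-7, or_high=3, or_low=0.33, combine="both")
        )
        assert [s.id for s in kept] == ["a", "e"]

    def test_strict_inequalities(self):
        boundary = [snp("x", "chr1", 1, p_value=1e-7, odds_ratio=3.0)]
        assert filter_association(boundary, AssociationFilter(p_max=1e-7, combine="p_only")) == []
        assert filter_association(
            boundary, AssociationFilter(or_high=3, or_low=0.33, combine="or_only")
        ) == []

    def test_missing_field_records_dropped(self, table):
        kept = filter_association(table, AssociationFilter(p_max=1.0, combine="p_only"))
        assert "f" not in [s.id for s in kept]

    def test_invalid_filters(self):
        with pytest.raises(ValueError):
            AssociationFilter(combine="p_only")  # no p_max
        with pytest.raises(ValueError):
            AssociationFilter(or_high=0.5, or_low=2.0, combine="or_only")
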