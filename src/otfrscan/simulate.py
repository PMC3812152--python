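"""Synthetic data with known ground truth for every pipeline stage.

The peak simulator emulates the clustered placement of ChIP-seq binding
loci: a fraction of peaks pile up around Gaussian "hotspots" (regulatory
regions dense in binding for many factors), the rest scatter uniformly.
The SNP simulator places a known fraction q of variants inside a given
OTFR union, so the true enrichment E = q*G/L is exact by construction —
the calibration backbone for the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .formats import BASES, GenomicInterval, MotifMatrix, Peak, SNPRecord
from .motif import AlleleWindowPair
from .otfr import OTFR


@dataclass(frozen=True)
class PeakSimConfig:
    """Clustered-peak track generator settings.

    Defaults give a 10 Mb single-chromosome genome with 5,000 peaks of
    length ~N(300, 100) bp, 70% of which gather around 150 hotspots with a
    400 bp spread — peak density and cluster depths comparable in kind to a
    genome-wide clustered TF-binding track, at desk scale.
    """

    genome_length: int = 10_000_000
    n_chrom: int = 1
    n_factors: int = 20
    n_peaks: int = 5_000
    peak_len_mean: float = 300.0
    peak_len_sd: float = 100.0
    n_hotspots: int = 150
    hotspot_sd: float = 400.0
    hotspot_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.hotspot_fraction <= 1):
            raise ValueError("hotspot_fraction must be in [0, 1]")
        if self.peak_len_mean <= 0:
            raise ValueError("peak_len_mean must be > 0")
        if self.n_chrom < 1 or self.genome_length < self.n_chrom:
            raise ValueError("need n_chrom >= 1 and genome_length >= n_chrom")


@dataclass(frozen=True)
class SnpSimConfig:
    """SNP set generator: each SNP lands inside the OTFR union with probability q."""

    n_snps: int
    q: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.q <= 1):
            raise ValueError("q must be in [0, 1]")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")


def _chrom_layout(cfg: PeakSimConfig) -> dict[str, int]:
    base = cfg.genome_length // cfg.n_chrom
    sizes = {f"chr{i + 1}": base for i in range(cfg.n_chrom)}
    sizes[f"chr{cfg.n_chrom}"] += cfg.genome_length - base * cfg.n_chrom
    return sizes


def simulate_peaks(cfg: PeakSimConfig) -> list[Peak]:
    """Draw a clustered peak track; fixed seed gives identical output.

    Hotspot centers are uniform over the genome. Each peak is hotspot-bound
    with probability ``hotspot_fraction`` (center ~ Normal around a random
    hotspot), else its center is uniform. Lengths ~ Normal(mean, sd),
    clipped to >= 1 bp; peaks clipped to chromosome bounds. Factor labels
    round-robin over ``n_factors``.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = _chrom_layout(cfg)
    chrom_names = list(sizes)
    offsets = np.concatenate(([0], np.cumsum([sizes[c] for c in chrom_names])))
    G = cfg.genome_length

    hotspot_centers = rng.uniform(0, G, size=max(cfg.n_hotspots, 1))
    in_hotspot = rng.random(cfg.n_peaks) < cfg.hotspot_fraction
    which = rng.integers(0, max(cfg.n_hotspots, 1), size=cfg.n_peaks)
    centers = np.where(
        in_hotspot & (cfg.n_hotspots > 0),
        hotspot_centers[which] + rng.normal(0, cfg.hotspot_sd, size=cfg.n_peaks),
        rng.uniform(0, G, size=cfg.n_peaks),
    )
    lengths = np.maximum(rng.normal(cfg.peak_len_mean, cfg.peak_len_sd, size=cfg.n_peaks), 1.0)

    peaks: list[Peak] = []
    for k in range(cfg.n_peaks):
        center = min(max(centers[k], 0.0), G - 1)
        chrom_idx = int(np.searchsorted(offsets, center, side="right")) - 1
        chrom = chrom_names[chrom_idx]
        local = center - offsets[chrom_idx]
        half = lengths[k] / 2
        start = int(max(0, round(local - half)))
        end = int(min(sizes[chrom], round(local + half)))
        if end <= start:
            end = min(start + 1, sizes[chrom])
            start = end - 1
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                factor=f"TF{k % cfg.n_factors + 1}",
                score=None,
            )
        )
    return peaks


def _alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return ref, alt


def simulate_snps(
    cfg: SnpSimConfig,
    otfrs: Sequence[OTFR],
    genome_length: int,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[SNPRecord]:
    """Place SNPs with known in-OTFR probability q.

    With probability q a position is uniform over the OTFR union, otherwise
    uniform over its complement, so the expected enrichment is exactly
    q*G/L. With a single chromosome (the default) regions live on one
    ``chr1``-style sequence of length ``genome_length``; pass
    ``chrom_sizes`` for multi-chromosome layouts.
    """
    if chrom_sizes is None:
        chroms = sorted({o.region.chrom for o in otfrs}) or ["chr1"]
        if len(chroms) > 1:
            raise ValueError("multi-chromosome OTFRs require chrom_sizes")
        chrom_sizes = {chroms[0]: genome_length}
    if sum(chrom_sizes.values()) != genome_length:
        raise ValueError("chrom_sizes must sum to genome_length")

    names = list(chrom_sizes)
    offsets = {c: o for c, o in zip(names, np.concatenate(([0], np.cumsum([chrom_sizes[c] for c in names[:-1]]))))}

    regions = sorted(
        (offsets[o.region.chrom] + o.region.start, offsets[o.region.chrom] + o.region.end)
        for o in otfrs
    )
    starts = np.array([r[0] for r in regions], dtype=np.int64)
    ends = np.array([r[1] for r in regions], dtype=np.int64)
    L = int((ends - starts).sum())
    if cfg.q > 0 and L == 0:
        raise ValueError("q > 0 requires a non-empty OTFR union")
    if cfg.q < 1 and L >= genome_length:
        raise ValueError("q < 1 requires the union to leave uncovered genome")

    rng = np.random.default_rng(cfg.seed)
    inside = rng.random(cfg.n_snps) < cfg.q

    # map a uniform offset within the union (or its complement) to a genome
    # position via cumulative lengths
    cum_in = np.concatenate(([0], np.cumsum(ends - starts)))
    gap_starts = np.concatenate(([0], ends))
    gap_ends = np.concatenate((starts, [genome_length]))
    gap_len = gap_ends - gap_starts
    cum_out = np.concatenate(([0], np.cumsum(gap_len)))

    pos = np.empty(cfg.n_snps, dtype=np.int64)
    n_in = int(inside.sum())
    if n_in:
        u = rng.integers(0, L, size=n_in)
        j = np.searchsorted(cum_in, u, side="right") - 1
        pos[inside] = starts[j] + (u - cum_in[j])
    n_out = cfg.n_snps - n_in
    if n_out:
        u = rng.integers(0, genome_length - L, size=n_out)
        j = np.searchsorted(cum_out, u, side="right") - 1
        pos[~inside] = gap_starts[j] + (u - cum_out[j])

    ref, alt = _alleles(rng, cfg.n_snps)
    chrom_bounds = np.concatenate(([0], np.cumsum([chrom_sizes[c] for c in names])))
    out: list[SNPRecord] = []
    for k in range(cfg.n_snps):
        ci = int(np.searchsorted(chrom_bounds, pos[k], side="right")) - 1
        out.append(
            SNPRecord(
                id=f"snp{k + 1}",
                chrom=names[ci],
                pos=int(pos[k] - chrom_bounds[ci]),
                ref_allele=BASES[ref[k]],
                alt_alleles=(BASES[alt[k]],),
            )
        )
    return out


def simulate_motif_case(
    motif: MotifMatrix,
    disrupt_position: int,
    seed: int = 0,
    flank: Optional[int] = None,
) -> AlleleWindowPair:
    """Embed the motif consensus in random flanks and break one column.

    The alternate allele replaces the consensus base at ``disrupt_position``
    with that column's minimum-count base, so the score drop equals that
    column's log-odds contribution.
    """
    w = motif.width
    if not (0 <= disrupt_position < w):
        raise ValueError("disrupt_position outside motif")
    if flank is None:
        flank = w - 1
    rng = np.random.default_rng(seed)
    left = "".join(BASES[i] for i in rng.integers(0, 4, size=flank))
    right = "".join(BASES[i] for i in rng.integers(0, 4, size=flank))
    consensus = motif.consensus
    worst = BASES[int(motif.counts[:, disrupt_position].argmin())]
    alt_core = consensus[:disrupt_position] + worst + consensus[disrupt_position + 1 :]
    return AlleleWindowPair(
        snp_id=f"sim_{motif.motif_id}_{disrupt_position}",
        flank=flank,
        seq_ref=left + consensus + right,
        seq_alt=left + alt_core + right,
        snp_offset=flank + disrupt_position,
    )


def expected_enrichment(q: float, otfr_total_length: int, genome_length: int) -> float:
    """Ground-truth E for SNPs placed inside the union with probability q: q*G/L."""
    if not (0 < otfr_total_length <= genome_length):
        raise ValueError("need 0 < L <= G")
    return q * genome_length / otfr_total_length
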