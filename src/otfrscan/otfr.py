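"""Overlapping TF-binding region (OTFR) construction and SNP annotation.

An OTFR is the maximal group of transitively overlapping ChIP-seq peaks
(single-linkage by >=1 bp shared sequence), optionally trimmed to the
central 2-sigma span of a Gaussian fit to the stacked peak-coverage depth.
Regions dense in binding loci for many factors are treated as putative
regulatory regions, and SNPs inside them as candidate regulatory SNPs.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .formats import GenomicInterval, Peak, SNPRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrimParams:
    """Gaussian-trim settings: keep the mean +/- k_sigma span of the depth profile."""

    k_sigma: float = 2.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be > 0")


@dataclass
class PeakCluster:
    """A maximal connected component of pairwise-overlapping peaks."""

    cluster_id: int
    chrom: str
    extent: GenomicInterval
    members: list[Peak]
    factor_set: set[str] = field(default_factory=set)

    @property
    def peak_count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OTFR:
    """A cluster's (optionally trimmed) region with its member-peak count."""

    cluster_id: int
    chrom: str
    region: GenomicInterval
    peak_count: int
    trimmed: bool


@dataclass
class DepthProfile:
    """Piecewise-constant peak coverage over a cluster's union span."""

    segments: list[tuple[GenomicInterval, int]]

    def depth_at(self, pos: int) -> int:
        for iv, d in self.segments:
            if iv.start <= pos < iv.end:
                return d
        return 0


@dataclass
class SNPAnnotation:
    snp_id: str
    in_otfr: bool
    cluster_id: Optional[int]
    depth_at_snp: int
    cluster_peak_count: Optional[int]


def cluster_peaks(peaks: Sequence[Peak]) -> list[PeakCluster]:
    """Single-linkage clustering of peaks by >=1 bp overlap.

    Abutting intervals (end == start) are NOT merged. Clustering is
    per-chromosome; clusters are sorted by (chrom, start) and ids assigned
    sequentially from 1 so identical input always yields identical output.
    Singleton peaks form clusters of peak_count 1.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    clusters: list[PeakCluster] = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        current: list[Peak] = []
        cur_end = -1
        for p in chrom_peaks:
            if current and p.interval.start < cur_end:
                current.append(p)
                cur_end = max(cur_end, p.interval.end)
            else:
                if current:
                    clusters.append(_make_cluster(chrom, current))
                current = [p]
                cur_end = p.interval.end
        if current:
            clusters.append(_make_cluster(chrom, current))
    for cid, c in enumerate(clusters, start=1):
        c.cluster_id = cid
    return clusters


def _make_cluster(chrom: str, members: list[Peak]) -> PeakCluster:
    start = min(p.interval.start for p in members)
    end = max(p.interval.end for p in members)
    return PeakCluster(
        cluster_id=0,
        chrom=chrom,
        extent=GenomicInterval(chrom, start, end),
        members=list(members),
        factor_set={p.factor for p in members},
    )


def depth_profile(cluster: PeakCluster) -> DepthProfile:
    """Sweep-line coverage depth over the cluster's member peaks.

    Segments exactly tile the union of member intervals (which is contiguous
    for an overlap-connected cluster) and carry constant depth >= 1.
    """
    events: dict[int, int] = {}
    for p in cluster.members:
        events[p.interval.start] = events.get(p.interval.start, 0) + 1
        events[p.interval.end] = events.get(p.interval.end, 0) - 1
    positions = sorted(events)
    segments: list[tuple[GenomicInterval, int]] = []
    depth = 0
    for pos, nxt in zip(positions, positions[1:]):
        depth += events[pos]
        if depth > 0:
            segments.append((GenomicInterval(cluster.chrom, pos, nxt), depth))
    return DepthProfile(segments=segments)


def cluster_moments(cluster: PeakCluster) -> tuple[float, float]:
    """Depth-weighted mean and SD of base position over a cluster.

    Each covered base b contributes weight depth(b) at its center b + 0.5.
    Segment sums use the closed forms sum_{b=s}^{e-1}(b+1/2) = (e^2-s^2)/2
    and sum_{b=s}^{e-1}(b+1/2)^2 = (e^3-s^3)/3 - (e-s)/12.
    """
    w_sum = 0.0
    x_sum = 0.0
    x2_sum = 0.0
    for iv, d in depth_profile(cluster).segments:
        s, e = float(iv.start), float(iv.end)
        n = e - s
        w_sum += d * n
        x_sum += d * (e * e - s * s) / 2.0
        x2_sum += d * ((e**3 - s**3) / 3.0 - n / 12.0)
    mu = x_sum / w_sum
    var = x2_sum / w_sum - mu * mu
    return mu, math.sqrt(var) if var > 0 else 0.0


def gaussian_trim(cluster: PeakCluster, params: TrimParams) -> GenomicInterval:
    """Central k-sigma span of a Gaussian fit to the peak-depth distribution.

    The returned interval is [floor(mu - k*sigma), ceil(mu + k*sigma))
    intersected with the cluster extent. Degenerate fits (sigma = 0) and
    empty intersections fall back to the untrimmed extent.
    """
    if not params.enabled:
        return cluster.extent
    mu, sigma = cluster_moments(cluster)
    if sigma == 0:
        return cluster.extent
    lo = math.floor(mu - params.k_sigma * sigma)
    hi = math.ceil(mu + params.k_sigma * sigma)
    lo = max(lo, cluster.extent.start)
    hi = min(hi, cluster.extent.end)
    if lo >= hi:
        return cluster.extent
    return GenomicInterval(cluster.chrom, lo, hi)


def otfrs_from_clusters(
    clusters: Sequence[PeakCluster],
    i_min: int,
    params: TrimParams = TrimParams(),
    *,
    _trim_cache: Optional[dict[int, GenomicInterval]] = None,
) -> list[OTFR]:
    """Select clusters with >= i_min member peaks and trim each.

    The trimmed region depends only on the cluster, so OTFR sets for
    different thresholds are nested. ``_trim_cache`` (cluster_id -> region)
    lets a caller sweeping many thresholds trim each cluster once.
    """
    if i_min < 2:
        raise ValueError(f"i_min must be >= 2, got {i_min}")
    out: list[OTFR] = []
    for c in clusters:
        if c.peak_count < i_min:
            continue
        if _trim_cache is not None and c.cluster_id in _trim_cache:
            region = _trim_cache[c.cluster_id]
        else:
            region = gaussian_trim(c, params)
            if _trim_cache is not None:
                _trim_cache[c.cluster_id] = region
        out.append(
            OTFR(
                cluster_id=c.cluster_id,
                chrom=c.chrom,
                region=region,
                peak_count=c.peak_count,
                trimmed=params.enabled and region != c.extent,
            )
        )
    return out


def build_otfr(
    peaks: Sequence[Peak], i_min: int, params: TrimParams = TrimParams()
) -> list[OTFR]:
    """Cluster peaks and return the OTFRs at threshold ``i_min`` (>= 2)."""
    return otfrs_from_clusters(cluster_peaks(peaks), i_min, params)


class _PointIndex:
    """Per-chromosome sorted-array index for point-in-interval queries."""

    def __init__(self, intervals: Sequence[GenomicInterval], payload: Sequence | None = None):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        groups: dict[str, list[int]] = {}
        for idx, iv in enumerate(intervals):
            groups.setdefault(iv.chrom, []).append(idx)
        for chrom, idxs in groups.items():
            idxs.sort(key=lambda i: intervals[i].start)
            starts = np.array([intervals[i].start for i in idxs])
            ends = np.array([intervals[i].end for i in idxs])
            pay = [payload[i] if payload is not None else None for i in idxs]
            self._by_chrom[chrom] = (starts, ends, pay)

    def coverage(self, chrom: str, pos: int) -> int:
        """Number of (possibly overlapping) intervals containing pos."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return 0
        starts, ends, _ = entry
        return int(np.count_nonzero((starts <= pos) & (pos < ends)))

    def find_disjoint(self, chrom: str, pos: int):
        """Payload of the (unique) containing interval, assuming disjointness."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, pay = entry
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j >= 0 and pos < ends[j]:
            return pay[j]
        return None


def annotate_snps(
    snps: Sequence[SNPRecord],
    peaks: Sequence[Peak],
    otfrs: Sequence[OTFR],
) -> list[SNPAnnotation]:
    """Annotate each SNP with its peak coverage depth and OTFR membership.

    depth_at_snp counts peaks whose half-open interval contains the position;
    in_otfr is point containment in any OTFR region (regions are disjoint,
    so the containing OTFR is unique).
    """
    # depth via per-chrom start/end arrays: depth(p) = #starts<=p - #ends<=p
    starts_by: dict[str, np.ndarray] = {}
    ends_by: dict[str, np.ndarray] = {}
    tmp: dict[str, tuple[list[int], list[int]]] = {}
    for p in peaks:
        s, e = tmp.setdefault(p.interval.chrom, ([], []))
        s.append(p.interval.start)
        e.append(p.interval.end)
    for chrom, (s, e) in tmp.items():
        starts_by[chrom] = np.sort(np.array(s))
        ends_by[chrom] = np.sort(np.array(e))

    otfr_index = _PointIndex([o.region for o in otfrs], list(otfrs))

    out: list[SNPAnnotation] = []
    for snp in snps:
        depth = 0
        if snp.chrom in starts_by:
            depth = int(
                np.searchsorted(starts_by[snp.chrom], snp.pos, side="right")
                - np.searchsorted(ends_by[snp.chrom], snp.pos, side="right")
            )
        hit: Optional[OTFR] = otfr_index.find_disjoint(snp.chrom, snp.pos)
        out.append(
            SNPAnnotation(
                snp_id=snp.id,
                in_otfr=hit is not None,
                cluster_id=hit.cluster_id if hit else None,
                depth_at_snp=depth,
                cluster_peak_count=hit.peak_count if hit else None,
            )
        )
    return out


def subtract_blacklist(
    snps: Sequence[SNPRecord], blacklist: Sequence[GenomicInterval]
) -> list[SNPRecord]:
    """Drop SNPs whose position falls inside any blacklist interval."""
    if not blacklist:
        return list(snps)
    index = _PointIndex(list(blacklist))
    kept = [s for s in snps if index.coverage(s.chrom, s.pos) == 0]
    removed = len(snps) - len(kept)
    if removed:
        log.info("blacklist removed %d of %d SNPs", removed, len(snps))
    return kept


def total_otfr_length(otfrs: Sequence[OTFR]) -> int:
    """Total bp covered by OTFR regions (regions are disjoint by construction)."""
    return sum(o.region.length for o in otfrs)
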