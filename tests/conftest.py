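"""Shared fixtures and per-base brute-force oracles.

The oracles materialize the genome as explicit arrays (one cell per base)
so clustering, coverage depth and point membership can be checked against
the sweep-line/searchsorted implementations on toy genomes.
"""

from __future__ import annotations

import numpy as np
import pytest

from otfrscan.formats import GenomicInterval, MotifMatrix, Peak, SNPRecord
from otfrscan.simulate import PeakSimConfig, simulate_peaks


def make_peak(chrom: str, start: int, end: int, factor: str = "TF1") -> Peak:
    return Peak(interval=GenomicInterval(chrom, start, end), factor=factor)


def brute_force_components(peaks: list[Peak]) -> list[frozenset[int]]:
    """Connected components of the pairwise-overlap graph (indices into peaks)."""
    n = len(peaks)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            if peaks[a].interval.overlaps(peaks[b].interval):
                parent[find(a)] = find(b)
    groups: dict[int, set[int]] = {}
    for a in range(n):
        groups.setdefault(find(a), set()).add(a)
    return [frozenset(g) for g in groups.values()]


def brute_force_depth(peaks: list[Peak], chrom: str, genome_len: int) -> np.ndarray:
    """Per-base peak coverage array for one chromosome."""
    depth = np.zeros(genome_len, dtype=int)
    for p in peaks:
        if p.interval.chrom == chrom:
            depth[p.interval.start : p.interval.end] += 1
    return depth


def brute_force_in_intervals(
    intervals: list[GenomicInterval], chrom: str, pos: int
) -> bool:
    return any(iv.contains(chrom, pos) for iv in intervals)


def random_toy_case(rng: np.random.Generator, genome_len: int = 2000, max_peaks: int = 100):
    """A random peak set on a toy single-chromosome genome."""
    n = int(rng.integers(1, max_peaks + 1))
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, genome_len - 1))
        length = int(rng.integers(1, min(200, genome_len - start) + 1))
        peaks.append(make_peak("chr1", start, start + length, f"TF{rng.integers(1, 6)}"))
    return peaks


@pytest.fixture(scope="session")
def fixture_peaks():
    """Default synthetic clustered peak track (10 Mb, 5,000 peaks)."""
    return simulate_peaks(PeakSimConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_config():
    return PeakSimConfig(seed=1)


@pytest.fixture
def simple_motif() -> MotifMatrix:
    """Width-4 motif with consensus ACGG and near-deterministic columns."""
    counts = np.zeros((4, 4))
    for j, b in enumerate("ACGG"):
        counts["ACGT".index(b), j] = 100.0
    return MotifMatrix(motif_id="MA9999.1", name="TESTM", counts=counts)


def snp(snp_id: str, chrom: str, pos: int, **kw) -> SNPRecord:
    return SNPRecord(id=snp_id, chrom=chrom, pos=pos, **kw)
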