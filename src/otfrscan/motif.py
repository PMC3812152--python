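"""Allele-specific motif impact: score both alleles of a SNP against
PWMs derived from JASPAR-style count matrices and call motifs created,
disrupted, strengthened or weakened by the substitution.

Scores are *relative* scores in [0, 1]: (raw log-odds - minimum possible)
/ (maximum - minimum), so the conventional 80% binding-site threshold and
the 5% between-allele difference rule both live on one scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .formats import BASES, MotifMatrix

log = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

Category = Literal["created", "disrupted", "strengthened", "weakened", "unchanged"]


class AmbiguousBaseError(ValueError):
    """Window contains a base outside {A, C, G, T}."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LogOddsMatrix:
    """Log2-odds scoring matrix with its per-window score range."""

    motif_id: str
    values: np.ndarray  # (4, w)
    min_score: float
    max_score: float

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AlleleWindowPair:
    """Reference and alternate sequence windows centered on one substitution."""

    snp_id: str
    flank: int
    seq_ref: str
    seq_alt: str
    snp_offset: int

    def __post_init__(self) -> None:
        if len(self.seq_ref) != len(self.seq_alt):
            raise ValueError("only substitutions are supported (equal-length alleles)")
        diffs = [i for i, (a, b) in enumerate(zip(self.seq_ref, self.seq_alt)) if a != b]
        if any(i != self.snp_offset for i in diffs):
            raise ValueError("sequences may differ only at snp_offset")
        if not (0 <= self.snp_offset < len(self.seq_ref)):
            raise ValueError("snp_offset outside sequence")


@dataclass(frozen=True)
class ImpactCall:
    motif_id: str
    strand: Literal["+", "-"]
    offset: int  # window start within the allele sequence (+ strand coords)
    score_ref: float
    score_alt: float
    category: Category


def pfm_to_logodds(
    pfm: MotifMatrix,
    pseudocount: float = 0.8,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> LogOddsMatrix:
    """Convert a count matrix to log2-odds against a background.

    value[b, j] = log2( (count[b,j] + pc*bg[b]) / (colsum_j + pc) / bg[b] ),
    the pseudocount being distributed over bases by the background.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must be 4 probabilities summing to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    values = np.log2(probs / bg[:, None])
    return LogOddsMatrix(
        motif_id=pfm.motif_id,
        values=values,
        min_score=float(values.min(axis=0).sum()),
        max_score=float(values.max(axis=0).sum()),
    )


def raw_score(matrix: LogOddsMatrix, window: str) -> float:
    if len(window) != matrix.width:
        raise ValueError(f"window length {len(window)} != motif width {matrix.width}")
    try:
        idx = [_BASE_INDEX[b] for b in window.upper()]
    except KeyError as exc:
        raise AmbiguousBaseError(f"ambiguous base {exc.args[0]!r} in window") from None
    return float(matrix.values[idx, np.arange(matrix.width)].sum())


def relative_score(matrix: LogOddsMatrix, window: str) -> float:
    """(raw - min) / (max - min), in [0, 1]; 1.0 iff per-column argmax bases."""
    return (raw_score(matrix, window) - matrix.min_score) / (
        matrix.max_score - matrix.min_score
    )


def _classify(
    score_ref: float, score_alt: float, threshold: float, delta: float
) -> Optional[Category]:
    """Category for one (motif, strand, offset), or None if the pair is omitted.

    Emission rule: a pair is omitted only when both alleles are below the
    threshold AND the score difference is within delta.
    """
    above_ref = score_ref >= threshold
    above_alt = score_alt >= threshold
    d = score_alt - score_ref
    if above_alt and not above_ref:
        return "created"
    if above_ref and not above_alt:
        return "disrupted"
    if above_ref and above_alt:
        if d > delta:
            return "strengthened"
        if -d > delta:
            return "weakened"
        return "unchanged"
    return "unchanged" if abs(d) > delta else None


def allele_impact(
    pair: AlleleWindowPair,
    motifs: Sequence[LogOddsMatrix],
    threshold: float = 0.80,
    delta: float = 0.05,
) -> list[ImpactCall]:
    """Scan every motif window overlapping the variant base, on both strands.

    Minus-strand scores are computed on the reverse complement of the same
    (+ strand) window; offsets are always reported in + coordinates of the
    allele sequence. Windows containing ambiguous bases are skipped with a
    notice. Output sorted by (motif_id, offset, strand).
    """
    if pair.seq_ref == pair.seq_alt:
        return []  # no substitution, nothing to call
    calls: list[ImpactCall] = []
    L = len(pair.seq_ref)
    for m in motifs:
        w = m.width
        lo = max(0, pair.snp_offset - w + 1)
        hi = min(L - w, pair.snp_offset)
        for offset in range(lo, hi + 1):
            win_ref = pair.seq_ref[offset : offset + w]
            win_alt = pair.seq_alt[offset : offset + w]
            for strand in ("+", "-"):
                try:
                    if strand == "+":
                        s_ref = relative_score(m, win_ref)
                        s_alt = relative_score(m, win_alt)
                    else:
                        s_ref = relative_score(m, reverse_complement(win_ref))
                        s_alt = relative_score(m, reverse_complement(win_alt))
                except AmbiguousBaseError:
                    log.info(
                        "skipping window at offset %d for motif %s: ambiguous base",
                        offset,
                        m.motif_id,
                    )
                    continue
                category = _classify(s_ref, s_alt, threshold, delta)
                if category is None:
                    continue
                calls.append(
                    ImpactCall(
                        motif_id=m.motif_id,
                        strand=strand,
                        offset=offset,
                        score_ref=s_ref,
                        score_alt=s_alt,
                        category=category,
                    )
                )
    calls.sort(key=lambda c: (c.motif_id, c.offset, c.strand))
    return calls
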