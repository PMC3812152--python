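"""Readers and writers for the external formats the pipeline touches.

All coordinates are normalized to a single internal convention at the
boundary: 0-based, half-open ``[start, end)`` intervals and 0-based point
positions, matching BED. 1-based sources (VCF, ``chr:start-end`` region
strings) are converted on read and never leak inward.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import motifs as bio_motifs

log = logging.getLogger(__name__)

BASES = "ACGT"


class ParseError(ValueError):
    """A malformed data line; the message names the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open.

    ``start`` is inclusive, ``end`` exclusive; a single base b is ``[b, b+1)``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True on >=1 bp of shared sequence; abutting intervals do NOT overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq binding locus: an interval plus the bound factor's name.

    ``extra`` keeps any trailing input columns verbatim (opaque metadata;
    never interpreted).
    """

    interval: GenomicInterval
    factor: str
    score: Optional[float] = None
    source_line: Optional[int] = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.factor:
            raise ValueError("factor must be non-empty")


@dataclass
class SNPRecord:
    """A point variant, optionally carrying association statistics."""

    id: str
    chrom: str
    pos: int  # 0-based
    ref_allele: str = ""
    alt_alleles: tuple[str, ...] = ()
    p_value: Optional[float] = None
    odds_ratio: Optional[float] = None
    sample_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"SNP {self.id}: pos must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class MotifMatrix:
    """A position frequency matrix: base counts per motif column.

    ``counts`` has shape (4, w), rows indexed A, C, G, T.
    """

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x w, w >= 1")
        if (c < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if (c.sum(axis=0) <= 0).any():
            raise ValueError(f"motif {self.motif_id}: zero-sum column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in self.counts.argmax(axis=0))


ChromSizes = dict  # chrom -> length (bp); validated by read_chrom_sizes


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) for data lines of a BED-like file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_coord(text: str, lineno: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer {what} {text!r}") from None


def read_tfbs_clusters(
    path: str | Path, dialect: Literal["bed4plus"] = "bed4plus"
) -> list[Peak]:
    """Read a TF-binding peak track in BED4+ layout.

    Columns: chrom, start, end, factor[, score, ...]. Extra columns are kept
    opaque on each ``Peak``. Returns peaks in file order. Empty file -> [].
    """
    if dialect != "bed4plus":
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: expected >=4 fields, got {len(fields)}")
        chrom, start, end, factor = fields[0], fields[1], fields[2], fields[3]
        s = _parse_coord(start, lineno, "start")
        e = _parse_coord(end, lineno, "end")
        if s >= e:
            raise ParseError(f"line {lineno}: start {s} >= end {e}")
        score: Optional[float] = None
        if len(fields) >= 5 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric score {fields[4]!r}") from None
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, s, e),
                factor=factor,
                score=score,
                source_line=lineno,
                extra=tuple(fields[5:]),
            )
        )
    return peaks


def _warn_duplicate_ids(records: Sequence[SNPRecord]) -> None:
    seen: set[str] = set()
    dupes = 0
    for r in records:
        if r.id in seen:
            dupes += 1
        seen.add(r.id)
    if dupes:
        log.warning("%d duplicate SNP ids encountered; all records kept", dupes)


def _read_snps_bed(path: str | Path) -> list[SNPRecord]:
    out: list[SNPRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected >=3 fields, got {len(fields)}")
        chrom = fields[0]
        s = _parse_coord(fields[1], lineno, "start")
        e = _parse_coord(fields[2], lineno, "end")
        if s >= e:
            raise ParseError(f"line {lineno}: start {s} >= end {e}")
        snp_id = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") else f"{chrom}:{s}"
        out.append(SNPRecord(id=snp_id, chrom=chrom, pos=s))
    return out


def _read_snps_vcf(path: str | Path) -> list[SNPRecord]:
    out: list[SNPRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            pos0 = rec.pos - 1  # pysam pos is 1-based
            if pos0 < 0:
                raise ParseError(f"VCF record at {rec.chrom}:{rec.pos}: position underflow")
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            out.append(
                SNPRecord(
                    id=snp_id,
                    chrom=rec.chrom,
                    pos=pos0,
                    ref_allele=rec.ref or "",
                    alt_alleles=tuple(a for a in (rec.alts or ()) if a),
                )
            )
    return out


# recognized tsv header names (case-insensitive) -> canonical field
_TSV_ALIASES = {
    "id": "id", "snp": "id", "rsid": "id", "snp_id": "id",
    "chrom": "chrom", "chr": "chrom", "chromosome": "chrom",
    "pos": "pos0", "pos0": "pos0", "pos1": "pos1", "position": "pos1",
    "ref": "ref", "alt": "alt",
    "p": "p_value", "p_value": "p_value", "pvalue": "p_value", "p-value": "p_value",
    "or": "odds_ratio", "odds_ratio": "odds_ratio",
    "sample": "sample_label", "sample_label": "sample_label",
}


def _read_snps_tsv(path: str | Path) -> list[SNPRecord]:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {}
    for c in df.columns:
        key = _TSV_ALIASES.get(str(c).strip().lower())
        if key is not None:
            cols[key] = c
    if "chrom" not in cols or ("pos0" not in cols and "pos1" not in cols):
        raise ParseError(
            f"{path}: association table must declare chrom and pos/pos1 columns "
            f"(got {list(df.columns)})"
        )
    out: list[SNPRecord] = []
    for idx, row in df.iterrows():
        if "pos0" in cols:
            pos = int(row[cols["pos0"]])
        else:
            pos = int(row[cols["pos1"]]) - 1
        if pos < 0:
            raise ParseError(f"{path} row {idx}: position underflow after 1->0-based conversion")

        def _opt_float(key: str) -> Optional[float]:
            if key not in cols:
                return None
            v = row[cols[key]]
            return None if pd.isna(v) else float(v)

        snp_id = str(row[cols["id"]]) if "id" in cols else f"row{idx}"
        alt = str(row[cols["alt"]]) if "alt" in cols and not pd.isna(row[cols["alt"]]) else ""
        out.append(
            SNPRecord(
                id=snp_id,
                chrom=str(row[cols["chrom"]]),
                pos=pos,
                ref_allele=str(row[cols["ref"]]) if "ref" in cols and not pd.isna(row[cols["ref"]]) else "",
                alt_alleles=tuple(alt.split(",")) if alt else (),
                p_value=_opt_float("p_value"),
                odds_ratio=_opt_float("odds_ratio"),
                sample_label=str(row[cols["sample_label"]]) if "sample_label" in cols else None,
            )
        )
    return out


def read_snps(path: str | Path, dialect: Literal["bed", "vcf", "tsv"]) -> list[SNPRecord]:
    """Read a SNP set; positions normalized to 0-based regardless of dialect.

    ``bed`` uses the BED start as the position; ``vcf`` converts the 1-based
    POS; ``tsv`` expects a header declaring the columns (``pos`` is taken as
    0-based, ``pos1``/``position`` as 1-based). Duplicate ids trigger a
    warning but both records are kept.
    """
    readers = {"bed": _read_snps_bed, "vcf": _read_snps_vcf, "tsv": _read_snps_tsv}
    if dialect not in readers:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(readers)}")
    records = readers[dialect](path)
    _warn_duplicate_ids(records)
    return records


_BARE_LABELED_ROW = re.compile(r"^\s*([ACGTacgt])\s+([-\d.eE\s]+)$")


def read_jaspar_pfm(path: str | Path) -> list[MotifMatrix]:
    """Read one or more JASPAR-format position frequency matrices.

    Accepts the standard layout (``>ID name`` header, then four count rows
    labeled A, C, G, T with or without brackets). Parsing is delegated to
    Bio.motifs after normalizing bare labeled rows, which the upstream parser
    does not accept.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return []
    if not text.lstrip().startswith(">"):
        raise ParseError(f"{path}: missing '>ID name' header")
    lines = []
    for line in text.splitlines():
        m = _BARE_LABELED_ROW.match(line)
        lines.append(f"{m.group(1)} [ {m.group(2)} ]" if m else line)
    try:
        parsed = bio_motifs.parse(io.StringIO("\n".join(lines)), "jaspar")
    except Exception as exc:  # Bio raises bare Exceptions on layout errors
        raise ParseError(f"{path}: malformed JASPAR record ({exc})") from exc
    out: list[MotifMatrix] = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        out.append(MotifMatrix(motif_id=m.matrix_id or m.name, name=m.name, counts=counts))
    return out


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: ChromSizes = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"line {lineno}: expected 'chrom length'")
        length = _parse_coord(fields[1], lineno, "length")
        if length <= 0:
            raise ParseError(f"line {lineno}: non-positive length {length}")
        sizes[fields[0]] = length
    return sizes


_REGION_RE = re.compile(r"^([^\s:]+):([\d,]+)-([\d,]+)$")


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``chrom:start-end`` string (commas allowed)
    into a 0-based half-open interval.

    ``chr6:29,909,708-31,325,212`` -> chr6:[29909707, 31325212).
    """
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ParseError(f"unparseable region string {text!r}")
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    if start1 < 1 or end1 < start1:
        raise ParseError(f"invalid 1-based region {text!r}")
    return GenomicInterval(m.group(1), start1 - 1, end1)


def read_blacklist(path: str | Path) -> list[GenomicInterval]:
    """Read exclusion intervals: BED lines or 1-based ``chrom:start-end`` strings."""
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        first = line.split()[0]
        if ":" in first and "-" in first:
            out.append(parse_region_string(first))
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected BED interval or chrom:start-end")
        s = _parse_coord(fields[1], lineno, "start")
        e = _parse_coord(fields[2], lineno, "end")
        if s >= e:
            raise ParseError(f"line {lineno}: start {s} >= end {e}")
        out.append(GenomicInterval(fields[0], s, e))
    return out


def write_otfr_bed(otfrs, path: str | Path) -> None:
    """Write OTFRs as BED6 plus a 7th true-peak-count column.

    The BED score is the peak count clamped to 1000 for browser validity; the
    unclamped count is emitted in column 7. Name is ``otfr_<cluster_id>``.
    """
    with open(path, "w") as fh:
        for o in otfrs:
            fh.write(
                f"{o.region.chrom}\t{o.region.start}\t{o.region.end}\t"
                f"otfr_{o.cluster_id}\t{min(o.peak_count, 1000)}\t.\t{o.peak_count}\n"
            )
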