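"""End-to-end pipeline: peaks -> OTFR(i) -> SNP annotation -> enrichment
curve with bootstrap -> candidate rSNP shortlist -> optional motif impact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .enrichment import (
    AssociationFilter,
    bootstrap_enrichment,
    count_snps_in_regions,
    enrichment,
    filter_association,
)
from .formats import read_blacklist, read_chrom_sizes, read_snps, read_tfbs_clusters, write_otfr_bed
from .motif import AlleleWindowPair, allele_impact, pfm_to_logodds
from .otfr import (
    TrimParams,
    annotate_snps,
    cluster_peaks,
    otfrs_from_clusters,
    subtract_blacklist,
    total_otfr_length,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    peaks_path: str
    snps_path: str
    out_dir: str
    snps_dialect: str = "bed"
    blacklist_path: Optional[str] = None
    chrom_sizes_path: Optional[str] = None
    pfm_path: Optional[str] = None
    fasta_path: Optional[str] = None
    i_min: int = 7
    i_range: tuple[int, ...] = tuple(range(2, 16))
    trim: TrimParams = field(default_factory=TrimParams)
    bootstrap_b: int = 500
    seed: int = 0
    ci_level: float = 0.99
    genome_length: int = 3_000_000_000
    association_filter: Optional[AssociationFilter] = None
    motif_threshold: float = 0.80
    motif_delta: float = 0.05

    def __post_init__(self) -> None:
        if self.i_min < 2:
            raise ValueError("i_min must be >= 2")


def _motif_stage(config: PipelineConfig, candidates, snp_by_id, out_path: Path) -> int:
    from pyfaidx import Fasta

    from .formats import read_jaspar_pfm

    pfms = read_jaspar_pfm(config.pfm_path)
    matrices = [pfm_to_logodds(m) for m in pfms]
    flank = max((m.width for m in matrices), default=1) - 1
    genome = Fasta(config.fasta_path, as_raw=True, sequence_always_upper=True)
    rows = []
    for ann in candidates:
        snp = snp_by_id[ann.snp_id]
        if len(snp.ref_allele) != 1 or not snp.alt_alleles:
            continue
        seq = str(genome[snp.chrom][max(0, snp.pos - flank) : snp.pos + flank + 1])
        offset = snp.pos - max(0, snp.pos - flank)
        if seq[offset] != snp.ref_allele:
            log.warning("SNP %s: reference allele mismatch with FASTA; skipped", snp.id)
            continue
        for alt in snp.alt_alleles:
            if len(alt) != 1:
                continue
            pair = AlleleWindowPair(
                snp_id=snp.id,
                flank=flank,
                seq_ref=seq,
                seq_alt=seq[:offset] + alt + seq[offset + 1 :],
                snp_offset=offset,
            )
            for call in allele_impact(
                pair, matrices, threshold=config.motif_threshold, delta=config.motif_delta
            ):
                rows.append(
                    dict(
                        snp_id=snp.id,
                        motif_id=call.motif_id,
                        strand=call.strand,
                        offset=call.offset,
                        score_ref=round(call.score_ref, 6),
                        score_alt=round(call.score_alt, 6),
                        category=call.category,
                    )
                )
    pd.DataFrame(
        rows,
        columns=["snp_id", "motif_id", "strand", "offset", "score_ref", "score_alt", "category"],
    ).to_csv(out_path, sep="\t", index=False)
    return len(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns a map of artifact name -> path.

    Artifacts: otfr.bed, annotated_snps.tsv, enrichment.tsv, candidates.tsv,
    impact.tsv (when PFM + FASTA inputs are given) and run_log.txt. Any
    stage failure removes partial outputs and raises a stage-named error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines: list[str] = [f"otfrscan {__version__}", f"seed {config.seed}"]

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in artifacts.values():
                        p.unlink(missing_ok=True)
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("read-peaks"):
        peaks = read_tfbs_clusters(config.peaks_path)
        log_lines.append(f"peaks {len(peaks)}")
    with stage("read-snps"):
        snps = read_snps(config.snps_path, config.snps_dialect)
        log_lines.append(f"snps {len(snps)}")
    with stage("blacklist"):
        if config.blacklist_path:
            blacklist = read_blacklist(config.blacklist_path)
            snps = subtract_blacklist(snps, blacklist)
        log_lines.append(f"snps_after_blacklist {len(snps)}")
    with stage("association-filter"):
        if config.association_filter is not None:
            snps = filter_association(snps, config.association_filter)
        log_lines.append(f"snps_after_filter {len(snps)}")
    with stage("genome-length"):
        genome_length = config.genome_length
        if config.chrom_sizes_path:
            genome_length = sum(read_chrom_sizes(config.chrom_sizes_path).values())
        log_lines.append(f"genome_length {genome_length}")
    with stage("build-otfr"):
        clusters = cluster_peaks(peaks)
        otfrs = otfrs_from_clusters(clusters, config.i_min, config.trim)
        path = out_dir / "otfr.bed"
        write_otfr_bed(otfrs, path)
        artifacts["otfr"] = path
        log_lines.append(f"clusters {len(clusters)}")
        log_lines.append(f"otfrs_at_i{config.i_min} {len(otfrs)}")
        log_lines.append(f"otfr_total_length {total_otfr_length(otfrs)}")
    with stage("annotate"):
        annotations = annotate_snps(snps, peaks, otfrs)
        snp_by_id = {s.id: s for s in snps}
        path = out_dir / "annotated_snps.tsv"
        pd.DataFrame(
            dict(
                snp_id=a.snp_id,
                chrom=snp_by_id[a.snp_id].chrom,
                pos0=snp_by_id[a.snp_id].pos,
                depth_at_snp=a.depth_at_snp,
                cluster_id=a.cluster_id,
                cluster_peak_count=a.cluster_peak_count,
                in_otfr=a.in_otfr,
            )
            for a in annotations
        ).to_csv(path, sep="\t", index=False)
        artifacts["annotated_snps"] = path
        n_in = sum(a.in_otfr for a in annotations)
        log_lines.append(f"snps_in_otfr {n_in}")
    with stage("enrichment"):
        i_values = sorted(set(config.i_range) | {config.i_min})
        rows = []
        trim_cache: dict = {}
        for i in i_values:
            otfrs_i = otfrs_from_clusters(clusters, i, config.trim, _trim_cache=trim_cache)
            length_i = total_otfr_length(otfrs_i)
            n_in_i = count_snps_in_regions(snps, otfrs_i)
            if otfrs_i and snps:
                res = enrichment(n_in_i, len(snps), length_i, genome_length, i_min=i)
                boot = bootstrap_enrichment(
                    snps,
                    otfrs_i,
                    B=config.bootstrap_b,
                    seed=config.seed + i,
                    ci_level=config.ci_level,
                    genome_length=genome_length,
                )
            else:  # no regions survive this threshold (or no SNPs): E undefined
                res, boot = None, None
            rows.append(
                dict(
                    i=i,
                    n_in=n_in_i,
                    n_total=len(snps),
                    L=length_i,
                    G=genome_length,
                    E=res.e_value if res else float("nan"),
                    boot_mean=boot.mean if boot else float("nan"),
                    boot_sd=boot.sd if boot else float("nan"),
                    ci_low=boot.ci_low if boot else float("nan"),
                    ci_high=boot.ci_high if boot else float("nan"),
                    chi2_p=boot.chi2_p if boot else float("nan"),
                )
            )
        path = out_dir / "enrichment.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        artifacts["enrichment"] = path
    with stage("candidates"):
        candidates = sorted(
            (a for a in annotations if a.in_otfr),
            key=lambda a: (-a.depth_at_snp, -(a.cluster_peak_count or 0), a.snp_id),
        )
        path = out_dir / "candidates.tsv"
        pd.DataFrame(
            dict(
                snp_id=a.snp_id,
                chrom=snp_by_id[a.snp_id].chrom,
                pos0=snp_by_id[a.snp_id].pos,
                depth_at_snp=a.depth_at_snp,
                cluster_id=a.cluster_id,
                cluster_peak_count=a.cluster_peak_count,
            )
            for a in candidates
        ).to_csv(path, sep="\t", index=False)
        artifacts["candidates"] = path
        log_lines.append(f"candidates {len(candidates)}")
    if config.pfm_path and config.fasta_path:
        with stage("motif-impact"):
            path = out_dir / "impact.tsv"
            n_calls = _motif_stage(config, candidates, snp_by_id, path)
            artifacts["impact"] = path
            log_lines.append(f"impact_calls {n_calls}")
    log_path = out_dir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    artifacts["run_log"] = log_path
    return artifacts
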