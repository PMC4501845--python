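"""mtDNA copy number from whole-genome sequencing coverage.

Sequencing coverage is proportional to the number of template molecules, so
with two autosomal copies per cell the number of mitochondrial genomes per
cell is

    copy number = 2 * (mean mtDNA depth) / (mean autosomal depth)

Mean depths are arithmetic means of per-base coverage over the requested
regions, counting zero-coverage positions and excluding reference N-gaps
(assembly gaps cannot be covered and would deflate the autosomal mean).
Depth is computed from the same read set the variant caller uses:
non-duplicate, primary alignments with mapping quality above the configured
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pysam

from .errors import InvalidInputError
from .qc_filters import FilterConfig

#: GRCh37/38-style autosome names, with and without the "chr" prefix
AUTOSOME_NAMES = tuple(str(i) for i in range(1, 23)) + tuple(
    f"chr{i}" for i in range(1, 23))


@dataclass
class CoverageSummary:
    per_chromosome_mean_depth: dict[str, float]
    mt_mean_depth: float
    autosomal_mean_depth: float
    copy_number: float

    def to_row(self, sample_id: str) -> str:
        return (f"{sample_id}\t{self.mt_mean_depth:.6g}\t"
                f"{self.autosomal_mean_depth:.6g}\t{self.copy_number:.6g}")


def estimate_copy_number(mt_mean: float, auto_mean: float) -> float:
    """Copies of mtDNA per cell: ``2 * mt_mean / auto_mean``."""
    if auto_mean <= 0:
        raise InvalidInputError(
            f"autosomal mean depth must be positive, got {auto_mean}")
    if mt_mean < 0:
        raise InvalidInputError(f"negative mtDNA mean depth {mt_mean}")
    return 2.0 * mt_mean / auto_mean


def _read_passes(cfg: FilterConfig):
    def cb(read):
        return (not read.is_unmapped and not read.is_duplicate
                and not read.is_secondary and not read.is_supplementary
                and not read.is_qcfail
                and read.mapping_quality >= cfg.min_mapping_quality)
    return cb


def _region_depth(bam: pysam.AlignmentFile, contig: str, start: int, end: int,
                  cfg: FilterConfig) -> np.ndarray:
    """Per-base depth over a 1-based inclusive interval."""
    cov = bam.count_coverage(contig, start - 1, end, quality_threshold=0,
                             read_callback=_read_passes(cfg))
    return np.asarray(cov).sum(axis=0)


def mean_depth(bam, regions, reference: Mapping[str, str] | None = None,
               cfg: FilterConfig | None = None) -> float:
    """Arithmetic mean of per-base depth over a set of regions.

    ``regions`` is a list of contig names (whole contig) or ``(contig,
    start, end)`` tuples with 1-based inclusive coordinates.  Zero-coverage
    positions count toward the mean; positions whose reference base is N are
    excluded when ``reference`` (a mapping contig -> sequence) is supplied.
    """
    cfg = cfg or FilterConfig()
    own = not isinstance(bam, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(bam)) if own else bam
    regions = list(regions)
    if not regions:
        raise InvalidInputError("empty region set")
    try:
        total, n_positions = 0.0, 0
        for region in regions:
            if isinstance(region, str):
                contig, start = region, 1
                end = af.get_reference_length(contig)
            else:
                contig, start, end = region
            if contig not in af.references:
                raise InvalidInputError(f"contig {contig!r} absent from BAM header")
            depth = _region_depth(af, contig, start, end, cfg)
            if reference is not None and contig in reference:
                seq = reference[contig][start - 1:end].upper()
                keep = np.frombuffer(seq.encode(), dtype=np.uint8) != ord("N")
                depth = depth[keep]
            total += float(depth.sum())
            n_positions += int(depth.size)
    finally:
        if own:
            af.close()
    if n_positions == 0:
        raise InvalidInputError("regions contain no usable positions")
    return total / n_positions


def coverage_summary(bam, mt_contig: str = "MT", autosomes=None,
                     reference: Mapping[str, str] | None = None,
                     cfg: FilterConfig | None = None) -> CoverageSummary:
    """Per-chromosome mean depths and the derived mtDNA copy number.

    ``autosomes`` defaults to whichever of chr1-chr22 (with or without
    prefix) are present in the BAM header; sex chromosomes and decoy contigs
    never contribute to the autosomal mean.
    """
    cfg = cfg or FilterConfig()
    own = not isinstance(bam, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(bam)) if own else bam
    try:
        if autosomes is None:
            autosomes = [c for c in af.references if c in AUTOSOME_NAMES]
        if not autosomes:
            raise InvalidInputError("no autosomal contigs found in BAM header")
        if mt_contig not in af.references:
            raise InvalidInputError(f"mtDNA contig {mt_contig!r} absent from BAM")
        per_chrom = {}
        auto_total, auto_n = 0.0, 0
        for contig in list(autosomes) + [mt_contig]:
            length = af.get_reference_length(contig)
            depth = _region_depth(af, contig, 1, length, cfg)
            if reference is not None and contig in reference:
                seq = reference[contig][:length].upper()
                keep = np.frombuffer(seq.encode(), dtype=np.uint8) != ord("N")
                depth = depth[keep]
            per_chrom[contig] = float(depth.mean()) if depth.size else float("nan")
            if contig != mt_contig:
                auto_total += float(depth.sum())
                auto_n += int(depth.size)
    finally:
        if own:
            af.close()
    auto_mean = auto_total / auto_n if auto_n else float("nan")
    mt_mean = per_chrom[mt_contig]
    return CoverageSummary(
        per_chromosome_mean_depth=per_chrom,
        mt_mean_depth=mt_mean,
        autosomal_mean_depth=auto_mean,
        copy_number=estimate_copy_number(mt_mean, auto_mean),
    )
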