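"""Quality-control filters for mtDNA variant calling.

The filter stack operates at four levels:

* reads: uniquely mtDNA-mapped, non-duplicate, mapping quality >= 20;
* bases: Phred quality >= 20 (error rate <= 1%);
* sites: raw depth >= 40 and quality-filtered depth >= 10;
* samples: overall mtDNA median depth strictly > 100;
* heteroplasmy calls: every called allele observed on both strands, and the
  minor allele fraction >= 4%.

Thresholds live in :class:`FilterConfig` and can be serialised to/from a
plain ``key = value`` text file.  Failures are reported as named flags so
downstream code can log why each call was rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ContractError, InvalidInputError
from .genotype_model import HETEROPLASMY, BASE_TO_CODE, GenotypeCall, PileupColumn

# named filter-failure flags
FLAG_RAW_DEPTH = "raw_depth"
FLAG_FILTERED_DEPTH = "filtered_depth"
FLAG_STRAND = "strand"
FLAG_MAF = "maf"
FLAG_MEDIAN_DEPTH = "median_depth"


@dataclass
class FilterConfig:
    min_mapping_quality: int = 20
    min_base_quality: int = 20
    min_sample_median_depth: float = 100.0  # strict ">"
    min_raw_site_depth: int = 40
    min_filtered_site_depth: int = 10
    min_maf: float = 0.04
    require_dual_strand: bool = True

    def __post_init__(self):
        for name in ("min_mapping_quality", "min_base_quality",
                     "min_sample_median_depth", "min_raw_site_depth",
                     "min_filtered_site_depth"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if not 0.0 <= self.min_maf <= 0.5:
            raise InvalidInputError("min_maf must lie in [0, 0.5]")

    def to_file(self, path):
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "FilterConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float,
                 "bool": lambda s: s.lower() in ("1", "true", "yes")}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise InvalidInputError(f"unknown filter option {key!r}")
                kwargs[key] = casts[types[key]](value.strip())
        return cls(**kwargs)


def filter_reads(reads: Iterable, cfg: FilterConfig | None = None,
                 mt_contigs=None) -> list:
    """Keep uniquely mtDNA-mapped, non-duplicate reads with sufficient
    mapping quality.

    ``reads`` is an iterable of :class:`pysam.AlignedSegment`-like objects.
    Secondary/supplementary records, QC-fail reads and unmapped reads are
    removed; if ``mt_contigs`` is given, reads mapped elsewhere are removed
    too.
    """
    cfg = cfg or FilterConfig()
    contigs = set(mt_contigs) if mt_contigs is not None else None
    kept = []
    for r in reads:
        if r.is_unmapped or r.is_duplicate:
            continue
        if getattr(r, "is_secondary", False) or getattr(r, "is_supplementary", False):
            continue
        if getattr(r, "is_qcfail", False):
            continue
        if r.mapping_quality < cfg.min_mapping_quality:
            continue
        if contigs is not None and r.reference_name not in contigs:
            continue
        kept.append(r)
    return kept


def filter_column(column: PileupColumn, cfg: FilterConfig | None = None):
    """Drop low-quality observations from a column and judge the site.

    Returns ``(filtered_column, verdict, flags)``.  ``verdict`` is False when
    the site must be excluded from calling: raw depth below
    ``min_raw_site_depth`` or quality-filtered depth below
    ``min_filtered_site_depth``.  Idempotent: filtering a filtered column
    changes nothing.
    """
    cfg = cfg or FilterConfig()
    keep = column.qualities >= cfg.min_base_quality
    filtered = PileupColumn(column.position, column.base_codes[keep],
                            column.qualities[keep], column.forward[keep],
                            raw_depth=column.raw_depth)
    flags = set()
    if column.raw_depth < cfg.min_raw_site_depth:
        flags.add(FLAG_RAW_DEPTH)
    if len(filtered) < cfg.min_filtered_site_depth:
        flags.add(FLAG_FILTERED_DEPTH)
    return filtered, not flags, flags


def sample_passes_depth(per_base_depths, cfg: FilterConfig | None = None) -> bool:
    """Sample-level gate: median raw depth over all positions (zeros
    included) strictly greater than the threshold."""
    cfg = cfg or FilterConfig()
    depths = np.asarray(per_base_depths, dtype=float)
    if depths.size == 0:
        raise InvalidInputError("empty depth vector")
    return bool(np.median(depths) > cfg.min_sample_median_depth)


def filter_heteroplasmy_call(call: GenotypeCall, column: PileupColumn,
                             cfg: FilterConfig | None = None):
    """Heteroplasmy-specific filters: dual-strand support for every called
    allele and minor allele fraction at or above the threshold.

    ``column`` may be raw or already quality-filtered; the strand requirement
    is evaluated on quality-filtered observations either way.  Returns
    ``(verdict, flags)``.
    """
    cfg = cfg or FilterConfig()
    if call.classification != HETEROPLASMY:
        raise ContractError("filter_heteroplasmy_call expects a heteroplasmic "
                            f"call, got {call.classification}")
    flags = set()
    if cfg.require_dual_strand:
        keep = column.qualities >= cfg.min_base_quality
        codes = column.base_codes[keep]
        forward = column.forward[keep]
        for allele in call.genotype.alleles:
            mask = codes == BASE_TO_CODE[allele]
            if not (np.any(mask & forward) and np.any(mask & ~forward)):
                flags.add(FLAG_STRAND)
                break
    if call.minor_allele_fraction < cfg.min_maf - 1e-12:
        flags.add(FLAG_MAF)
    return (not flags, flags)
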