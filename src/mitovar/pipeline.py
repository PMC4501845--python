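"""End-to-end variant-calling pipeline over the double alignment.

``run_call_pipeline`` ties the pieces together for one sample: pileups from
the primary (standard reference) and shifted BAMs, the sample-level median-
depth gate, per-column filtering and genotype calling inside each
alignment's owned region, remapping and merging of the two call sets, and
TSV/VCF export.  Deterministic given identical inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import io as mio
from .circular_ref import (CircularReferencePair, merge_variant_sets,
                           original_to_shifted, shifted_to_original)
from .genotype_model import (HETEROPLASMY, REFERENCE, GenotypeCall,
                             PileupColumn, call_genotype)
from .qc_filters import (FLAG_MEDIAN_DEPTH, FilterConfig, filter_column,
                         filter_heteroplasmy_call, sample_passes_depth)

logger = logging.getLogger(__name__)


def call_sample_columns(columns: Sequence[PileupColumn],
                        ref_bases: Sequence[str],
                        cfg: FilterConfig | None = None,
                        prior=None) -> list[GenotypeCall]:
    """Filter and call a set of pileup columns against per-column reference
    bases.

    Sites failing the raw/filtered depth requirements are skipped entirely
    (no call is emitted for them).  Heteroplasmic calls carry the named
    flags of any strand/MAF filter failures; all other calls pass through
    unflagged.
    """
    cfg = cfg or FilterConfig()
    if len(columns) != len(ref_bases):
        raise ValueError("columns and ref_bases differ in length")
    calls = []
    for column, ref in zip(columns, ref_bases):
        filtered, ok, _flags = filter_column(column, cfg)
        if not ok:
            continue
        call = call_genotype(filtered, ref, prior)
        if call.classification == HETEROPLASMY:
            _verdict, hflags = filter_heteroplasmy_call(call, filtered, cfg)
            call.filter_flags |= hflags
        calls.append(call)
    return calls


@dataclass
class PipelineResult:
    sample_id: str
    records: list  # VariantRecord, sorted by position
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


def _owned_depth_vector(pair: CircularReferencePair,
                        primary_cols: dict[int, PileupColumn],
                        shifted_cols: dict[int, PileupColumn]) -> np.ndarray:
    """Per-position raw depth over the whole genome, each position read from
    the alignment that owns it (zero where uncovered)."""
    depths = np.zeros(pair.length)
    for pos in range(1, pair.length + 1):
        if pair.owns_primary(pos):
            col = primary_cols.get(pos)
        else:
            col = shifted_cols.get(original_to_shifted(pos, pair))
        if col is not None:
            depths[pos - 1] = col.raw_depth
    return depths


def run_call_pipeline(primary_bam, shifted_bam, pair: CircularReferencePair,
                      cfg: FilterConfig | None = None, *,
                      sample_id: str = "SAMPLE",
                      mt_contig: str = "MT",
                      shifted_contig: str = "MT_shifted",
                      prior=None,
                      out_prefix: str | None = None) -> PipelineResult:
    """Call mtDNA variants for one sample from its double alignment.

    Returns a :class:`PipelineResult`; when the sample fails the median-depth
    gate no records are produced and ``skipped_reason`` says why.  With
    ``out_prefix`` the merged variant set is written to ``<prefix>.tsv`` and
    ``<prefix>.vcf``.
    """
    cfg = cfg or FilterConfig()
    primary = {c.position: c for c in mio.pileup_from_bam(primary_bam,
                                                          mt_contig, cfg=cfg)}
    shifted = {c.position: c for c in mio.pileup_from_bam(shifted_bam,
                                                          shifted_contig,
                                                          cfg=cfg)}

    depths = _owned_depth_vector(pair, primary, shifted)
    if not sample_passes_depth(depths, cfg):
        logger.warning("sample %s skipped: median depth %.1f not above %g",
                       sample_id, float(np.median(depths)),
                       cfg.min_sample_median_depth)
        return PipelineResult(sample_id, [], skipped_reason=FLAG_MEDIAN_DEPTH)

    primary_columns = [c for p, c in sorted(primary.items())
                       if pair.owns_primary(p)]
    primary_refs = [pair.original[c.position - 1] for c in primary_columns]
    shifted_seq = pair.shifted
    shifted_columns = [
        c for p, c in sorted(shifted.items())
        if not pair.owns_primary(shifted_to_original(p, pair))]
    shifted_refs = [shifted_seq[c.position - 1] for c in shifted_columns]

    primary_calls = call_sample_columns(primary_columns, primary_refs, cfg,
                                        prior)
    shifted_calls = call_sample_columns(shifted_columns, shifted_refs, cfg,
                                        prior)
    merged = merge_variant_sets(primary_calls, shifted_calls, pair)

    records = [
        mio.VariantRecord.from_call(sample_id, call,
                                    pair.original[call.position - 1])
        for call in merged if call.classification != REFERENCE
    ]
    if out_prefix is not None:
        mio.write_variants_tsv(records, f"{out_prefix}.tsv")
        mio.write_variants_vcf(records, f"{out_prefix}.vcf",
                               contig=mt_contig, contig_length=pair.length)
    return PipelineResult(sample_id, records)
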