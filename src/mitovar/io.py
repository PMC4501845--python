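"""File formats: FASTA/FASTQ, pileup text, variant TSV/VCF, BAM ingestion.

The caller's native tabular output is a per-sample variant TSV (one row per
called site); a VCF 4.2 export is provided for interoperability, encoding
heteroplasmies as multi-allelic records with per-ALT allele fractions in the
``AF`` format field and failed filters in the FILTER column.  Both formats
round-trip every :class:`VariantRecord` field.

The bundled pileup text format (used by the simulator and tests) is
tab-separated with one observation per line::

    position  base  phred_quality  strand(+/-)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError
from .genotype_model import (BASE_TO_CODE, BASES, FORWARD, REVERSE, Genotype,
                             GenotypeCall, PileupColumn, classify_genotype)
from .qc_filters import FilterConfig

# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable, path) -> None:
    """Write pooled reads (pysam segments or objects with ``query_name``,
    forward-orientation sequence and qualities) as FASTQ for realignment."""
    with open(path, "w") as fh:
        for read in reads:
            seq = None
            if hasattr(read, "get_forward_sequence"):
                seq = read.get_forward_sequence()
                quals = read.get_forward_qualities()
            if seq is None:
                seq = read.query_sequence
                quals = read.query_qualities
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read.query_name}\n{seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# pileup text
# ---------------------------------------------------------------------------


def write_pileup(columns: Iterable[PileupColumn], path) -> None:
    with open(path, "w") as fh:
        for col in columns:
            for c, q, f in zip(col.base_codes, col.qualities, col.forward):
                strand = FORWARD if f else REVERSE
                q = int(q) if float(q).is_integer() else q
                fh.write(f"{col.position}\t{BASES[c]}\t{q}\t{strand}\n")


def read_pileup(path) -> list[PileupColumn]:
    """Parse the pileup text format into columns, sorted by position."""
    per_site: dict[int, list] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InvalidInputError(f"{path}:{ln}: expected 4 columns")
            pos, base, qual, strand = parts
            if base not in BASE_TO_CODE:
                raise InvalidInputError(f"{path}:{ln}: invalid base {base!r}")
            if strand not in (FORWARD, REVERSE):
                raise InvalidInputError(f"{path}:{ln}: invalid strand {strand!r}")
            per_site.setdefault(int(pos), []).append(
                (BASE_TO_CODE[base], float(qual), strand == FORWARD))
    columns = []
    for pos in sorted(per_site):
        codes, quals, fwd = zip(*per_site[pos])
        columns.append(PileupColumn(pos, codes, quals, fwd))
    return columns


# ---------------------------------------------------------------------------
# variant records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One called variant site for one sample, serialisable to TSV and VCF."""

    sample_id: str
    position: int
    ref: str
    genotype: Genotype
    fractions: tuple[tuple[str, float], ...]  # (allele, fraction), allele-sorted
    posterior: float
    log_likelihood: float
    classification: str
    filter_flags: frozenset[str] = frozenset()

    @classmethod
    def from_call(cls, sample_id: str, call: GenotypeCall,
                  ref_base: str) -> "VariantRecord":
        return cls(
            sample_id=sample_id,
            position=call.position,
            ref=ref_base,
            genotype=call.genotype,
            fractions=tuple(sorted(call.fractions.items())),
            posterior=call.posterior,
            log_likelihood=call.log_likelihood,
            classification=call.classification,
            filter_flags=frozenset(call.filter_flags),
        )

    @property
    def fraction_dict(self) -> dict[str, float]:
        return dict(self.fractions)

    @property
    def passes_filters(self) -> bool:
        return not self.filter_flags


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "position": r.position,
            "ref": r.ref,
            "genotype": str(r.genotype),
            "fractions": ";".join(f"{a}={f:.17g}" for a, f in r.fractions),
            "posterior": r.posterior,
            "log_likelihood": r.log_likelihood,
            "classification": r.classification,
            "filters": ",".join(sorted(r.filter_flags)) or "PASS",
        })
    return pd.DataFrame(rows, columns=[
        "sample_id", "position", "ref", "genotype", "fractions", "posterior",
        "log_likelihood", "classification", "filters"])


def write_variants_tsv(records: Sequence[VariantRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False,
                                     float_format="%.17g")


def read_variants_tsv(path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                        float_precision="round_trip")
    records = []
    for row in frame.itertuples(index=False):
        fractions = tuple(
            (part.split("=")[0], float(part.split("=")[1]))
            for part in str(row.fractions).split(";"))
        flags = (frozenset() if row.filters in ("PASS", "", None)
                 else frozenset(str(row.filters).split(",")))
        records.append(VariantRecord(
            sample_id=str(row.sample_id),
            position=int(row.position),
            ref=str(row.ref),
            genotype=Genotype.from_string(str(row.genotype)),
            fractions=fractions,
            posterior=float(row.posterior),
            log_likelihood=float(row.log_likelihood),
            classification=str(row.classification),
            filter_flags=flags,
        ))
    return records


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_FILTERS = {
    "raw_depth": "Raw site depth below threshold",
    "filtered_depth": "Quality-filtered site depth below threshold",
    "strand": "A called allele lacks dual-strand support",
    "maf": "Minor allele fraction below threshold",
    "median_depth": "Sample-level median depth below threshold",
}


def write_variants_vcf(records: Sequence[VariantRecord], path,
                       contig: str = "MT", contig_length: int = 16569) -> None:
    """Single-sample VCF 4.2 export; all records must share one sample id."""
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise InvalidInputError("VCF export handles one sample per file")
    sample = samples.pop() if samples else "SAMPLE"

    lines = [
        "##fileformat=VCFv4.2",
        "##source=mitovar",
        f"##contig=<ID={contig},length={contig_length}>",
    ]
    for name, desc in _VCF_FILTERS.items():
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    lines += [
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Call classification">',
        '##INFO=<ID=LL,Number=1,Type=Float,Description="Maximised genotype log-likelihood">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Estimated fraction of each ALT allele">',
        '##FORMAT=<ID=CPP,Number=1,Type=Float,Description="Posterior probability of the called genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for r in sorted(records, key=lambda r: r.position):
        fracs = r.fraction_dict
        alts = [a for a in r.genotype.alleles if a != r.ref]
        allele_order = [r.ref] + alts
        gt = "/".join(str(allele_order.index(a)) for a in r.genotype.alleles)
        alt_field = ",".join(alts) if alts else "."
        af_field = (",".join(f"{fracs[a]:.17g}" for a in alts) if alts else ".")
        filt = ";".join(sorted(r.filter_flags)) or "PASS"
        info = f"CLASS={r.classification};LL={r.log_likelihood:.17g}"
        lines.append(
            f"{contig}\t{r.position}\t.\t{r.ref}\t{alt_field}\t.\t{filt}\t"
            f"{info}\tGT:AF:CPP\t{gt}:{af_field}:{r.posterior:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_variants_vcf(path) -> list[VariantRecord]:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for var in vcf:
            data = var.samples[sample]
            alts = [a for a in (var.alts or ()) if a is not None]
            allele_order = [var.ref] + list(alts)
            gt_alleles = sorted({allele_order[i] for i in data["GT"]
                                 if i is not None})
            if not gt_alleles:
                gt_alleles = [var.ref]
            fracs = {}
            af = data.get("AF")
            if alts and af is not None:
                for a, f in zip(alts, np.atleast_1d(af)):
                    fracs[a] = float(f)
            total_alt = sum(fracs.values())
            if var.ref in gt_alleles:
                fracs[var.ref] = 1.0 - total_alt
            genotype = Genotype(tuple(gt_alleles))
            flags = frozenset(f for f in var.filter.keys() if f != "PASS")
            records.append(VariantRecord(
                sample_id=sample,
                position=var.pos,
                ref=var.ref,
                genotype=genotype,
                fractions=tuple(sorted(
                    (a, fracs.get(a, 0.0)) for a in genotype.alleles)),
                posterior=float(data["CPP"]),
                log_likelihood=float(var.info["LL"]),
                classification=str(var.info["CLASS"]),
                filter_flags=flags,
            ))
    return records


# ---------------------------------------------------------------------------
# BAM ingestion
# ---------------------------------------------------------------------------


def pileup_from_bam(bam, contig: str, start: int = 1, end: int | None = None,
                    cfg: FilterConfig | None = None) -> list[PileupColumn]:
    """Build pileup columns from an indexed BAM over a 1-based inclusive
    region of the mtDNA contig.

    Read-level filters follow the caller's policy: duplicates, secondary/
    supplementary records, QC failures and low mapping quality are excluded
    (the ``all`` stepper plus the mapping-quality cutoff).  Bases at indels
    or reference skips, and N calls, are excluded from the column.  The
    column's ``raw_depth`` is the observation count before base-quality
    filtering; base-quality filtering itself is left to
    :func:`mitovar.qc_filters.filter_column`.
    """
    cfg = cfg or FilterConfig()
    own = not isinstance(bam, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(bam)) if own else bam
    try:
        if contig not in af.references:
            raise InvalidInputError(f"contig {contig!r} absent from BAM header")
        if end is None:
            end = af.get_reference_length(contig)
        columns = []
        for pcol in af.pileup(contig, start - 1, end, truncate=True,
                              stepper="all", max_depth=1_000_000,
                              min_base_quality=0, ignore_overlaps=False,
                              min_mapping_quality=cfg.min_mapping_quality):
            codes, quals, fwd = [], [], []
            for pread in pcol.pileups:
                if pread.is_del or pread.is_refskip or pread.query_position is None:
                    continue
                aln = pread.alignment
                base = aln.query_sequence[pread.query_position].upper()
                if base not in BASE_TO_CODE:
                    continue
                codes.append(BASE_TO_CODE[base])
                quals.append(aln.query_qualities[pread.query_position])
                fwd.append(not aln.is_reverse)
            if codes:
                columns.append(PileupColumn(pcol.reference_pos + 1, codes,
                                            quals, fwd))
        return columns
    finally:
        if own:
            af.close()
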