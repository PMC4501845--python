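"""Double-alignment support for the circular mitochondrial genome.

Linear alignment against the standard 16,569-base mtDNA reference discards
reads spanning the artificial breakpoint between positions 16,569 and 1.  The
remedy implemented here is a second, "shifted" linear reference that starts at
original position 8,000 (by default) and ends at original position 7,999, so
the original breakpoint falls in the middle of the shifted sequence.  Reads
mapped to the mtDNA contig plus reads left unmapped in the primary alignment
are pooled and realigned (by an external aligner) against the shifted
reference; variants are then called on each alignment only inside the region
far from its own breakpoint, and the two call sets are merged:

* primary alignment owns original positions 4,001-12,000;
* shifted alignment owns 1-4,000 and 12,001-16,569.

The two regions are disjoint and cover the genome exactly once.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

RCRS_LENGTH = 16569
DEFAULT_SHIFT_ORIGIN = 8000
DEFAULT_PRIMARY_REGION = (4001, 12000)


@dataclass(frozen=True)
class CircularReferencePair:
    """The original linear reference plus its rotation, with the coordinate
    bijection and the region-ownership split between the two alignments.

    ``primary_region`` is a closed 1-based interval in original coordinates;
    everything outside it belongs to the shifted alignment.  For references
    that are not full-length mtDNA (toy sequences in tests), the default
    primary region is the middle half of the sequence.
    """

    original: str
    shift_origin: int = DEFAULT_SHIFT_ORIGIN
    primary_region: tuple[int, int] | None = None

    def __post_init__(self):
        L = len(self.original)
        if L < 2:
            raise InvalidInputError("reference must have at least 2 bases")
        if not 1 <= self.shift_origin <= L:
            raise InvalidInputError(
                f"shift origin {self.shift_origin} outside [1, {L}]"
            )
        region = self.primary_region
        if region is None:
            region = DEFAULT_PRIMARY_REGION if L == RCRS_LENGTH else (
                L // 4 + 1, (3 * L) // 4)
        lo, hi = region
        if not (1 <= lo <= hi <= L):
            raise InvalidInputError(
                f"primary region {region} invalid for reference of length {L}"
            )
        object.__setattr__(self, "primary_region", (int(lo), int(hi)))

    @property
    def length(self) -> int:
        return len(self.original)

    @property
    def shifted(self) -> str:
        """The rotated sequence, starting at ``shift_origin``."""
        o = self.shift_origin - 1
        return self.original[o:] + self.original[:o]

    @property
    def shifted_call_region(self) -> tuple[tuple[int, int], ...]:
        """Original-coordinate intervals owned by the shifted alignment."""
        lo, hi = self.primary_region
        parts = []
        if lo > 1:
            parts.append((1, lo - 1))
        if hi < self.length:
            parts.append((hi + 1, self.length))
        return tuple(parts)

    def owns_primary(self, position: int) -> bool:
        lo, hi = self.primary_region
        return lo <= position <= hi


def make_shifted_reference(original: str,
                           shift_origin: int = DEFAULT_SHIFT_ORIGIN,
                           primary_region: tuple[int, int] | None = None,
                           ) -> CircularReferencePair:
    """Rotate ``original`` so the shifted sequence starts at 1-based position
    ``shift_origin`` of the original."""
    return CircularReferencePair(original=str(original),
                                 shift_origin=int(shift_origin),
                                 primary_region=primary_region)


def shifted_to_original(position: int, pair: CircularReferencePair) -> int:
    """Map a 1-based shifted coordinate back to the original coordinate."""
    L = pair.length
    if not 1 <= position <= L:
        raise InvalidInputError(f"position {position} outside [1, {L}]")
    return (position - 1 + pair.shift_origin - 1) % L + 1


def original_to_shifted(position: int, pair: CircularReferencePair) -> int:
    """Inverse of :func:`shifted_to_original`."""
    L = pair.length
    if not 1 <= position <= L:
        raise InvalidInputError(f"position {position} outside [1, {L}]")
    return (position - pair.shift_origin) % L + 1


def pool_reads_for_realignment(reads: Iterable, mt_contigs=("MT", "chrM")) -> list:
    """Select the reads that must be realigned against the shifted reference:
    those mapped to the mtDNA contig plus all unmapped reads.

    Accepts an iterable of :class:`pysam.AlignedSegment` (or anything exposing
    ``is_unmapped``, ``is_secondary``, ``is_supplementary``, ``is_read2``,
    ``reference_name`` and ``query_name``).  Secondary and supplementary
    records are skipped; a read seen more than once (same name and mate) is
    pooled only once.
    """
    mt_contigs = set(mt_contigs)
    pooled, seen = [], set()
    for read in reads:
        if getattr(read, "is_secondary", False) or getattr(read, "is_supplementary", False):
            continue
        if not (read.is_unmapped or read.reference_name in mt_contigs):
            continue
        key = (read.query_name, bool(getattr(read, "is_read2", False)))
        if key in seen:
            continue
        seen.add(key)
        pooled.append(read)
    return pooled


def merge_variant_sets(primary_calls: Sequence, shifted_calls: Sequence,
                       pair: CircularReferencePair) -> list:
    """Combine the two per-alignment call sets into one genome-wide set.

    ``shifted_calls`` carry shifted coordinates and are remapped to original
    coordinates.  Each call is kept only if it falls inside the region its
    alignment owns; anything else is dropped with a logged warning.  The
    result is sorted by original coordinate with each position appearing at
    most once.
    """
    merged = {}

    def _keep(call, position):
        if position in merged:
            logger.warning("duplicate call at position %d dropped", position)
            return
        merged[position] = call

    for call in primary_calls:
        if pair.owns_primary(call.position):
            _keep(call, call.position)
        else:
            logger.warning(
                "primary-alignment call at %d outside owned region %s; dropped",
                call.position, pair.primary_region)
    for call in shifted_calls:
        orig = shifted_to_original(call.position, pair)
        if not pair.owns_primary(orig):
            _keep(dataclasses.replace(call, position=orig), orig)
        else:
            logger.warning(
                "shifted-alignment call at shifted %d (original %d) inside the "
                "primary-owned region; dropped", call.position, orig)
    return [merged[p] for p in sorted(merged)]
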