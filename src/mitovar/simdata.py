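"""Synthetic pileups, reads, cohorts and trios with known ground truth.

The generator mimics a whole-genome sequencing experiment at the read-pile
level: per-site depth is Poisson around a configurable mean (default 180x,
the mtDNA coverage scale of a low-pass WGS cohort), Phred base qualities are
drawn uniformly from [20, 30], and each read base is miscalled with
probability ``e = 10^(-Q/10)``, flipping to one of the three other bases
uniformly.  Strands are Bernoulli(1/2) per read.  Heteroplasmies are spiked
at chosen sites as true minor-allele fractions in (0, 0.5]; everything else
is pure reference plus sequencing error.

The same machinery drives the empirical calibration of the minor-allele-
fraction detection threshold: :func:`fdr_calibration` runs the full caller
and filter stack over simulated genomes and tabulates, for a grid of MAF
thresholds, the false discovery rate (false heteroplasmy calls over all
heteroplasmy calls) and the sensitivity over the spiked sites.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .genotype_model import (BASE_TO_CODE, BASES, HETEROPLASMY, PileupColumn)
from .qc_filters import FLAG_STRAND, FilterConfig

#: base composition of the human mitochondrial genome (A, C, G, T)
_MT_BASE_FREQS = (0.309, 0.313, 0.131, 0.247)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the simulator.

    ``heteroplasmy_spec`` pins specific spiked sites as ``(site, minor
    allele, fraction)`` triples; when ``None``, each simulated genome gets
    ``n_heteroplasmies`` sites drawn afresh with fractions uniform on
    ``fraction_range``.
    """

    mean_depth: float = 180.0
    quality_range: tuple[int, int] = (20, 30)  # uniform integer Phred
    n_sites: int = 2000
    n_individuals: int = 200
    n_heteroplasmies: int = 25
    fraction_range: tuple[float, float] = (0.05, 0.5)
    heteroplasmy_spec: tuple[tuple[int, str, float], ...] | None = None
    maternal_transmission: float = 0.3
    forward_strand_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise InvalidInputError("mean_depth must be positive")
        if self.n_sites < 1 or self.n_sites > 16569:
            raise InvalidInputError("n_sites must lie in [1, 16569]")
        lo, hi = self.fraction_range
        if not 0.0 < lo <= hi <= 0.5:
            raise InvalidInputError("spiked fractions must lie in (0, 0.5]")
        if self.heteroplasmy_spec is not None:
            for site, allele, f in self.heteroplasmy_spec:
                if allele not in BASE_TO_CODE:
                    raise InvalidInputError(f"invalid spiked allele {allele!r}")
                if not 0.0 < f <= 0.5:
                    raise InvalidInputError(
                        f"spiked fraction {f} outside (0, 0.5]")
        if not 0.0 <= self.maternal_transmission <= 1.0:
            raise InvalidInputError("maternal_transmission must be in [0, 1]")


def synthetic_reference(length: int = 16569, seed: int = 20150715) -> str:
    """A synthetic stand-in for the human mtDNA reference sequence.

    Random bases drawn at the base composition of human mtDNA; used wherever
    only sequence length and per-position base identity matter.  This is NOT
    the rCRS (which is not redistributed here); it is a synthetic fixture.
    """
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=_MT_BASE_FREQS)
    return "".join(BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# pileup simulation
# ---------------------------------------------------------------------------


@dataclass
class GenomeSim:
    """One simulated individual's pileups with ground truth."""

    columns: list[PileupColumn]
    ref_bases: list[str]
    truth: dict[int, tuple[str, float]]  # site -> (minor allele, fraction)


def _draw_truth(cfg: SimulationConfig, rng: np.random.Generator,
                ref_bases: Sequence[str]) -> dict[int, tuple[str, float]]:
    if cfg.heteroplasmy_spec is not None:
        truth = {}
        for site, allele, f in cfg.heteroplasmy_spec:
            if not 1 <= site <= cfg.n_sites:
                raise InvalidInputError(f"spiked site {site} outside the "
                                        f"simulated range [1, {cfg.n_sites}]")
            if allele == ref_bases[site - 1]:
                raise InvalidInputError(
                    f"spiked allele at site {site} equals the reference base")
            truth[site] = (allele, float(f))
        return truth
    n = min(cfg.n_heteroplasmies, cfg.n_sites)
    sites = rng.choice(cfg.n_sites, size=n, replace=False) + 1
    lo, hi = cfg.fraction_range
    fractions = rng.uniform(lo, hi, size=n)
    truth = {}
    for site, f in zip(sites, fractions):
        ref = ref_bases[site - 1]
        alts = [b for b in BASES if b != ref]
        truth[int(site)] = (alts[rng.integers(0, 3)], float(f))
    return truth


def _simulate_observations(cfg: SimulationConfig, rng: np.random.Generator,
                           n_reads: int, ref_code: np.ndarray,
                           minor_code: np.ndarray, minor_frac: np.ndarray):
    """Vectorised read-base simulation; all inputs are per-read arrays."""
    true_codes = ref_code.copy()
    is_minor = rng.random(n_reads) < minor_frac
    true_codes[is_minor] = minor_code[is_minor]
    qlo, qhi = cfg.quality_range
    quals = rng.integers(qlo, qhi + 1, size=n_reads)
    e = 10.0 ** (-quals / 10.0)
    flip = rng.random(n_reads) < e
    offsets = rng.integers(1, 4, size=n_reads).astype(np.uint8)
    obs = np.where(flip, (true_codes + offsets) % 4, true_codes).astype(np.uint8)
    forward = rng.random(n_reads) < cfg.forward_strand_prob
    return obs, quals, forward


def simulate_column(cfg: SimulationConfig, site: int,
                    rng: np.random.Generator | None = None,
                    reference: str | None = None):
    """Simulate a single pileup column; returns ``(column, truth)`` where
    ``truth`` is ``(minor allele, fraction)`` or ``None`` for a pure
    reference site.  The site's true mixture comes from
    ``cfg.heteroplasmy_spec``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if reference is None:
        reference = synthetic_reference(cfg.n_sites)
    if not 1 <= site <= len(reference):
        raise InvalidInputError(f"site {site} outside the reference")
    ref = reference[site - 1]
    spec = {s: (a, f) for s, a, f in (cfg.heteroplasmy_spec or ())}
    truth = spec.get(site)
    if truth is not None and truth[0] == ref:
        raise InvalidInputError(
            f"spiked allele at site {site} equals the reference base")
    depth = int(rng.poisson(cfg.mean_depth))
    minor_code = np.full(depth, BASE_TO_CODE[truth[0]] if truth else 0,
                         dtype=np.uint8)
    minor_frac = np.full(depth, truth[1] if truth else 0.0)
    obs, quals, forward = _simulate_observations(
        cfg, rng, depth, np.full(depth, BASE_TO_CODE[ref], dtype=np.uint8),
        minor_code, minor_frac)
    return PileupColumn(site, obs, quals, forward), truth


def simulate_genome(cfg: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    reference: str | None = None,
                    truth: Mapping[int, tuple[str, float]] | None = None,
                    ) -> GenomeSim:
    """Simulate pileup columns for every site of one individual."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if reference is None:
        reference = synthetic_reference(cfg.n_sites)
    ref_bases = list(reference[:cfg.n_sites])
    ref_codes = np.array([BASE_TO_CODE[b] for b in ref_bases], dtype=np.uint8)
    if truth is None:
        truth = _draw_truth(cfg, rng, ref_bases)

    depths = rng.poisson(cfg.mean_depth, size=cfg.n_sites)
    total = int(depths.sum())
    site_idx = np.repeat(np.arange(cfg.n_sites), depths)

    minor_code = np.zeros(cfg.n_sites, dtype=np.uint8)
    minor_frac = np.zeros(cfg.n_sites)
    for site, (allele, f) in truth.items():
        minor_code[site - 1] = BASE_TO_CODE[allele]
        minor_frac[site - 1] = f

    obs, quals, forward = _simulate_observations(
        cfg, rng, total, ref_codes[site_idx], minor_code[site_idx],
        minor_frac[site_idx])

    columns = []
    bounds = np.concatenate([[0], np.cumsum(depths)])
    for i in range(cfg.n_sites):
        lo, hi = bounds[i], bounds[i + 1]
        columns.append(PileupColumn(i + 1, obs[lo:hi], quals[lo:hi],
                                    forward[lo:hi]))
    return GenomeSim(columns=columns, ref_bases=ref_bases, truth=dict(truth))


# ---------------------------------------------------------------------------
# cohorts and trios
# ---------------------------------------------------------------------------


@dataclass
class IndividualSim:
    """Deferred per-individual simulation: truth is drawn eagerly, the pileup
    columns are generated on demand from the stored sub-seed."""

    sample_id: str
    cfg: SimulationConfig
    seed: int
    truth: dict[int, tuple[str, float]]
    reference: str

    def generate(self) -> GenomeSim:
        rng = np.random.default_rng(self.seed)
        return simulate_genome(self.cfg, rng, self.reference, truth=self.truth)


@dataclass
class TrioSim:
    child: IndividualSim
    mother: IndividualSim
    father: IndividualSim


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_cohort(cfg: SimulationConfig, trio_mode: bool = False,
                    reference: str | None = None):
    """Draw a cohort of independent individuals, or parent-child trios.

    In trio mode the mother's spiked heteroplasmies are transmitted to the
    child independently with probability ``cfg.maternal_transmission``
    (keeping the maternal fraction); the child then receives additional
    private heteroplasmies so its expected total matches
    ``cfg.n_heteroplasmies``.  Fathers are simulated independently.
    """
    rng = np.random.default_rng(cfg.seed)
    if reference is None:
        reference = synthetic_reference(cfg.n_sites)
    ref_bases = list(reference[:cfg.n_sites])

    def individual(sample_id, truth=None):
        if truth is None:
            truth = _draw_truth(cfg, rng, ref_bases)
        return IndividualSim(sample_id=sample_id, cfg=cfg,
                             seed=_sub_seed(rng), truth=truth,
                             reference=reference)

    if not trio_mode:
        return [individual(f"S{i:04d}") for i in range(cfg.n_individuals)]

    trios = []
    p = cfg.maternal_transmission
    for i in range(cfg.n_individuals):
        mother = individual(f"F{i:04d}-M")
        father = individual(f"F{i:04d}-F")
        inherited = {site: tf for site, tf in mother.truth.items()
                     if rng.random() < p}
        n_private = max(0, cfg.n_heteroplasmies - len(inherited))
        private_cfg = replace(cfg, n_heteroplasmies=n_private)
        private = _draw_truth(private_cfg, rng, ref_bases)
        child_truth = {**private, **inherited}
        trios.append(TrioSim(
            child=individual(f"F{i:04d}-C", truth=child_truth),
            mother=mother, father=father))
    return trios


# ---------------------------------------------------------------------------
# MAF-threshold FDR calibration
# ---------------------------------------------------------------------------

DEFAULT_MAF_GRID = (0.016, 0.03, 0.04, 0.05, 0.06)


def fdr_calibration(cfg: SimulationConfig,
                    thresholds: Sequence[float] = DEFAULT_MAF_GRID,
                    filter_cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Empirical FDR and sensitivity of the full caller over a MAF grid.

    Simulates ``cfg.n_individuals`` genomes, runs the complete caller with
    all depth/quality/strand filters, and sweeps the minor-allele-fraction
    threshold over ``thresholds`` (the caller itself runs once per genome;
    the MAF cut is applied to each call's estimated minor fraction, so the
    per-threshold passing sets are nested by construction).

    Returns a DataFrame with columns ``threshold``, ``n_calls``,
    ``n_false``, ``fdr`` (NaN where no calls pass) and ``sensitivity``.
    FDR counts a passing heteroplasmy call as false when its site was not
    spiked or the spiked allele is not among the called alleles.
    """
    from .pipeline import call_sample_columns  # local import: no cycle at runtime

    filter_cfg = filter_cfg or FilterConfig()
    sweep_cfg = replace_filter(filter_cfg, min_maf=0.0)
    thresholds = sorted(float(t) for t in thresholds)
    reference = synthetic_reference(cfg.n_sites)
    rng = np.random.default_rng(cfg.seed)

    n_calls = {t: 0 for t in thresholds}
    n_false = {t: 0 for t in thresholds}
    n_recovered = {t: 0 for t in thresholds}
    n_spiked = 0

    for _ in range(cfg.n_individuals):
        genome = simulate_genome(cfg, rng, reference)
        n_spiked += len(genome.truth)
        calls = call_sample_columns(genome.columns, genome.ref_bases,
                                    cfg=sweep_cfg)
        for call in calls:
            if call.classification != HETEROPLASMY:
                continue
            if FLAG_STRAND in call.filter_flags:
                continue
            maf = call.minor_allele_fraction
            spiked = genome.truth.get(call.position)
            is_true = (spiked is not None
                       and spiked[0] in call.genotype.alleles)
            for t in thresholds:
                if maf >= t - 1e-12:
                    n_calls[t] += 1
                    if is_true:
                        n_recovered[t] += 1
                    else:
                        n_false[t] += 1

    rows = []
    for t in thresholds:
        fdr = n_false[t] / n_calls[t] if n_calls[t] else float("nan")
        sens = n_recovered[t] / n_spiked if n_spiked else float("nan")
        rows.append({"threshold": t, "n_calls": n_calls[t],
                     "n_false": n_false[t], "fdr": fdr, "sensitivity": sens})
    return pd.DataFrame(rows)


def replace_filter(cfg: FilterConfig, **kwargs) -> FilterConfig:
    """A copy of a filter config with some thresholds replaced."""
    import dataclasses
    return dataclasses.replace(cfg, **kwargs)


# ---------------------------------------------------------------------------
# read-level simulation (for coverage and end-to-end alignment tests)
# ---------------------------------------------------------------------------


@dataclass
class SimulatedRead:
    """A read placed on the circular genome; ``start`` is 0-based on the
    original coordinate system and the read may wrap past the origin."""

    name: str
    start: int
    sequence: str
    quality: int
    reverse: bool

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wraps(self, genome_length: int) -> bool:
        return self.start + self.length > genome_length


def simulate_reads(reference: str, mean_depth: float, read_length: int = 100,
                   variants: Mapping[int, tuple[str, float]] | None = None,
                   rng: np.random.Generator | None = None,
                   base_quality: int = 30) -> list[SimulatedRead]:
    """Place reads uniformly on the circular genome (no sequencing error).

    ``variants`` maps 1-based positions to ``(allele, fraction)``; each read
    covering such a position carries the alternate allele with the given
    probability, emulating a heteroplasmic template pool.
    """
    rng = rng or np.random.default_rng(0)
    L = len(reference)
    if read_length > L:
        raise InvalidInputError("read length exceeds genome length")
    n_reads = int(round(mean_depth * L / read_length))
    doubled = reference + reference
    variants = dict(variants or {})
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, L))
        seq = list(doubled[start:start + read_length])
        for pos, (allele, fraction) in variants.items():
            offset = (pos - 1 - start) % L
            if offset < read_length and rng.random() < fraction:
                seq[offset] = allele
        reads.append(SimulatedRead(
            name=f"r{i:07d}", start=start, sequence="".join(seq),
            quality=base_quality, reverse=bool(rng.random() < 0.5)))
    return reads


def write_double_alignment(reads: Iterable[SimulatedRead], pair,
                           primary_path: str, shifted_path: str,
                           contig: str = "MT",
                           shifted_contig: str = "MT_shifted") -> None:
    """Emit the two coordinate-sorted, indexed BAMs an aligner would produce.

    The "alignment" is exact placement: a read is mapped on a linear
    reference iff it does not cross that reference's breakpoint, otherwise
    it is recorded as unmapped -- the situation the double-alignment
    strategy exists to repair.
    """
    import pysam

    reads = list(reads)
    L = pair.length

    def emit(path, name, to_coords):
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": name, "LN": L}]}
        mapped, unmapped = [], []
        for r in reads:
            start = to_coords(r.start)
            seg = pysam.AlignedSegment()
            seg.query_name = r.name
            seg.query_sequence = r.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                chr(r.quality + 33) * r.length)
            if start + r.length <= L:
                seg.reference_id = 0
                seg.reference_start = start
                seg.cigarstring = f"{r.length}M"
                seg.mapping_quality = 60
                seg.flag = 16 if r.reverse else 0
                mapped.append((start, seg))
            else:
                seg.flag = 4
                seg.mapping_quality = 0
                unmapped.append(seg)
        mapped.sort(key=lambda t: t[0])
        with pysam.AlignmentFile(path, "wb", header=header) as fh:
            for _, seg in mapped:
                fh.write(seg)
            for seg in unmapped:
                fh.write(seg)
        pysam.index(path)

    emit(primary_path, contig, lambda s: s)
    emit(shifted_path, shifted_contig,
         lambda s: (s - (pair.shift_origin - 1)) % L)


def simulate_coverage_ratio(rho: float, n_auto_reads: int = 10000,
                            read_length: int = 100,
                            auto_length: int = 200000,
                            mt_length: int = 16569,
                            rng: np.random.Generator | None = None):
    """Uniform read placement with an mtDNA:autosome read-density ratio of
    ``rho``; returns ``(mt_mean_depth, auto_mean_depth)`` measured from the
    realised per-base coverage (linear contigs, reads truncated at the ends).
    """
    rng = rng or np.random.default_rng(0)
    if rho <= 0:
        raise InvalidInputError("rho must be positive")
    n_mt_reads = int(rng.poisson(rho * n_auto_reads * mt_length / auto_length))

    def mean_cov(length, n_reads):
        starts = rng.integers(0, length, size=n_reads)
        ends = np.minimum(starts + read_length, length)
        delta = np.zeros(length + 1)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        return float(np.cumsum(delta[:-1]).mean())

    return mean_cov(mt_length, n_mt_reads), mean_cov(auto_length, n_auto_reads)
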