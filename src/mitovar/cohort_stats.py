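"""Cohort- and family-level summaries of mtDNA variant calls.

Covers the descriptive statistics a population study reports on top of the
per-sample caller output: how widely variants are shared across a cohort,
transition/transversion classification, parent-child sharing in trios (the
signature of maternal inheritance), and a Poisson loglinear model for the
age trend in per-individual heteroplasmy counts.

Variant identity throughout is ``(position, alternate allele)``; estimated
fractions are ignored for sharing purposes.  A heteroplasmy is "shared" with
a parent only if the parent carries a heteroplasmic call at the same site
with an overlapping alternate allele (homoplasmies likewise require a
homoplasmic match), so the two classifications are never mixed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateFitError, InvalidInputError
from .genotype_model import BASES, HETEROPLASMY, HOMOPLASMY

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

TRANSITION = "transition"
TRANSVERSION = "transversion"


def classify_substitution(ref: str, alt: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs
    transversion."""
    if ref not in BASES or alt not in BASES:
        raise InvalidInputError(f"invalid bases ({ref!r}, {alt!r})")
    if ref == alt:
        raise InvalidInputError("ref and alt must differ")
    same_class = ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)
    return TRANSITION if same_class else TRANSVERSION


@dataclass
class IndividualProfile:
    """One cohort member: metadata plus their variant calls.

    ``calls`` holds :class:`~mitovar.io.VariantRecord`-like objects (anything
    with ``position``, ``ref``, ``genotype`` and ``classification``).
    """

    sample_id: str
    age: float | None = None
    sex: str | None = None
    calls: list = field(default_factory=list)
    copy_number: float | None = None


def _variant_keys(record) -> set[tuple[int, str]]:
    """(position, alternate allele) keys of one call."""
    return {(record.position, a) for a in record.genotype.alleles
            if a != record.ref}


def _keys_by_class(profile, classification) -> set[tuple[int, str]]:
    keys = set()
    for rec in profile.calls:
        if rec.classification == classification:
            keys |= _variant_keys(rec)
    return keys


def _sites_by_class(profile, classification):
    """site -> set of alternate alleles, for calls of one classification."""
    sites: dict[int, set[str]] = {}
    for rec in profile.calls:
        if rec.classification == classification:
            alts = {a for a in rec.genotype.alleles if a != rec.ref}
            if alts:
                sites.setdefault(rec.position, set()).update(alts)
    return sites


# ---------------------------------------------------------------------------
# sharing spectrum
# ---------------------------------------------------------------------------


@dataclass
class SharingSpectrum:
    """Carrier counts per variant plus the cumulative sharing curve."""

    carrier_counts: dict[tuple[int, str], int]
    n_individuals: int

    @property
    def n_variants(self) -> int:
        return len(self.carrier_counts)

    def fraction_shared_by_more_than(self, k: int) -> float:
        """Fraction of distinct variants carried by more than ``k``
        individuals."""
        if not self.carrier_counts:
            return float("nan")
        counts = np.fromiter(self.carrier_counts.values(), dtype=int)
        return float(np.mean(counts > k))

    def cumulative_curve(self, ks: Sequence[int]) -> pd.Series:
        return pd.Series(
            [self.fraction_shared_by_more_than(k) for k in ks],
            index=pd.Index(ks, name="shared_by_more_than"),
            name="fraction_of_variants",
        )


def sharing_spectrum(cohort: Iterable[IndividualProfile],
                     classification: str | None = None) -> SharingSpectrum:
    """Count, for every (position, alternate allele), how many individuals
    carry it; optionally restricted to one classification."""
    counter: Counter = Counter()
    n = 0
    for profile in cohort:
        n += 1
        if classification is None:
            keys = (_keys_by_class(profile, HOMOPLASMY)
                    | _keys_by_class(profile, HETEROPLASMY))
        else:
            keys = _keys_by_class(profile, classification)
        counter.update(keys)
    return SharingSpectrum(dict(counter), n)


# ---------------------------------------------------------------------------
# trio sharing
# ---------------------------------------------------------------------------


@dataclass
class TrioSharingTable:
    """Counts of variant sites in children/mothers and how many are shared
    with each parent, for one classification."""

    classification: str
    n_families: int = 0
    child_variants: int = 0
    shared_with_mother: int = 0
    shared_with_father: int = 0
    mother_variants: int = 0
    mother_shared_with_father: int = 0

    def percentages(self) -> dict[str, float]:
        return {
            "child_mother": sharing_percentage(self.shared_with_mother,
                                               self.child_variants),
            "child_father": sharing_percentage(self.shared_with_father,
                                               self.child_variants),
            "mother_father": sharing_percentage(self.mother_shared_with_father,
                                                self.mother_variants),
        }


def sharing_percentage(shared: int, total: int) -> float:
    """``shared / total`` as a percentage rounded to 0.1, NaN when total is 0."""
    if shared > total:
        raise InvalidInputError(f"shared count {shared} exceeds total {total}")
    if total == 0:
        return float("nan")
    return round(100.0 * shared / total, 1)


def _shared_site_count(child_sites, parent_sites) -> int:
    return sum(1 for pos, alts in child_sites.items()
               if pos in parent_sites and alts & parent_sites[pos])


def trio_sharing(trios: Iterable[tuple]) -> dict[str, TrioSharingTable]:
    """Accumulate parent-child sharing counts over ``(child, mother, father)``
    profile triples, per classification.

    A child variant site is shared with a parent when the parent carries a
    call of the same classification at the same position with an overlapping
    alternate allele.  Incomplete trios are skipped with a warning.
    """
    tables = {c: TrioSharingTable(classification=c)
              for c in (HOMOPLASMY, HETEROPLASMY)}
    for trio in trios:
        child, mother, father = trio
        if child is None or mother is None or father is None:
            logger.warning("incomplete trio %s skipped",
                           tuple(getattr(m, "sample_id", None) for m in trio))
            continue
        for cls, table in tables.items():
            c_sites = _sites_by_class(child, cls)
            m_sites = _sites_by_class(mother, cls)
            f_sites = _sites_by_class(father, cls)
            table.n_families += 1
            table.child_variants += len(c_sites)
            table.shared_with_mother += _shared_site_count(c_sites, m_sites)
            table.shared_with_father += _shared_site_count(c_sites, f_sites)
            table.mother_variants += len(m_sites)
            table.mother_shared_with_father += _shared_site_count(m_sites, f_sites)
    return tables


# ---------------------------------------------------------------------------
# Poisson loglinear age trend
# ---------------------------------------------------------------------------


@dataclass
class AgeTrendFit:
    """Poisson loglinear fit of per-individual variant counts on age:
    ``E[count] = exp(intercept + slope * age)``."""

    intercept: float
    slope: float
    slope_pvalue: float
    result: object  # statsmodels GLMResults

    def expected_counts(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        return np.exp(self.intercept + self.slope * ages)


def fit_age_trend(counts, ages) -> AgeTrendFit:
    """Fit the Poisson loglinear model by IRLS and test the age slope.

    ``counts`` are non-negative integers (variants per individual), ``ages``
    in years.  Returns the fitted coefficients, the Wald p-value for the age
    slope, and a callable expected-count curve.  Raises
    :class:`DegenerateFitError` when the slope is unidentifiable (all counts
    zero or constant ages).
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if counts.shape != ages.shape or counts.ndim != 1:
        raise InvalidInputError("counts and ages must be 1-D of equal length")
    if counts.size < 10:
        raise InvalidInputError("need at least 10 individuals")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise InvalidInputError("counts must be non-negative integers")
    if np.all(counts == 0):
        raise DegenerateFitError("all counts are zero")
    if np.ptp(ages) == 0:
        raise DegenerateFitError("ages are constant; slope unidentifiable")
    X = sm.add_constant(ages)
    result = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    return AgeTrendFit(
        intercept=float(result.params[0]),
        slope=float(result.params[1]),
        slope_pvalue=float(result.pvalues[1]),
        result=result,
    )
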