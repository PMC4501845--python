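"""Tests for cohort summaries: Ts/Tv, sharing spectra, trio sharing and the
Poisson loglinear age trend."""

import itertools

import numpy as np
import pytest

from mitovar import (
    Genotype,
    IndividualProfile,
    classify_substitution,
    fit_age_trend,
    sharing_spectrum,
    trio_sharing,
)
from mitovar.cohort_stats import sharing_percentage
from mitovar.errors import DegenerateFitError, InvalidInputError
from mitovar.io import VariantRecord


def record(sample, position, ref, genotype, classification,
           fractions=None) -> VariantRecord:
    g = Genotype.from_string(genotype)
    if fractions is None:
        fractions = tuple((a, 1.0 / g.n_alleles) for a in g.alleles)
    return VariantRecord(sample_id=sample, position=position, ref=ref,
                         genotype=g, fractions=tuple(fractions),
                         posterior=1.0, log_likelihood=0.0,
                         classification=classification)


class TestSubstitutionClasses:
    def test_purine_purine_is_transition(self):
        assert classify_substitution("A", "G") == "transition"
        assert classify_substitution("C", "T") == "transition"

    def test_purine_pyrimidine_is_transversion(self):
        assert classify_substitution("A", "C") == "transversion"

    def test_four_transitions_eight_transversions(self):
        kinds = [classify_substitution(r, a)
                 for r, a in itertools.permutations("ACGT", 2)]
        assert kinds.count("transition") == 4
        assert kinds.count("transversion") == 8

    def test_identity_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_substitution("A", "A")


class TestSharingSpectrum:
    def test_counts_carriers_per_variant(self):
        cohort = [
            IndividualProfile(f"s{i}", calls=[
                record(f"s{i}", 100, "A", "G", "homoplasmy")])
            for i in range(3)
        ]
        cohort.append(IndividualProfile("s3", calls=[
            record("s3", 200, "C", "T", "homoplasmy")]))
        spec = sharing_spectrum(cohort)
        assert spec.carrier_counts == {(100, "G"): 3, (200, "T"): 1}
        assert spec.fraction_shared_by_more_than(1) == pytest.approx(0.5)
        assert spec.fraction_shared_by_more_than(2) == pytest.approx(0.5)
        assert spec.fraction_shared_by_more_than(3) == pytest.approx(0.0)

    def test_empty_cohort(self):
        spec = sharing_spectrum([])
        assert spec.carrier_counts == {} and spec.n_variants == 0

    def test_cumulative_curve_is_non_increasing(self, rng):
        cohort = []
        for i in range(50):
            calls = [record(f"s{i}", int(p), "A", "G", "homoplasmy")
                     for p in rng.choice(200, size=10, replace=False) + 1]
            cohort.append(IndividualProfile(f"s{i}", calls=calls))
        curve = sharing_spectrum(cohort).cumulative_curve(range(0, 50, 5))
        assert (np.diff(curve.values) <= 1e-12).all()

    def test_generator_round_trip(self, rng):
        """A cohort built with known carrier counts reproduces them."""
        target = {(10, "G"): 7, (20, "T"): 3, (30, "C"): 1}
        cohort = [IndividualProfile(f"s{i}") for i in range(10)]
        for (pos, alt), n in target.items():
            for prof in cohort[:n]:
                prof.calls.append(record(prof.sample_id, pos, "A", alt,
                                         "homoplasmy"))
        assert sharing_spectrum(cohort).carrier_counts == target


class TestTrioSharing:
    def _trio(self, child_calls, mother_calls, father_calls):
        return (IndividualProfile("c", calls=child_calls),
                IndividualProfile("m", calls=mother_calls),
                IndividualProfile("f", calls=father_calls))

    def test_reported_percentages_recompute_from_counts(self):
        assert sharing_percentage(7238, 7273) == 99.5
        assert sharing_percentage(2940, 7273) == 40.4
        assert sharing_percentage(66, 207) == 31.9
        assert sharing_percentage(2937, 7266) == 40.4
        assert sharing_percentage(1, 207) == 0.5  # rounded to 0.1%

    def test_shared_requires_same_classification(self):
        """A maternal homoplasmy does not count as sharing the child's
        heteroplasmy at the same site."""
        trio = self._trio(
            [record("c", 100, "A", "A/G", "heteroplasmy")],
            [record("m", 100, "A", "G", "homoplasmy")],
            [])
        tables = trio_sharing([trio])
        het = tables["heteroplasmy"]
        assert het.child_variants == 1 and het.shared_with_mother == 0

    def test_overlapping_allele_required(self):
        trio = self._trio(
            [record("c", 100, "A", "A/G", "heteroplasmy"),
             record("c", 200, "A", "A/C", "heteroplasmy")],
            [record("m", 100, "A", "A/G", "heteroplasmy"),
             record("m", 200, "A", "A/T", "heteroplasmy")],
            [])
        het = trio_sharing([trio])["heteroplasmy"]
        assert het.child_variants == 2
        assert het.shared_with_mother == 1  # site 200 alleles do not overlap

    def test_counts_accumulate_over_families(self):
        t1 = self._trio([record("c", 1, "A", "G", "homoplasmy")],
                        [record("m", 1, "A", "G", "homoplasmy")],
                        [record("f", 1, "A", "G", "homoplasmy")])
        t2 = self._trio([record("c", 2, "C", "T", "homoplasmy")],
                        [], [])
        hom = trio_sharing([t1, t2])["homoplasmy"]
        assert hom.n_families == 2
        assert hom.child_variants == 2
        assert hom.shared_with_mother == 1
        assert hom.shared_with_father == 1
        assert hom.mother_variants == 1
        assert hom.mother_shared_with_father == 1
        assert hom.percentages()["child_mother"] == 50.0

    def test_childless_variants_contribute_nothing(self):
        trio = self._trio([], [record("m", 5, "A", "G", "homoplasmy")], [])
        hom = trio_sharing([trio])["homoplasmy"]
        assert hom.child_variants == 0 and hom.shared_with_mother == 0

    def test_incomplete_trio_skipped(self):
        trio = (IndividualProfile("c"), None, IndividualProfile("f"))
        tables = trio_sharing([trio])
        assert tables["homoplasmy"].n_families == 0


class TestAgeTrend:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(2000)
        n = 2000
        ages = rng.uniform(20, 90, n)
        counts = rng.poisson(np.exp(np.log(0.3) + 0.012 * ages))
        fit = fit_age_trend(counts, ages)
        assert fit.slope == pytest.approx(0.012, abs=0.004)
        assert fit.intercept == pytest.approx(np.log(0.3), abs=0.3)

    def test_expected_curve_matches_coefficients(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 90, 500)
        counts = rng.poisson(np.exp(-1.0 + 0.01 * ages))
        fit = fit_age_trend(counts, ages)
        grid = np.array([20.0, 55.0, 90.0])
        np.testing.assert_allclose(
            fit.expected_counts(grid),
            np.exp(fit.intercept + fit.slope * grid))

    def test_all_zero_counts_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_age_trend(np.zeros(100), np.linspace(20, 90, 100))

    def test_constant_ages_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_age_trend(np.ones(100), np.full(100, 50.0))

    def test_too_few_individuals_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_age_trend([1, 2, 0], [20, 30, 40])

    def test_rmse_shrinks_with_sample_size(self):
        """Slope RMSE over replicates decreases roughly as 1/sqrt(n)."""
        rng = np.random.default_rng(77)
        rmse = {}
        for n in (200, 2000, 20000):
            errs = []
            for _ in range(8):
                ages = rng.uniform(20, 90, n)
                counts = rng.poisson(np.exp(np.log(0.3) + 0.012 * ages))
                errs.append(fit_age_trend(counts, ages).slope - 0.012)
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[2000] < rmse[200]
        assert rmse[20000] < rmse[2000]
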