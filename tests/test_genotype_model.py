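"""Unit and property tests for the likelihood-based genotype model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitovar import (
    AlleleFractions,
    Genotype,
    ObservedBase,
    PileupColumn,
    call_genotype,
    enumerate_genotypes,
    genotype_log_likelihood,
    genotype_posteriors,
    mle_allele_fractions,
    phred_to_error,
    read_likelihood,
)
from mitovar.errors import ContractError, InvalidInputError, NoDataError
from mitovar.genotype_model import _em_mle, _likelihood_matrix

from conftest import make_column, random_biallelic_column


# ---------------------------------------------------------------------------
# genotype space
# ---------------------------------------------------------------------------


class TestGenotypeSpace:
    def test_fifteen_genotypes_four_single_eleven_multi(self):
        gts = enumerate_genotypes()
        assert len(gts) == 15
        singles = [g for g in gts if g.n_alleles == 1]
        assert {g.alleles[0] for g in singles} == {"A", "C", "G", "T"}
        assert sum(1 for g in gts if g.is_heteroplasmic) == 11

    def test_enumeration_is_deterministic_and_unique(self):
        assert enumerate_genotypes() == enumerate_genotypes()
        assert len(set(enumerate_genotypes())) == 15

    def test_alleles_canonicalised_alphabetically(self):
        assert Genotype(("T", "A")).alleles == ("A", "T")
        assert str(Genotype.from_string("T/A")) == "A/T"

    @pytest.mark.parametrize("bad", [(), ("A",) * 5, ("A", "A"), ("X",)])
    def test_invalid_allele_sets_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            Genotype(bad)


class TestAlleleFractions:
    def test_must_sum_to_one(self):
        with pytest.raises(ContractError):
            AlleleFractions({"A": 0.6, "C": 0.5})

    def test_minimum_is_minor_fraction(self):
        assert AlleleFractions({"A": 0.9, "C": 0.1}).minimum == pytest.approx(0.1)


# ---------------------------------------------------------------------------
# Phred mapping
# ---------------------------------------------------------------------------


class TestPhred:
    @pytest.mark.parametrize("q,e", [(20, 0.01), (0, 1.0), (30, 0.001),
                                     (10, 0.1)])
    def test_known_values(self, q, e):
        assert phred_to_error(q) == pytest.approx(e, rel=1e-12)

    def test_negative_score_rejected(self):
        with pytest.raises(InvalidInputError):
            phred_to_error(-1)

    def test_array_input(self):
        np.testing.assert_allclose(phred_to_error(np.array([20.0, 30.0])),
                                   [0.01, 0.001])


# ---------------------------------------------------------------------------
# per-read likelihood
# ---------------------------------------------------------------------------


class TestReadLikelihood:
    def test_single_allele_match_and_mismatch(self):
        a = ObservedBase("A", 20)
        c = ObservedBase("C", 20)
        assert read_likelihood(a, Genotype("A")) == pytest.approx(0.99)
        assert read_likelihood(c, Genotype("A")) == pytest.approx(0.01 / 3)

    def test_error_free_mixture_returns_fraction(self):
        obs = ObservedBase("A", math.inf)  # e = 0
        f = AlleleFractions({"A": 0.6, "C": 0.4})
        assert read_likelihood(obs, Genotype("AC"), f) == pytest.approx(0.6)

    def test_mismatched_fractions_rejected(self):
        obs = ObservedBase("A", 20)
        with pytest.raises(ContractError):
            read_likelihood(obs, Genotype("AC"),
                            AlleleFractions({"A": 0.5, "G": 0.5}))

    @given(st.integers(0, 60), st.integers(0, 14),
           st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_total_probability_over_four_bases_is_one(self, q, gi, raw):
        """For any quality and genotype, the four possible observed bases'
        likelihoods form a probability distribution."""
        g = enumerate_genotypes()[gi]
        w = np.array(raw[: g.n_alleles])
        w /= w.sum()
        f = AlleleFractions(dict(zip(g.alleles, w))) if g.is_heteroplasmic else None
        total = sum(read_likelihood(ObservedBase(b, q), g, f)
                    for b in "ACGT")
        assert total == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# column log-likelihood
# ---------------------------------------------------------------------------


class TestGenotypeLogLikelihood:
    def test_hand_multiplied_three_read_column(self):
        # two A reads and one C read, all at Q20: 0.99 * 0.99 * (0.01/3)
        col = make_column(1, {"A": 2, "C": 1})
        expected = math.log(0.99**2 * 0.01 / 3)
        assert genotype_log_likelihood(col, Genotype("A")) == pytest.approx(
            expected, abs=1e-12)

    def test_degenerate_mixture_equals_single_allele(self):
        col = make_column(1, {"A": 5, "C": 3})
        ll_single = genotype_log_likelihood(col, Genotype("A"))
        ll_mixture = genotype_log_likelihood(
            col, Genotype("AC"), AlleleFractions({"A": 1.0, "C": 0.0}))
        assert ll_mixture == pytest.approx(ll_single, abs=1e-12)

    def test_order_invariance(self, rng):
        col, *_ = random_biallelic_column(rng, mixed_quality=True)
        perm = rng.permutation(len(col))
        shuffled = PileupColumn(col.position, col.base_codes[perm],
                                col.qualities[perm], col.forward[perm])
        for g in (Genotype("A"), Genotype("C")):
            assert genotype_log_likelihood(col, g) == pytest.approx(
                genotype_log_likelihood(shuffled, g), abs=1e-9)

    def test_empty_column_raises(self):
        col = PileupColumn(1, [], [], [])
        with pytest.raises(NoDataError):
            genotype_log_likelihood(col, Genotype("A"))


# ---------------------------------------------------------------------------
# allele-fraction MLE
# ---------------------------------------------------------------------------


def constant_error_biallelic_mle(n1, n2, e):
    """Closed-form MLE for a biallelic column with constant error rate:
    derived by setting the score of n1*log(f*q + e/3) + n2*log((1-f)*q + e/3)
    to zero with q = 1 - 4e/3, then clipping to [0, 1]."""
    p = n1 / (n1 + n2)
    f = (p * (1 - 2 * e / 3) - e / 3) / (1 - 4 * e / 3)
    return min(1.0, max(0.0, f))


def grid_search_biallelic(col, g1, g2, step=1e-4):
    """Dense 1-D grid maximisation of the biallelic log-likelihood."""
    M = _likelihood_matrix(col, [  # allele order (g1, g2)
        "ACGT".index(g1), "ACGT".index(g2)])
    grid = np.arange(0.0, 1.0 + step / 2, step)
    with np.errstate(divide="ignore"):
        ll = np.log(np.outer(M[:, 0], grid)
                    + np.outer(M[:, 1], 1.0 - grid)).sum(axis=0)
    return float(grid[np.argmax(ll)])


class TestAlleleFractionMLE:
    def test_error_free_mle_is_empirical_fraction(self):
        col = make_column(1, {"A": 60, "C": 40}, quality=math.inf)
        f, _ = mle_allele_fractions(col, Genotype("AC"))
        assert f["A"] == pytest.approx(0.6, abs=1e-6)

    def test_matches_constant_error_closed_form(self):
        col = make_column(1, {"A": 60, "C": 40}, quality=20)
        f, _ = mle_allele_fractions(col, Genotype("AC"))
        expected = constant_error_biallelic_mle(60, 40, 0.01)
        assert expected == pytest.approx(0.6007, abs=5e-5)  # sanity on oracle
        assert f["A"] == pytest.approx(expected, abs=1e-4)

    def test_boundary_maximum_is_exact(self):
        col = make_column(1, {"A": 100}, quality=20)
        f, ll = mle_allele_fractions(col, Genotype("AC"))
        assert f["A"] == 1.0 and f["C"] == 0.0
        assert ll == pytest.approx(100 * math.log(0.99))

    def test_single_allele_genotype_rejected(self):
        col = make_column(1, {"A": 10})
        with pytest.raises(ContractError):
            mle_allele_fractions(col, Genotype("A"))

    def test_matches_dense_grid_on_mixed_quality_columns(self, rng):
        for _ in range(20):
            col, b1, b2 = random_biallelic_column(rng, mixed_quality=True)
            f, _ = mle_allele_fractions(col, Genotype((b1, b2)))
            f_grid = grid_search_biallelic(col, b1, b2)
            assert f[b1] == pytest.approx(f_grid, abs=1e-4)

    def test_em_fast_path_agrees_with_simplex(self, rng):
        """The caller's EM solver and the public Nelder-Mead optimiser find
        the same maximum."""
        for _ in range(20):
            col, b1, b2 = random_biallelic_column(rng, mixed_quality=True)
            g = Genotype((b1, b2))
            f_nm, ll_nm = mle_allele_fractions(col, g)
            M = _likelihood_matrix(col, g.codes)
            f_em, ll_em = _em_mle(M)
            assert abs(f_em[0] - f_nm[g.alleles[0]]) < 1e-5
            assert ll_em == pytest.approx(ll_nm, abs=1e-7)

    def test_triallelic_recovery_error_free(self):
        col = make_column(1, {"A": 50, "C": 30, "G": 20}, quality=math.inf)
        f, _ = mle_allele_fractions(col, Genotype("ACG"))
        assert f["A"] == pytest.approx(0.5, abs=1e-4)
        assert f["C"] == pytest.approx(0.3, abs=1e-4)
        assert f["G"] == pytest.approx(0.2, abs=1e-4)


# ---------------------------------------------------------------------------
# posteriors
# ---------------------------------------------------------------------------


def _simplex_grid(k, step):
    """Grid points of the k-simplex (includes all boundary faces)."""
    if k == 1:
        yield np.ones(1)
        return
    grid = np.arange(0.0, 1.0 + step / 2, step)
    if k == 2:
        for f1 in grid:
            yield np.array([f1, 1.0 - f1])
    elif k == 3:
        for f1 in grid:
            for f2 in grid:
                if f1 + f2 <= 1.0 + 1e-12:
                    yield np.array([f1, f2, 1.0 - f1 - f2])
    else:
        for f1 in grid:
            for f2 in grid:
                for f3 in grid:
                    if f1 + f2 + f3 <= 1.0 + 1e-12:
                        yield np.array([f1, f2, f3, 1.0 - f1 - f2 - f3])


def oracle_posteriors(col, prior=None):
    """Independent posterior oracle: maximised likelihood per genotype by
    dense grid search over the fraction simplex, then normalise.  Grids are
    fine for 1-2 alleles and coarser for 3-4; the boundary faces (where the
    nested-genotype ties live) lie on every grid exactly."""
    genotypes = enumerate_genotypes()
    prior = prior or {g: 1 / 15 for g in genotypes}
    steps = {1: 1.0, 2: 1e-4, 3: 0.004, 4: 0.02}
    lls = []
    for g in genotypes:
        M = _likelihood_matrix(col, g.codes)
        F = np.array(list(_simplex_grid(g.n_alleles, steps[g.n_alleles])))
        best = -np.inf
        for lo in range(0, len(F), 20000):
            with np.errstate(divide="ignore"):
                chunk = np.log(M @ F[lo:lo + 20000].T).sum(axis=0)
            best = max(best, float(chunk.max()))
        lls.append(best)
    lls = np.array(lls)
    w = np.array([prior[g] for g in genotypes]) * np.exp(lls - lls.max())
    return dict(zip(genotypes, w / w.sum()))


class TestPosteriors:
    def test_normalisation(self, rng):
        col, *_ = random_biallelic_column(rng)
        post = genotype_posteriors(col)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_order_invariance(self, rng):
        col, *_ = random_biallelic_column(rng, mixed_quality=True)
        perm = rng.permutation(len(col))
        shuffled = PileupColumn(col.position, col.base_codes[perm],
                                col.qualities[perm], col.forward[perm])
        p1, p2 = genotype_posteriors(col), genotype_posteriors(shuffled)
        for g in enumerate_genotypes():
            assert p1[g] == pytest.approx(p2[g], abs=1e-9)

    def test_degenerate_prior_pins_posterior(self):
        col = make_column(1, {"A": 50})
        prior = {Genotype("C"): 1.0}
        post = genotype_posteriors(col, prior)
        assert post[Genotype("C")] == pytest.approx(1.0)

    def test_invalid_prior_rejected(self):
        col = make_column(1, {"A": 5, "C": 5, "G": 5, "T": 5})
        with pytest.raises(ContractError):
            genotype_posteriors(col, {Genotype("A"): 0.5})

    def test_monomorphic_column_posterior_splits_over_supersets(self):
        """With maximised likelihoods, every genotype containing the observed
        base ties at the simplex boundary, so under a flat prior a pure
        column gives the single-allele genotype posterior exactly 1/8 (the
        other seven A-containing genotypes absorb the rest).  Verified
        against an independent grid-search oracle."""
        col = make_column(1, {"A": 100}, quality=30)
        post = genotype_posteriors(col)
        assert post[Genotype("A")] == pytest.approx(1 / 8, abs=1e-9)
        oracle = oracle_posteriors(col)
        assert post[Genotype("A")] == pytest.approx(oracle[Genotype("A")],
                                                    abs=1e-3)

    def test_matches_grid_oracle_on_biallelic_column(self, rng):
        col, b1, b2 = random_biallelic_column(rng, depth=80)
        post = genotype_posteriors(col)
        oracle = oracle_posteriors(col)
        # tolerance covers the oracle's own O(N * step^2) grid-resolution bias
        for g in enumerate_genotypes():
            assert post[g] == pytest.approx(oracle[g], abs=5e-3)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


class TestCallGenotype:
    def test_pure_reference_column(self):
        call = call_genotype(make_column(1, {"A": 60}), "A")
        assert str(call.genotype) == "A"
        assert call.classification == "reference"

    def test_pure_alternate_column_is_homoplasmy(self):
        call = call_genotype(make_column(1, {"G": 60}), "A")
        assert str(call.genotype) == "G"
        assert call.classification == "homoplasmy"

    def test_balanced_mixture_is_heteroplasmy(self):
        call = call_genotype(make_column(1, {"A": 60, "C": 40}), "A")
        assert str(call.genotype) == "A/C"
        assert call.classification == "heteroplasmy"
        assert call.fractions["A"] == pytest.approx(0.6, abs=0.01)

    def test_spiked_fraction_recovered_at_high_depth(self):
        """A 10% heteroplasmy at depth 2000/Q30 is called as the two-allele
        genotype with the spiked fraction recovered within 0.02."""
        rng = np.random.default_rng(20150306)
        depth = 2000
        truth = rng.random(depth) < 0.10
        e = 0.001
        flip = rng.random(depth) < e
        bases = np.where(truth, 1, 0)  # A=0, C=1
        bases = np.where(flip, (bases + rng.integers(1, 4, depth)) % 4, bases)
        col = PileupColumn(1, bases.astype(np.uint8), np.full(depth, 30.0),
                           rng.random(depth) < 0.5)
        call = call_genotype(col, "A")
        assert str(call.genotype) == "A/C"
        assert call.fractions["C"] == pytest.approx(0.10, abs=0.02)

    def test_single_error_read_does_not_add_allele(self):
        """One stray Q20 base among hundreds must not expand the called
        genotype (model-complexity allowance)."""
        call = call_genotype(make_column(1, {"A": 300, "C": 60, "G": 1}), "A")
        assert str(call.genotype) == "A/C"

    def test_prior_mass_one_forces_genotype(self):
        call = call_genotype(make_column(1, {"A": 50}), "A",
                             prior={Genotype("C"): 1.0})
        assert str(call.genotype) == "C"
        assert call.classification == "homoplasmy"
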