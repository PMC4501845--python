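"""Likelihood-based genotype model for mitochondrial variant calling.

At a single mtDNA position an individual's genotype ``G`` is an unordered set
of 1-4 distinct bases out of {A, C, G, T} -- 15 possibilities in total.  A
single-allele genotype that differs from the reference base is a homoplasmy;
any multi-allele genotype is a heteroplasmy, with per-individual allele
fractions ``f`` describing the mixture of mtDNA molecules in the cell.

Each aligned read base ``r_i`` with Phred quality ``Q_i`` is treated as an
independent draw from the cell's pool of mtDNA molecules, miscalled with
probability ``e_i = 10^(-Q_i/10)`` (uniformly to each of the three other
bases).  The per-read likelihood is therefore a mixture

    P(r_i | G, f) = sum_a  f_a * [ (1 - e_i)  if r_i == a  else  e_i / 3 ]

and the genotype likelihood is the product over the reads covering the
position.  For multi-allele genotypes the fractions are free parameters and
the genotype likelihood is maximised over the probability simplex
(Nelder-Mead on softmax coordinates, see :func:`mle_allele_fractions`).
Posterior probabilities over the 15 genotypes combine the maximised
likelihoods with a genotype prior (uniform by default) and the call goes to
the highest-scoring genotype.

Because genotypes are nested (any superset's maximised likelihood is at least
as large as its subset's, with equality on the boundary of the simplex), a
raw argmax systematically prefers genotypes padded with alleles supported by
one or two sequencing-error reads.  Genotype selection therefore charges each
additional allele fraction a model-complexity allowance of ``0.5 * ln N``
(the BIC rate for one extra free parameter); exact ties are broken toward
fewer alleles, then toward genotypes containing the reference base.  The
reported posterior itself is the plain normalised product of maximised
likelihood and prior.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import ContractError, InvalidInputError, NoDataError, OptimizationError

BASES = ("A", "C", "G", "T")
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

#: classification labels used throughout the package
REFERENCE = "reference"
HOMOPLASMY = "homoplasmy"
HETEROPLASMY = "heteroplasmy"

FORWARD = "+"
REVERSE = "-"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Genotype:
    """An unordered set of 1-4 distinct bases, stored in alphabetical order.

    ``Genotype("AC")`` and ``Genotype(("C", "A"))`` both denote the A/C
    heteroplasmic genotype.
    """

    alleles: tuple[str, ...]

    def __post_init__(self):
        alleles = tuple(self.alleles)
        if not 1 <= len(alleles) <= 4:
            raise InvalidInputError(
                f"a genotype has 1-4 alleles, got {len(alleles)}"
            )
        if len(set(alleles)) != len(alleles):
            raise InvalidInputError(f"duplicate alleles in genotype: {alleles}")
        for a in alleles:
            if a not in BASE_TO_CODE:
                raise InvalidInputError(f"invalid allele {a!r}; expected one of {BASES}")
        object.__setattr__(self, "alleles", tuple(sorted(alleles)))

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def is_heteroplasmic(self) -> bool:
        return len(self.alleles) > 1

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(BASE_TO_CODE[a] for a in self.alleles)

    def __str__(self) -> str:
        return "/".join(self.alleles)

    @classmethod
    def from_string(cls, text: str) -> "Genotype":
        """Parse ``"A"``, ``"A/C"`` or ``"AC"``."""
        return cls(tuple(text.split("/")) if "/" in text else tuple(text))


@dataclass(frozen=True)
class AlleleFractions:
    """Per-allele fractions of a genotype; must sum to 1 (within 1e-9)."""

    fractions: Mapping[str, float]

    def __post_init__(self):
        fractions = dict(self.fractions)
        if not fractions:
            raise ContractError("empty allele fractions")
        for a, f in fractions.items():
            if a not in BASE_TO_CODE:
                raise ContractError(f"invalid allele {a!r} in fractions")
            if not -1e-12 <= f <= 1 + 1e-12:
                raise ContractError(f"fraction for {a} outside [0,1]: {f}")
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ContractError(f"allele fractions sum to {total}, expected 1")
        object.__setattr__(self, "fractions", fractions)

    @classmethod
    def uniform(cls, genotype: Genotype) -> "AlleleFractions":
        k = genotype.n_alleles
        return cls({a: 1.0 / k for a in genotype.alleles})

    def matches(self, genotype: Genotype) -> bool:
        return set(self.fractions) == set(genotype.alleles)

    def as_array(self, genotype: Genotype) -> np.ndarray:
        return np.array([self.fractions[a] for a in genotype.alleles], dtype=float)

    @property
    def minimum(self) -> float:
        """The smallest fraction -- the minor allele fraction of the genotype."""
        return min(self.fractions.values())

    def __getitem__(self, allele: str) -> float:
        return self.fractions[allele]

    def items(self):
        return self.fractions.items()


@dataclass(frozen=True)
class ObservedBase:
    """One aligned read base: the called base, its Phred quality and strand."""

    base: str
    quality: float
    strand: str = FORWARD

    def __post_init__(self):
        if self.base not in BASE_TO_CODE:
            raise InvalidInputError(f"invalid base {self.base!r}")
        if self.quality < 0:
            raise InvalidInputError(f"negative Phred score {self.quality}")
        if self.strand not in (FORWARD, REVERSE):
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def error_rate(self) -> float:
        return float(phred_to_error(self.quality))


class PileupColumn:
    """All observed bases covering one reference position.

    Array-backed for speed: bases are stored as integer codes (A=0, C=1, G=2,
    T=3) alongside parallel quality and strand arrays.  ``raw_depth`` is the
    read count before any base-quality filtering and is carried through
    filtering steps unchanged.
    """

    __slots__ = ("position", "base_codes", "qualities", "forward", "raw_depth")

    def __init__(self, position, base_codes, qualities, forward, raw_depth=None):
        if position < 1:
            raise InvalidInputError(f"positions are 1-based; got {position}")
        self.position = int(position)
        self.base_codes = np.asarray(base_codes, dtype=np.uint8)
        self.qualities = np.asarray(qualities, dtype=float)
        self.forward = np.asarray(forward, dtype=bool)
        if not (len(self.base_codes) == len(self.qualities) == len(self.forward)):
            raise InvalidInputError("base/quality/strand arrays differ in length")
        if np.any(self.qualities < 0):
            raise InvalidInputError("negative Phred score in column")
        n = len(self.base_codes)
        self.raw_depth = n if raw_depth is None else int(raw_depth)
        if self.raw_depth < n:
            raise InvalidInputError(
                f"raw_depth {self.raw_depth} smaller than observation count {n}"
            )

    @classmethod
    def from_observations(cls, position, observations: Iterable[ObservedBase],
                          raw_depth=None) -> "PileupColumn":
        obs = list(observations)
        return cls(
            position,
            [BASE_TO_CODE[o.base] for o in obs],
            [o.quality for o in obs],
            [o.strand == FORWARD for o in obs],
            raw_depth=raw_depth,
        )

    def __len__(self) -> int:
        return len(self.base_codes)

    @property
    def depth(self) -> int:
        return len(self.base_codes)

    @property
    def observations(self) -> tuple[ObservedBase, ...]:
        return tuple(
            ObservedBase(BASES[c], q, FORWARD if f else REVERSE)
            for c, q, f in zip(self.base_codes, self.qualities, self.forward)
        )

    @property
    def error_rates(self) -> np.ndarray:
        return 10.0 ** (-self.qualities / 10.0)

    def base_counts(self) -> np.ndarray:
        """Counts of A, C, G, T among the observations."""
        return np.bincount(self.base_codes, minlength=4)[:4]

    def observed_bases(self) -> tuple[str, ...]:
        """The distinct bases present, alphabetically."""
        return tuple(BASES[c] for c in sorted(set(int(c) for c in self.base_codes)))

    def __repr__(self):
        return (f"PileupColumn(position={self.position}, depth={self.depth}, "
                f"raw_depth={self.raw_depth})")


@dataclass
class GenotypeCall:
    """The per-position output of the caller."""

    position: int
    genotype: Genotype
    fractions: AlleleFractions
    log_likelihood: float
    posterior: float
    classification: str
    filter_flags: set[str] = field(default_factory=set)

    @property
    def passes_filters(self) -> bool:
        return not self.filter_flags

    @property
    def minor_allele_fraction(self) -> float:
        return self.fractions.minimum


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def enumerate_genotypes() -> tuple[Genotype, ...]:
    """All 15 genotypes: subsets of {A,C,G,T} of size 1-4, smallest first,
    alphabetical within a size."""
    return tuple(
        Genotype(combo)
        for k in range(1, 5)
        for combo in itertools.combinations(BASES, k)
    )


#: number of free allele-fraction parameters per genotype, in enumeration order
_EXTRA_PARAMS = np.array([len(c) - 1 for k in range(1, 5)
                          for c in itertools.combinations(BASES, k)])


def phred_to_error(quality):
    """Phred score -> error probability, ``e = 10^(-Q/10)``.

    Accepts scalars or arrays; raises :class:`InvalidInputError` on negative
    scores.
    """
    q = np.asarray(quality, dtype=float)
    if np.any(q < 0):
        raise InvalidInputError("Phred scores must be non-negative")
    e = 10.0 ** (-q / 10.0)
    return float(e) if np.isscalar(quality) or q.ndim == 0 else e


def classify_genotype(genotype: Genotype, ref_base: str) -> str:
    """Reference / homoplasmy / heteroplasmy classification of a genotype
    relative to the reference base at the position."""
    if ref_base not in BASE_TO_CODE:
        raise InvalidInputError(f"invalid reference base {ref_base!r}")
    if genotype.is_heteroplasmic:
        return HETEROPLASMY
    return REFERENCE if genotype.alleles[0] == ref_base else HOMOPLASMY


def read_likelihood(obs: ObservedBase, genotype: Genotype,
                    fractions: AlleleFractions | None = None) -> float:
    """P(observed base | genotype, fractions) for a single read.

    For single-allele genotypes the fraction is trivially 1 and ``fractions``
    may be omitted.
    """
    if genotype.is_heteroplasmic:
        if fractions is None or not fractions.matches(genotype):
            raise ContractError(
                f"fractions {fractions} do not match genotype {genotype}"
            )
    e = obs.error_rate
    if not genotype.is_heteroplasmic:
        return 1.0 - e if obs.base == genotype.alleles[0] else e / 3.0
    return float(
        sum(
            fractions[a] * ((1.0 - e) if obs.base == a else e / 3.0)
            for a in genotype.alleles
        )
    )


def _likelihood_matrix(column: PileupColumn, codes: Sequence[int]) -> np.ndarray:
    """(N, k) matrix of per-read, per-allele likelihood terms."""
    e = column.error_rates[:, None]
    match = column.base_codes[:, None] == np.asarray(codes, dtype=np.uint8)[None, :]
    return np.where(match, 1.0 - e, e / 3.0)


def genotype_log_likelihood(column: PileupColumn, genotype: Genotype,
                            fractions: AlleleFractions | None = None) -> float:
    """Log of the product of per-read likelihoods over the column.

    Computed in log space; may be ``-inf`` when an observation is impossible
    under the genotype (e.g. error rate exactly 0 and a non-genotype base).
    """
    if len(column) == 0:
        raise NoDataError(f"no observations at position {column.position}")
    if genotype.is_heteroplasmic:
        if fractions is None or not fractions.matches(genotype):
            raise ContractError(
                f"fractions {fractions} do not match genotype {genotype}"
            )
        f = fractions.as_array(genotype)
    else:
        f = np.ones(1)
    M = _likelihood_matrix(column, genotype.codes)
    p = M @ f
    with np.errstate(divide="ignore"):
        return float(np.log(p).sum())


# ---------------------------------------------------------------------------
# allele-fraction maximisation
# ---------------------------------------------------------------------------


def _softmax_full(z: np.ndarray) -> np.ndarray:
    """Map k-1 free coordinates to a point of the k-simplex (last coord 0)."""
    x = np.append(z, 0.0)
    x -= x.max()
    ex = np.exp(x)
    return ex / ex.sum()


def _candidate_log_likelihood(M: np.ndarray, f: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        return float(np.log(M @ f).sum())


def mle_allele_fractions(column: PileupColumn, genotype: Genotype, *,
                         fatol: float = 1e-10, xatol: float = 1e-8,
                         maxiter: int = 4000):
    """Maximise the genotype log-likelihood over the allele-fraction simplex.

    Runs Nelder-Mead on softmax-reparameterised coordinates from two starts
    (uniform fractions and empirical base-count fractions), then compares the
    best interior point against the simplex vertices and a "snapped" copy with
    near-zero components removed, so boundary optima are returned exactly
    (e.g. ``f = 1.0`` for a column with no minor-allele reads).

    Returns ``(AlleleFractions, log_likelihood)``.  Raises
    :class:`OptimizationError` (carrying the best point found) if no restart
    converges.
    """
    k = genotype.n_alleles
    if k < 2:
        raise ContractError("mle_allele_fractions needs a multi-allele genotype")
    if len(column) == 0:
        raise NoDataError(f"no observations at position {column.position}")

    M = _likelihood_matrix(column, genotype.codes)
    # Reads that no allele of the genotype can explain (possible when e == 0)
    # contribute log 0 regardless of f; exclude them from the search and add
    # the -inf back at the end.
    explainable = M.max(axis=1) > 0.0
    impossible = not bool(explainable.all())
    Mx = M[explainable]
    if Mx.shape[0] == 0:
        # every observation is impossible; any fraction vector is "optimal"
        return AlleleFractions.uniform(genotype), float("-inf")

    def nll(z):
        p = Mx @ _softmax_full(z)
        if np.any(p <= 0.0):
            return np.inf
        return -float(np.log(p).sum())

    counts = np.array([np.sum(column.base_codes == c) for c in genotype.codes],
                      dtype=float)
    empirical = (counts + 0.5) / (counts + 0.5).sum()
    starts = [np.zeros(k - 1), np.log(empirical[:-1] / empirical[-1])]

    best = None
    converged = False
    for z0 in starts:
        res = minimize(nll, z0, method="Nelder-Mead",
                       options={"fatol": fatol, "xatol": xatol,
                                "maxiter": maxiter * k, "maxfev": maxiter * k})
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    f_interior = _softmax_full(best.x)
    candidates = []
    for j in range(k):  # simplex vertices: exact boundary optima
        v = np.zeros(k)
        v[j] = 1.0
        candidates.append(v)
    snapped = np.where(f_interior < 1e-7, 0.0, f_interior)
    if snapped.sum() > 0:
        candidates.append(snapped / snapped.sum())
    candidates.append(f_interior)

    best_f, best_ll = None, -np.inf
    for f in candidates:
        ll = _candidate_log_likelihood(Mx, f)
        if ll > best_ll:
            best_f, best_ll = f, ll

    fractions = AlleleFractions(dict(zip(genotype.alleles, map(float, best_f))))
    if impossible:
        best_ll = float("-inf")
    if not converged:
        raise OptimizationError(
            f"allele-fraction maximisation did not converge for {genotype} at "
            f"position {column.position}",
            best_fractions=fractions, best_log_likelihood=float(best_ll),
        )
    return fractions, float(best_ll)


def _em_mle(M: np.ndarray, f0: np.ndarray | None = None, *,
            tol: float = 1e-10, maxiter: int = 2000):
    """Fast mixture-fraction MLE by expectation-maximisation.

    Used on the caller's hot path; agrees with :func:`mle_allele_fractions`
    to well below 1e-5 (asserted in the test suite).  Monotone in the
    log-likelihood, with the same exact-boundary snapping as the simplex
    route.
    """
    n, k = M.shape
    explainable = M.max(axis=1) > 0.0
    impossible = not bool(explainable.all())
    Mx = M[explainable]
    if Mx.shape[0] == 0:
        return np.full(k, 1.0 / k), float("-inf")
    if f0 is None:
        f = np.full(k, 1.0 / k)
    else:
        f = np.clip(np.asarray(f0, dtype=float), 1e-6, None)
        f /= f.sum()
    MxT = np.ascontiguousarray(Mx.T)
    n_eff = Mx.shape[0]
    prev = -np.inf
    for _ in range(maxiter):
        p = Mx @ f
        ll = float(np.log(p).sum())
        if ll - prev <= tol:
            prev = ll
            break
        prev = ll
        f = f * (MxT @ (1.0 / p)) / n_eff
        f /= f.sum()
    ll = prev
    # exact boundary candidates
    best_f, best_ll = f, ll
    for j in range(k):
        with np.errstate(divide="ignore"):
            llv = float(np.log(Mx[:, j]).sum())
        if llv >= best_ll:
            v = np.zeros(k)
            v[j] = 1.0
            best_f, best_ll = v, llv
    if impossible:
        best_ll = float("-inf")
    return best_f, best_ll


# ---------------------------------------------------------------------------
# posteriors and calling
# ---------------------------------------------------------------------------


def _prior_vector(prior) -> np.ndarray:
    genotypes = enumerate_genotypes()
    if prior is None:
        return np.full(len(genotypes), 1.0 / len(genotypes))
    p = np.array([float(prior.get(g, 0.0)) for g in genotypes])
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ContractError("prior is not a probability distribution over the "
                            "15 genotypes")
    return p


@lru_cache(maxsize=32)
def _subset_plan(observed: tuple[str, ...]):
    """For a set of observed bases, the mapping from each of the 15 genotypes
    to the subset of its alleles actually observed (possibly empty)."""
    observed_set = set(observed)
    plan = []
    for g in enumerate_genotypes():
        plan.append(tuple(a for a in g.alleles if a in observed_set))
    subsets = sorted(
        {s for s in plan if s},
        key=lambda s: (len(s), s),
    )
    return tuple(plan), tuple(subsets)


def _max_log_likelihoods(column: PileupColumn, *, use_em: bool = True):
    """Maximised log-likelihood (and fractions) for every genotype.

    Genotype alleles with no observed support take fraction 0 at the optimum
    (adding mass to an unseen allele can only lower every read's likelihood
    when error rates are below 3/4), so each genotype's maximum is computed on
    the subset of its alleles that were actually observed.  Columns containing
    reads with error rate >= 0.75 (Phred < ~1.25) fall back to the full
    per-genotype optimisation.
    """
    if len(column) == 0:
        raise NoDataError(f"no observations at position {column.position}")
    genotypes = enumerate_genotypes()
    errors = column.error_rates
    if np.any(errors >= 0.75):  # reduction argument no longer valid
        lls, fracs = [], {}
        for g in genotypes:
            if g.is_heteroplasmic:
                f, ll = mle_allele_fractions(column, g)
            else:
                f = AlleleFractions({g.alleles[0]: 1.0})
                ll = genotype_log_likelihood(column, g)
            lls.append(ll)
            fracs[g] = f
        return np.array(lls), fracs.__getitem__

    with np.errstate(divide="ignore"):
        ll_err = float(np.log(errors / 3.0).sum())  # every read a miscall
    observed = column.observed_bases()
    plan, subsets = _subset_plan(observed)

    memo_ll: dict[tuple[str, ...], float] = {}
    memo_f: dict[tuple[str, ...], np.ndarray] = {}
    counts = column.base_counts()
    for s in subsets:
        codes = [BASE_TO_CODE[a] for a in s]
        M = _likelihood_matrix(column, codes)
        if len(s) == 1:
            memo_f[s] = np.ones(1)
            with np.errstate(divide="ignore"):
                memo_ll[s] = float(np.log(M[:, 0]).sum())
        else:
            f0 = counts[codes].astype(float) + 0.5
            if use_em:
                f, ll = _em_mle(M, f0 / f0.sum())
            else:
                g = Genotype(s)
                af, ll = mle_allele_fractions(column, g)
                f = af.as_array(g)
            memo_f[s] = f
            memo_ll[s] = ll

    lls = np.empty(len(genotypes))
    plan_by_genotype = {}
    for i, (g, s) in enumerate(zip(genotypes, plan)):
        lls[i] = memo_ll[s] if s else ll_err
        plan_by_genotype[g] = s

    def fractions_for(g: Genotype) -> AlleleFractions:
        s = plan_by_genotype[g]
        if not s:
            return AlleleFractions.uniform(g)
        fs = dict.fromkeys(g.alleles, 0.0)
        fs.update(zip(s, map(float, memo_f[s])))
        return AlleleFractions(fs)

    return lls, fractions_for


def genotype_posteriors(column: PileupColumn, prior=None) -> dict[Genotype, float]:
    """Posterior over the 15 genotypes: maximised likelihood x prior,
    normalised with log-sum-exp.

    ``prior`` maps :class:`Genotype` to probability; ``None`` means uniform.
    """
    with np.errstate(divide="ignore"):
        log_prior = np.log(np.maximum(_prior_vector(prior), 0.0))
    lls, _ = _max_log_likelihoods(column)
    with np.errstate(invalid="ignore"):
        logpost = lls + log_prior
    logpost[np.isnan(logpost)] = -np.inf  # -inf + -inf
    if np.all(np.isneginf(logpost)):
        raise ContractError("posterior undefined: prior excludes every genotype "
                            "with non-zero likelihood")
    post = np.exp(logpost - logsumexp(logpost))
    return dict(zip(enumerate_genotypes(), map(float, post)))


def call_genotype(column: PileupColumn, ref_base: str, prior=None, *,
                  parsimony: bool = True) -> GenotypeCall:
    """Assign the best-supported genotype to a pileup column.

    Selection maximises ``log posterior - 0.5 * ln(N) * (extra fractions)``
    when ``parsimony`` is on (the default); near-exact ties go to fewer
    alleles, then to genotypes containing the reference base, then
    alphabetical.  The reported ``posterior`` is the unpenalised normalised
    posterior of the selected genotype.
    """
    if ref_base not in BASE_TO_CODE:
        raise InvalidInputError(f"invalid reference base {ref_base!r}")
    genotypes = enumerate_genotypes()
    with np.errstate(divide="ignore"):
        log_prior = np.log(np.maximum(_prior_vector(prior), 0.0))
    lls, fractions_for = _max_log_likelihoods(column)
    with np.errstate(invalid="ignore"):
        logpost = lls + log_prior
    logpost[np.isnan(logpost)] = -np.inf
    if np.all(np.isneginf(logpost)):
        raise ContractError("prior excludes every genotype with non-zero "
                            "likelihood")
    m = logpost.max()
    post = np.exp(logpost - m)
    post /= post.sum()

    n = len(column)
    if parsimony and n > 0:
        penalty = 0.5 * math.log(n)
        score = logpost - penalty * _EXTRA_PARAMS
    else:
        score = logpost

    top = score.max()
    tied = [i for i in range(len(genotypes)) if score[i] >= top - 1e-9]
    tied.sort(key=lambda i: (genotypes[i].n_alleles,
                             0 if ref_base in genotypes[i].alleles else 1,
                             genotypes[i].alleles))
    i = tied[0]
    g = genotypes[i]
    return GenotypeCall(
        position=column.position,
        genotype=g,
        fractions=fractions_for(g),
        log_likelihood=float(lls[i]),
        posterior=float(post[i]),
        classification=classify_genotype(g, ref_base),
    )


def call_columns(columns: Sequence[PileupColumn], ref_bases: Sequence[str],
                 prior=None, *, parsimony: bool = True) -> list[GenotypeCall]:
    """Call a batch of columns (one reference base per column).

    Semantics identical to :func:`call_genotype` applied per column; exists so
    pipelines have a single entry point for whole-genome calling.
    """
    if len(columns) != len(ref_bases):
        raise ContractError("columns and ref_bases differ in length")
    return [call_genotype(col, rb, prior, parsimony=parsimony)
            for col, rb in zip(columns, ref_bases)]
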