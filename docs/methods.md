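# Methods

## Genotype model

At one mtDNA position for one individual, the genotype *G* is an unordered
set of 1–4 distinct bases (15 possible values). Reads are modelled as
independent draws from the cell's mtDNA pool: a read whose template carries
base *a* reports *a* with probability 1 − *e* and each other base with
probability *e*/3, where *e* = 10^(−Q/10) from the recalibrated Phred
quality. For multi-allele genotypes the per-read likelihood is the mixture
Σₐ fₐ·[(1−e) if r=a else e/3] over the genotype's allele fractions *f* (for
three and four alleles this is the same mixture with more components); the
column likelihood is the product over reads, computed in log space since
depths can exceed 10⁴.

Assumptions worth stating: reads are independent given the template pool
(overlapping mate pairs are counted twice — see limitations), quality
scores are treated as exact error rates, errors are strand-symmetric and
uniform over the three wrong bases, and alignment errors/NUMT contamination
are handled upstream by the mapping-quality and uniqueness filters, not by
the model.

### Allele-fraction maximisation

`mle_allele_fractions` maximises the column log-likelihood over the
(k−1)-dimensional probability simplex using Nelder–Mead on
softmax-reparameterised coordinates, restarting from (i) uniform fractions
and (ii) empirical base-count fractions (pseudocount ½). Convergence
tolerances are 1e-10 on the log-likelihood and 1e-8 on the coordinates;
with two restarts this resolves the fraction to well below 1e-4 (asserted
against a constant-error closed form and a 1e-4 grid search in the test
suite). Because softmax coordinates cannot reach the boundary, the
optimiser's result is compared against all simplex vertices and against a
copy with components < 1e-7 snapped to zero; boundary optima (e.g. f = 1
when a minor allele has no reads) are therefore returned exactly. Reads
that no allele of the genotype can explain (possible only at e = 0)
contribute log 0: they are excluded from the search and the reported
log-likelihood is −inf, which is the honest value.

The calling hot path solves the same maximisation by
expectation-maximisation (multiplicative updates, monotone in the
log-likelihood, same boundary snapping, tolerance 1e-10). The suite asserts
EM–Nelder-Mead agreement below 1e-5; EM exists purely because genome-scale
calling touches ~10⁵–10⁶ columns and the simplex search is 5–10× slower per
column.

### Posteriors, selection and the nested-model issue

The posterior over the 15 genotypes is the normalised product of maximised
likelihood and prior (uniform by default; any distribution over the 15
genotypes can be supplied). One structural fact dominates the design here:
genotypes are nested, so a superset's maximised likelihood is never smaller
than its subset's — with equality exactly on the boundary of the fraction
simplex. Two consequences:

1. *Posterior mass spreads over supersets.* For a pure 100-read A column,
   all eight A-containing genotypes tie (the supersets at fₓ = 0), so under
   a flat prior the posterior of {A} is exactly 1/8. The reported posterior
   is kept honest rather than aggregated.
2. *Raw argmax over-calls alleles.* Any allele with even one supporting
   error read raises the maximised likelihood slightly, so a raw argmax
   pads the call with spurious alleles at almost every deep column, and the
   minimum-fraction MAF filter would then discard genuinely heteroplasmic
   sites. Genotype selection therefore maximises the log-posterior minus a
   model-complexity allowance of ½·ln N per additional allele fraction (the
   BIC rate for one extra free parameter, N = quality-filtered depth).
   Exact ties are still broken toward fewer alleles, then toward genotypes
   containing the reference base (parsimony). An allele needs roughly
   ln N/(2·ln(p/(e/3))) supporting reads to enter a call — about 2–4 reads
   at the depths this package targets — which matches the intent of the
   downstream dual-strand and MAF filters. Selection without the allowance
   is available via ``parsimony=False``.

Classification is definitional: a single-allele call equal to the reference
base is *reference* (not counted as a variant), a differing single-allele
call is a *homoplasmy*, any multi-allele call is a *heteroplasmy*. No
posterior cutoff is applied when emitting calls; retention is decided by
the filters.

## Circular genome handling

The standard linear mtDNA reference breaks the circle between positions
16,569 and 1, losing reads that span the junction. The package constructs a
shifted reference beginning at original position 8,000 (configurable), so
the shifted sequence runs 8,000…16,569,1…7,999. The coordinate maps are the
rotation bijections; shifted→original is ((pos−1 + origin−1) mod L) + 1.
Reads mapped to the mtDNA contig plus all unmapped reads are pooled
(deduplicated by read name and mate) and re-aligned externally — alignment
itself is deliberately out of scope, any short-read aligner works. Variants
are accepted from the primary alignment only at positions 4,001–12,000 and
from the shifted alignment only at 1–4,000 and 12,001–16,569: the two
closed regions are disjoint, cover the genome exactly once, and keep every
call ≥ 4,000 bases from the breakpoint of the alignment that produced it.
Calls landing outside their alignment's owned region are dropped with a
logged warning.

## Filters

Defaults (all overridable via `FilterConfig`, a plain key = value file, or
CLI flags):

| level | rule | default |
|---|---|---|
| read | uniquely mtDNA-mapped, non-duplicate, MQ ≥ | 20 |
| base | Phred quality ≥ (error ≤ 1%) | 20 |
| sample | median raw depth over all 16,569 positions, strict > | 100 |
| site | raw depth ≥ / quality-filtered depth ≥ | 40 / 10 |
| heteroplasmy | every called allele on both strands | on |
| heteroplasmy | minor allele fraction ≥ | 0.04 |

Interpretation choices: the sample median is taken over raw depths with
zeros included; the MAF of a 3/4-allele call is its minimum estimated
fraction; the strand requirement is evaluated on quality-filtered
observations; thresholds are inclusive (raw depth 40, filtered depth 10,
MAF 0.04 all pass). Filters are idempotent, and raising the MAF threshold
never adds a passing call, so threshold sweeps produce nested call sets.

## Copy number

Copies per cell = 2 × mean mtDNA depth / mean autosomal depth. Means are
arithmetic over per-base depth with zero-coverage positions included;
autosomes 1–22 only (sex chromosomes and decoys excluded); positions whose
reference base is N are excluded because assembly gaps cannot be covered
and would deflate the autosomal mean. Depth is counted from the same read
class the caller uses (non-duplicate primary alignments passing the
mapping-quality cutoff) for internal consistency. Further mappability
masking is possible by passing explicit regions but is off by default.

## Cohort statistics

Variant identity for sharing is (position, alternate allele); estimated
fractions are ignored. Sharing between relatives is per classification: a
child heteroplasmy counts as shared only if the parent has a heteroplasmic
call at the same site with an overlapping alternate allele, and likewise
for homoplasmies — the same thresholds are applied to parents and
children. Substitutions are transitions iff {ref,alt} is {A,G} or {C,T}.
The age trend in per-individual heteroplasmy counts is a Poisson loglinear
model, E[count] = exp(β₀ + β₁·age), fitted by IRLS (statsmodels GLM) with a
Wald test on β₁; degenerate inputs (all-zero counts, constant ages) raise
rather than returning a meaningless fit. Selection of unrelated individuals
for the age model is accepted as an input list — pedigree handling is out
of scope.

## Simulator and the MAF-threshold calibration

The simulator mimics sequencing at the pileup level: per-site depth
Poisson(180) by default, Phred qualities uniform integers on [20, 30]
(mean error ≈ 0.4%), per-read miscalls to a uniform wrong base with
probability e, strands Bernoulli(½). Heteroplasmies are spiked as true
minor fractions; by default each simulated genome receives 25 spiked sites
with fractions uniform on [0.05, 0.50]. Output is byte-identical given the
seed. What it does **not** emulate: alignment artifacts (soft-clips,
chimeras, NUMT cross-mapping), overdispersed or miscalibrated quality
strings, strand-correlated errors, and overlapping mate pairs — so passing
tests demonstrate correctness of the calling machinery under its own error
model, not robustness to real-data artifacts. A quality-overdispersion
stress mode can be emulated by widening `quality_range` downward.

`fdr_calibration` runs the full caller and filter stack over simulated
genomes once with the MAF filter released, then sweeps the threshold over
{1.6, 3, 4, 5, 6}% on each call's estimated minor fraction (the passing
sets are nested by construction). FDR is the fraction of passing
heteroplasmy calls whose site was not spiked (or whose spiked allele is not
among the called alleles); sensitivity is the fraction of spiked sites
recovered. Under the default conditions the FDR at the 4% threshold is
effectively zero and rises steeply below ~2%, supporting 4% as a
conservative detection floor; both curves are monotone in the threshold.

Problem sizes: the calibration defaults to 200 genomes × 2,000 sites
(~4×10⁵ columns, a few minutes on one CPU). Site count scales the number of
error-only columns linearly and leaves the per-column rates unchanged, so
2,000 sites per genome gives the same FDR/sensitivity estimates as the full
16,569 at a quarter of the compute; both knobs are plain config fields.

## Numerical choices and degenerate inputs

All likelihoods in log space; −inf is propagated, never clamped. Posterior
normalisation by log-sum-exp. Ties in selection are resolved within 1e-9 of
the maximum. MAF threshold comparisons allow 1e-12 slack so exact-boundary
fractions (0.04) pass. Empty columns raise `NoDataError`; fraction/genotype
mismatches and invalid priors raise `ContractError`; the optimiser raises
`OptimizationError` carrying its best point if no restart converges.
Columns containing reads with error rate ≥ 0.75 (Phred < 1.25) disable the
observed-allele reduction shortcut and fall back to full per-genotype
optimisation.

## Known limitations

* SNV-only: indels and rearrangements are not called; bases at indels,
  clips and reference skips are excluded from columns.
* Overlapping mate pairs are double-counted (no fragment-level collapsing),
  slightly overstating effective depth for short fragments.
* The bundled reference is a synthetic stand-in with human-mtDNA base
  composition; analyses of real data should supply the actual mtDNA
  reference FASTA (only sequence length and per-position bases are used).
* Single-sample calling only; no joint calling across a cohort and no
  linkage-aware modelling.
* The posterior of a called genotype is diluted by boundary-tied supersets
  (see above); treat it as a relative score, not a calibrated probability.
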