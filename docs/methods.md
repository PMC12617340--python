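# Methods

## Model and assumptions

Two haploid allopatric populations adapt from new mutations in the
strong-selection, weak-mutation regime (`Ns >> 1`, `N*mu << 1`): evolution is
a sequence of single-mutation fixations, and the probability that a given
beneficial mutation is the next to fix is proportional to its selection
coefficient.  Loci are biallelic (ancestral/derived).  Individually
beneficial derived alleles at two different loci can be negatively epistatic
when first combined in a hybrid — a Dobzhansky–Muller incompatibility (DMI)
of severity `t` (hybrid fitness `1 - t`).  Severity parameterises how bad the
incompatibility is, not whether it forms; all formation probabilities here
are invariant to `t`, and the simulator asserts that invariance.

Environmental heterogeneity enters through a single symmetry parameter
`phi = s_foreign / s_home` in [0, 1]: each locus has a home environment where
it confers `s_i`, and confers `phi * s_i` in the other.  `phi = 1` is the
mutation-order endpoint (identical selection), `phi = 0` the fully ecological
endpoint (alleles neutral abroad).  Because substitution rates are
proportional to `s`, `phi` also rescales the foreign population's rate of
adaptive substitution — at `phi = 0.4` the foreign lineage substitutes at
~40% of the home rate, which the simulator reproduces.

### Closed forms

* Two-locus, identical environments: `P_U = 2 s_A s_B / (s_A + s_B)^2`.
* Two-locus with symmetry `phi`:
  `P_E = s_A s_B (1 + phi^2) / ((s_A + phi s_B)(phi s_A + s_B))`.
  This is the unique reading of the flattened published expression that
  simultaneously (i) reduces to `P_U` at `phi = 1` and (ii) equals 1 at
  `phi = 0`; it is also reproduced, within Monte-Carlo error, by the
  first-fixation-race mechanism across a 5x5x5 parameter grid, which is the
  strongest evidence for this parsing.
* Polygenic (`n` loci): `P_P = 1 - phi^(sigma_1 sigma_2 / sum_i s_i^2)`,
  the exponent reading of the flattened source expression.  It satisfies the
  stated `phi = 0` boundary (certain DMI formation), stays in [0, 1], and
  yields the clean equal-coefficient simplification `1 - phi^n`.  **Known
  tension**: at `phi = 1` this form gives 0 for every `n`, whereas an
  n-locus generalisation of the two-locus race has a positive collision
  probability (e.g. 0.75 for four equal loci).  The linear alternative
  reading violates [0, 1] for `n > 1` and was rejected.  The tension is
  documented rather than resolved; the simulator's
  `estimate_polygenic` gives the mechanistically correct value for any
  configuration and should be preferred where the two disagree.
* Coefficient transfer convention: population `k` experiences `s_i` at loci
  with `home_env == k` and `phi * s_i` otherwise.  `population_sums` applies
  this convention; `p_dmi_poly` accepts precomputed sums so the symmetric
  (`sigma_1 = sigma_2 = n s`) case underlying `1 - phi^n` can be expressed
  exactly.

### Degenerate inputs

`s_A = s_B = 0` raises an error rather than returning 0 (a silent zero would
mask misconfiguration).  At `phi = 0` with exactly one zero coefficient the
two-locus formula is a 0/0 form; it raises rather than imputing a value.  All
probabilities are clamped to [0, 1] with a 1e-12 tolerance; internal
comparisons use relative tolerance 1e-9.

## Simulator

Waiting times to the next substitution are exponential with rate equal to the
summed local coefficients, the proportionality constant (absorbing `2 N mu
2s` scale factors) set to 1 — absolute times are arbitrary units; only
ratios are meaningful.  The horizon is counted in substitutions per
population (fixation order defines DMI events, not wall-clock time).
Sequential races sample without replacement, and for horizons > 1 a locus
that would be incompatible (severity > 0) with an allele already fixed in the
same population is purged from that population's race (the "peak-stuck"
convention: such a mutation is never carried to fixation locally).  When a
population has no positively selected locus (e.g. `phi = 0` with no home
locus) it returns a no-substitution sentinel rather than raising; a replicate
where exactly one population substitutes counts as a DMI event iff the lone
fixed allele participates in some interaction pair.  For horizons > 1 in the
foreign population, per-locus `home_env` decides which coefficients are
phi-scaled at every step (the source model is silent on this; the per-locus
convention is this package's documented choice).

A single seeded NumPy generator drives each run with a fixed draw order, so a
`SimConfig` (seed included) maps to a bit-identical `SimResult`.  The
substitution-rate ratio is estimated as the ratio of mean waiting times, with
a delta-method standard error; its relative bias is O(1/n_reps).

## Reproductive-isolation pipeline

`RI = 1 - 2H/(H + C)` per ordered population comparison, with `H` the
unweighted mean proportion over that pair's inter-population crosses and `C`
the mean of the two parental intra-population control means (per-cross
averaging; the alternative of pooling flower heads is not used).  Crosses are
classified by ordered maternal x paternal ecotype — reciprocal directions
(DxH vs HxD) stay distinct for classification and cell tests, and are
averaged (`average_reciprocals`) for regression inputs.  Viability records
with zero tested seeds are dropped with a warning, never imputed.  Cell
contrasts are one-sided one-sample t-tests of mean RI > 0 (direction fixed;
no two-sided fallback).

The ecotype contrast replaces a random-intercept mixed model with
fixed-effects least squares (clade scope + ecotype similarity) plus a seeded
permutation test that shuffles ecotype-similarity labels across population
comparisons (default 9999 permutations).  The permutation test is exactly
specifiable and calibrated under the null by construction, at the cost of
ignoring the comparison-level random intercept.

The one-sample t-test assumes independent per-comparison estimates.  In a
shared-parent design (a handful of populations crossed in all combinations)
the comparisons within a cell share parental controls and are therefore
positively correlated, which inflates the test's type-I error.  The
calibration and power checks in the test suite accordingly use a generator
with disjoint population pairs; on shared-parent designs the t-test p-values
should be read as approximate.

## Distance stage

Trait matrices are column-standardised (mean 0, sd 1, n-1 denominator;
constant columns rejected by name).  Creating a Euclidean distance matrix on
standardised data and running classical metric MDS is mathematically the same
as PCA on that data, so the ordination is implemented as PCA (scikit-learn),
with the equivalence asserted in tests (`variance_target = 1` reproduces
plain Euclidean distances exactly).  Axis retention is threshold-based
(default: smallest axis count reaching 95% cumulative variance) with an
override to force a fixed count (e.g. 5 axes for soil, 7 for phenotypes).
Raw PC scores are used (not eigenvalue-rescaled scores).  Patristic distances
are tip-to-tip branch-length sums via dendropy.  The RI ~ genetic + other
distance regression is OLS with sequential (type-I) F-tests, so the second
predictor is tested after controlling for genetic distance; fits on six or
fewer pairs carry an explicit `small_n` flag.

## Synthetic-data generator

`make_crosses` emulates a paired-ecotype crossing design: 8 populations (two
dune-headland pairs per clade, two clades), all 56 ordered inter-population
pairs at 4 crosses each, plus intra-population controls padded round-robin to
260 total crosses.  Outcomes are binomial: seed set out of a per-head count
(`10 + NegBin(5, 0.5)`, mean 15) and germination out of 5 tested seeds.
Design cells carry planted RI values inverted through the index
(`H = C(1 - r)/(1 + r)`); the defaults (mild hybrid vigour for same-ecotype
within-clade cells, RI ~0.4 for between-clade headland seed set, ~0.9 for
between-clade different-ecotype crosses, seed-set controls at 0.8) are
illustrative of the qualitative published pattern, not estimates of real cell
means.  Trait matrices are built from orthonormal factors with controlled
singular values plus Gaussian noise, so the latent dimension is recoverable
by the variance-threshold rule; trees are random bifurcating newick strings,
optionally with long clade stems forcing between-clade > within-clade
patristic distances.  What the generator does *not* emulate: overdispersion
beyond binomial sampling, maternal effects, family structure within
populations, missing data, and correlated soil variables with real
covariance — so green pipeline tests demonstrate estimator correctness and
calibration under the stated sampling model, not robustness to those
real-data features.

## Numerical and testing choices

Monte-Carlo agreement tests use 3-standard-error bands at 1e5 replicates.
The 125-cell oracle grid performs 125 simultaneous 3-sigma checks, so ~0.3
cells are expected outside 3 SE by chance; the suite pre-registers an
allowance of at most 2 cells within (3 SE, 4 SE], which is a
multiple-comparison allowance, not a loosened tolerance.  Type-I calibration
of the cell t-test uses 2000 generator seeds (six independent pairs each);
power checks use 500 seeds.  Problem sizes throughout (1e5 replicates, 50
crosses per cell for recovery, 200-ish seeds for null-uniformity checks) were
chosen as the smallest sizes at which the binomial/Monte-Carlo standard
errors are well below the tolerances being asserted.

## Known limitations

Haploid, no standing variation, no gene flow, no recombination, no dominance,
no explicit drift (no finite-N Wright–Fisher dynamics): the model is
origination–fixation only.  The polygenic closed form's `phi -> 1` behaviour
is unresolved (see above).  Regressions on few population pairs are
underpowered and flagged rather than blocked.
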