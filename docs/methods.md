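# Methods

## The model and its assumptions

The GPS test treats the two traits' GWAS p-values at a common variant
panel as paired draws (u_i, v_i) from random variables (U, V) and tests
the null hypothesis that U and V are independent. The statistic

D = sup over observed points of
sqrt(n / ln n) · |F_UV − F_U F_V| / sqrt(F_U F_V − F_U² F_V²)

is a weighted Kolmogorov–Smirnov-type supremum over the empirical
copula discrepancy. The weight (the square root of the variance of the
Binomial proportion F_U F_V under independence) inflates discrepancies
near the corners of the unit square, in particular at jointly small
p-values; D is therefore most sensitive to a small number of strong
shared association signals, and comparatively insensitive to diffuse
polygenic sharing. It is rank-based: strictly monotone transforms of
either margin leave D unchanged.

Assumptions: variants are approximately exchangeable after upstream LD
pruning (the permutation null permutes one vector wholesale); p-values
are in (0, 1]; each vector may have arbitrary marginal distribution.
Residual LD among pruned variants and shared samples between the two
studies both violate exchangeability to a degree — the experiment
modules quantify the practical consequences (see below).

## Null calibrations

**GPS-Exp.** The legacy null takes 1/D² ~ Exp(1), giving
p = 1 − exp(−1/D²), oriented so that larger D yields smaller p. It
requires no computation beyond D but is miscalibrated: its null
p-values are demonstrably non-uniform (the test suite reproduces this).

**GPS-GEV.** The improved null models D as generalised extreme value,
G(x) = exp(−[1 + c(x − a)/b]^(−1/c)) on 1 + c(x − a)/b > 0, with the
c → 0 Gumbel limit. The fit uses null realisations of D obtained by
permuting one vector's order and recomputing the statistic. As a sample
maximum over n weighted discrepancy terms, D is in the domain where an
extreme-value family is the natural parametric smoother of the
permutation null; the fitted right tail sits at or above the empirical
tail in the large majority of fits, so far-tail p-values err on the
conservative side. GEV parameters shift with the variant count, so the
null must be refitted per pair — there is no global reference null.

Defaults: 3,000 permutations per pair for single-pair analyses (the
accuracy/runtime compromise also used as the package default) and 1,000
for large experiment grids. A warning is emitted below 1,000 and values
below 100 are rejected.

## Maximum-likelihood GEV fitting

The negative log-likelihood is minimised by Nelder–Mead over
(a, log b, c) with function/parameter tolerances of 1e-8, started from
Hosking's probability-weighted-moments estimator and from a Gumbel
method-of-moments point; if neither start converges, up to five seeded
random perturbations of the best start are tried before a fit error
(carrying the best parameters, flagged unconverged) is raised. The
support constraint is enforced by returning +inf outside it. Standard
errors come from the numerically inverted observed information
(finite-difference Hessian in the natural parameterisation); when the
Hessian is not positive definite the standard errors are NaN rather
than fabricated. scipy's `genextreme` uses the opposite shape-sign
convention (c_here = −c_scipy); the conversion happens only in tests,
where scipy serves as an independent cross-check of the optimum.

The shape convention, start values and tolerances are documented here
because GEV likelihoods have hard support boundaries that trap poor
starts; the probability-weighted-moments start lands inside the support
by construction.

## Permutation machinery and reproducibility

A master integer seed spawns one `numpy.random.SeedSequence` substream
per replicate; each replicate draws its permutation from its own
generator. Serial and (hypothetical) parallel execution therefore give
bit-identical null samples, and the first k replicates do not depend on
how many more are requested.

Marginal ranks are computed once per pair: a permutation changes only
the joint counts. The default backend fuses the joint-count sweep and
the running maximum in a numba kernel (a Fenwick tree over v-ranks,
swept in u-order with tied-u batches inserted before querying), making
one permutation of a 10,000-variant pair ≈ 0.5 ms. The naive and
divide-and-conquer backends produce exactly the same integer counts and
are used as oracles and for small inputs.

## Tie and degeneracy conventions

All ecdfs count "≤" (maximal rank), for margins and the joint alike;
backends are compared on integer counts so agreement is exact, not
approximate. At evaluation points where F_U F_V = 1 the weight is 0/0;
such points (only the maximal corner can produce them) are excluded
from the supremum and reported in `n_excluded` instead of being
silently zeroed. If every point is degenerate — possible only when both
vectors are constant — a degenerate-input error is raised. Arg-max ties
resolve to the smallest index for determinism. p-values exactly 1 are
legal; non-positive p-values are an upstream (ingestion) concern:
p = 0 rows are dropped and counted rather than clamped, because a clamp
would manufacture a massive tie at the minimum of a rank-based
statistic.

## Hoeffding comparator

The classical tie-corrected Hoeffding D (×30 scaling) with midranks and
half-count concordances is implemented directly (no pre-installed
implementation exists in the Python stack used here) and verified
against a brute-force double-loop oracle. Significance uses the same
permutation scheme as the GPS tests — exact at desk scale and directly
comparable on identical inputs — rather than asymptotic tables.

## Sample-overlap correlation

For two case-control studies with shared controls n0 and shared cases
n1, the expected correlation of effect estimates at null SNPs follows
Lin and Sullivan:

rho = [n0·sqrt((n_k1 n_l1)/(n_k0 n_l0)) + n1·sqrt((n_k0 n_l0)/(n_k1 n_l1))]
      / sqrt((n_k0 + n_k1)(n_l0 + n_l1))

with the subscript convention n_k0 = controls of study k fixed
canonically (renderings of this formula elsewhere mix n_0k and n_k0
styles). rho is 0 with no overlap, 1 for a study paired with itself
(used for matrix diagonals), symmetric in the studies, and
non-decreasing in both shared counts.

## Synthetic data: what it emulates and what it does not

Generators produce per-trait Z scores and convert to two-sided
p = 2Φ(−|z|) (clamped at the smallest positive normal float, with
clamping counted in metadata). Components:

* base Z pairs with cross-trait correlation `rho` at every SNP —
  the null-SNP effect-estimate correlation induced by sample overlap;
* a fraction `pi1` per trait of associated SNPs receiving an addend
  drawn Normal(`zmean`, `zsd`); `n_shared` of them get the *same*
  addend in both traits (maximal per-SNP sharing), the rest are
  trait-private with disjoint index sets;
* optional equicorrelated blocks (`block_size`, `block_r`) within each
  trait's base Z — the residual dependence structure left by LD pruning
  at a high r² threshold, in stylised form.

The closed-form expected genome-wide-significant fraction
pi1·P(|N(zmean, sqrt(1+zsd²))| > Φ⁻¹(1 − 2.5e-8)) + (1−pi1)·5e-8
positions scenarios on the power scale.

What this does **not** emulate: realistic LD from haplotype panels,
minor-allele-frequency/odds-ratio effect-size coupling, case-control
sampling noise, or per-SNP partial sharing (shared SNPs share their
addend entirely). Passing tests therefore demonstrate the statistical
behaviour of the tests under the assumed dependence structures, not
performance on any particular real cohort. Effect signs are not tracked
because the statistic is computed from two-sided p-values and is
sign-agnostic.

## Study sizes (desk scale)

Simulation studies in the test suite use 10,000-variant pairs:
200 replicates × 1,000 permutations for the type-1-error study (also
what `scripts/acceptance.py` reruns); 500 replicates × 500 permutations
for the null p-value uniformity study (refitting the GEV every
replicate; 500 permutations is enough for the *calibration* question,
while single-pair inference defaults to 3,000); 50 repeats × 3,000
permutations for fit adequacy and tail conservativeness; 100 replicates
per point on power grids at 500 permutations; 100 replicates × 400
permutations for the Hoeffding residual-LD study; and, for the
overlap-inflation study, 500 replicates on the inflated arm (the
inflation is about twice nominal, so resolving it against Monte-Carlo
noise needs the larger sample) and 200 on the controlled arm, at 1,000
permutations each. These sizes
are the package's chosen desk-scale study conditions; the monotone
qualitative conclusions are insensitive to them, and anything that is a
proportion carries a Wilson 95% interval.

Scenario constants for the overlap-inflation study: both arms use
pi1 = 0.01 per trait, zsd = 1, rho = 0.2. The low-power arm (zmean = 1,
≈ 0.08 expected genome-wide-significant hits per trait — an order of
magnitude under one expected hit, which is what "very low power" means
operationally here) shows the inflation; the high-power arm (zmean = 5,
≈ 37 expected hits) is controlled. The Hoeffding residual-LD study uses
blocks of 20 variants, a stylised post-pruning LD-cluster size.

## Numerical details and edge cases

* GEV CDF evaluation returns exactly 0 below a finite lower endpoint
  (c > 0) and 1 above a finite upper endpoint (c < 0); a statistic
  beyond a fitted finite upper endpoint gets p = 0 with the flag
  "p beyond fitted support" — no pseudo-count floor is applied.
* GPS-Exp at D = 0 returns p = 1 by continuity, flagged.
* The Anderson–Darling adequacy check transforms the null sample by the
  fitted CDF and tests uniformity of the transform, with the A² null
  distribution simulated from uniform samples of the same size (2,000
  Monte-Carlo draws by default). Because the parameters are fitted on
  the same sample, the check is conservative in the passing direction;
  it is used as an adequacy screen, not a calibrated test of the GEV
  hypothesis.
* Wilson intervals come from statsmodels; KS tests from scipy.

## Known limitations

* The supremum-norm construction favours architectures with a few
  strong shared variants; diffuse polygenic sharing is better served by
  quadratic-functional statistics.
* The permutation null assumes exchangeability; residual LD and sample
  overlap bias the test in opposite directions (conservative tail fit
  vs. inflation at very low power), and neither is corrected for —
  they are characterised empirically by the experiment modules.
* Only pairs of traits are supported, and only p-values are consumed
  (no effect sizes, no allele harmonisation).
* Multiple-testing across many trait pairs is deliberately not
  adjusted; downstream adjustment is the user's responsibility.
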