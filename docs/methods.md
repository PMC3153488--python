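# Methods

## The problem

A regression of a quantitative trait on the allele count of a biallelic
marker tests for linkage disequilibrium (LD) between the marker and a
quantitative trait locus (QTL): in a single randomly mating population the
population slope is

    b = Cov(X, Y) / Var(X) = 2D (d + (1 − 2q) h) / (2p(1 − p)),

where `X` is the marker allele count (0/1/2), `Y` the trait, `p` and `q`
the marker and QTL allele frequencies, `D` their LD coefficient and
`d`, `h` the additive and dominance effects of the QTL (genotype means
`μ+d`, `μ+h`, `μ−d`).  When the sample is an admixture of two
subpopulations in proportions `m : 1−m`, both the LD and the covariance
pick up confounded terms:

    D_mix  = m D₁ + (1−m) D₂ + m(1−m)(p₁−p₂)(q₁−q₂)
    Cov    = [m Cov₁ + (1−m) Cov₂]  +  2m(1−m)(p₁−p₂)(μ₁−μ₂)
             `— genuine (within-pop LD)`   `— spurious (structure)`

A marker with no physical relation to the trait appears associated
whenever allele frequencies and trait means both differ between the
subpopulations.

## The control-marker correction

A *control marker* `Z` — autosomal, on a different chromosome from the
test marker, in linkage equilibrium with both the QTL and the test marker
*within* each subpopulation — carries a pure structure signal.  Under
admixture its genotype variance exceeds the Hardy–Weinberg expectation at
the pooled frequency by the Wahlund excess

    δ = Var_obs(Z) − 2c̄(1−c̄) = 2m(1−m)(c₁−c₂)².

Because the only covariation of `Z` with `X` and `Y` flows through the
structure,

    Cov(X,Z) = 4m(1−m)(p₁−p₂)(c₁−c₂),   Cov(Z,Y) = 2m(1−m)(c₁−c₂)(μ₁−μ₂),

the product `Cov(X,Z)·Cov(Z,Y) / (2δ)` equals the spurious covariance
*exactly*, for any control marker with `c₁ ≠ c₂`.  The corrected statistic

    Cov* = Cov(X,Y) − Cov(X,Z) Cov(Z,Y) / (2δ),      b* = Cov* / Var(X)

therefore estimates a slope whose population value is zero whenever the
within-subpopulation LD is zero, however strong the structure.  The
package verifies this identity against a brute-force enumeration of the
full mixture distribution (tests) and exposes it as
`popmodel.theoretical_coefficient`.

At sample level all moments are replaced by their complete-case sample
counterparts (n−1 denominators; the expected variance uses the plug-in
frequency `p̂ = mean(Z)/2`).  `δ̂` can be negative under panmixia; it is
never used as a divisor unless it exceeds a tolerance (below).

## Standard error of the corrected slope

The slope is tested by Student's t with `n − 3` degrees of freedom.  For
its standard error two estimators are implemented:

* **jackknife** (default): the delete-one jackknife of the whole
  statistic `b*`, computed in O(n) from leave-one-out sums.  It accounts
  for the sampling noise of the correction term (the ratio of three
  sample covariances to `δ̂`), which the plug-in form ignores.
* **"ols"**: the plug-in OLS-style slope standard error built from the
  corrected coefficient of determination,
  `se² = (S_yy − b*² S_xx) / ((n−3) S_xx)`.

The choice was settled empirically, with type-I error calibration as the
arbiter: on strong-structure null scenarios at n = 200 the plug-in form
rejects at ≈ 0.085 for a nominal 0.05 (the correction noise is material),
while the jackknife form stays at 0.03–0.05 across null scenarios without
losing agreement with the noncentral-t power theory.  The plug-in form is
kept as an option because it is the natural closed-form counterpart of the
power formula.

## The comparison methods

* **simple** — ordinary least squares of `Y` on `X`, df `n − 2`.  Its
  population slope is `Cov/Var(X)` including the spurious term; under
  structure it is badly anti-conservative (and can also *lose* power when
  the admixture term opposes the genuine LD).
* **structured** — multiple regression `Y ~ 1 + X + P` with `P` the
  probability of membership to subpopulation 1, df `n − 3`.  With exact
  membership its population slope is the genuine covariance over the
  admixture-weighted *within*-subpopulation marker variance
  `m·2p₁(1−p₁) + (1−m)·2p₂(1−p₂)`.  A constant membership column is
  dropped (the slope then equals the simple one); a membership column
  collinear with the genotype is an error.  Corrupting the membership
  information (see `simulate.corrupt_membership`) degrades it smoothly
  toward the simple regression's behaviour.

## Control-marker selection

Candidates are autosomal markers on chromosomes other than the test
marker's with missing fraction below a threshold (default 0.10).  Each is
scored by `δ̂ = var_observed − var_expected`; the maximiser wins, with a
deterministic (chromosome, position) tie-break.  `fit_corrected` refuses a
control marker whose `δ̂` does not exceed `k` jackknife standard errors of
itself (default `k = 2`): dividing by a noise-level `δ̂` both inflates the
type-I error and destroys power.  Callers may instead request a fallback
to the uncorrected fit, which is the right behaviour when the sample is
actually panmictic.

## Power prediction

The two-sided slope test has power `P(|T'_{v,ncp}| > t_{α/2,v})` with
`v = n − 3` and

    ncp = κ_v · b · sqrt(n · Var(X) / σ²_resid),
    κ_v = sqrt(2/v) · Γ(v/2) / Γ((v−1)/2),

where `σ²_resid = Var(Y) − b² Var(X)` is the residual trait variance about
the regression line and `κ_v` a small-sample gamma-function factor
(Johnson & Kotz); `ncp_form="asymptotic"` drops `κ_v` (it differs from 1
by < 0.4% at n = 200).  The prediction treats the control-marker
correction as noiseless.  That is accurate when the structure signal
`2m(1−m)(c₁−c₂)²` is strong — balanced admixture and a strongly diverged
control marker — and optimistic otherwise: with `|c₁−c₂| = 0.4` instead of
0.6, or `m = 0.3` instead of 0.5, realised power falls measurably below
the curve.  The power-agreement test grid therefore uses m = 0.5 and
`|c₁−c₂| = 0.6`, which is also the recommended practice (pick the control
marker with the largest frequency divergence).

## Simulator

`simulate_admixed_sample` draws, per individual: origin ~ Bernoulli(m);
the (QTL, test-marker) genotype pair from the exact two-locus joint
distribution of its subpopulation (random mating, parameterised by
`p, q, D` through the conditional allele probabilities `Q = (pq+D)/q`,
`R = (p(1−q)−D)/(1−q)`); the control genotype ~ Binomial(2, cᵢ); and
`Y = genotype mean + N(0, σ²)`.  The QTL genotype is latent — analyses
only ever see `X`, `Z`, `Y` and membership.  `simulate_marker_panel`
generates multi-locus genotypes as two independent haplotype Markov chains
with prescribed adjacent-locus LD.  Replicate studies spawn one RNG stream
per replicate from a single seed, so results are reproducible and
independent of execution order.

What the generator does **not** emulate: genotyping error, missingness
mechanisms (missing data enter only through the readers), linkage between
test and control markers, more than two source populations, multi-QTL
traits, and non-normal trait residuals.  Passing tests therefore
demonstrate correctness of the statistics under the model's own
assumptions, not robustness to their violation.

### Default scenario library

Supplementary parameter tables for the original simulation study are not
bundled, so the library ships a qualitative counterpart built on the
grids: sample size 200, m = 0.5, between-subpopulation frequency
differences in {0.2, 0.4, 0.6} (subpopulation frequencies `0.5 ± δ/2`),
within-subpopulation LD in {0, 0.05, 0.08}, d = 1, h = 0 (dominance
defaults to zero in all scenario builders), σ² = 1, nominal α = 0.05.
`default_null_scenario` (δ = 0.6 everywhere, D = 0) is the
strong-structure null used for calibration.  Exact external parameter sets
can be supplied verbatim through `make_scenario` or scenario YAML files.

## eQTL layer

Scans fit one association per polymorphic marker (failures are reported
per marker with a reason, never dropped silently).  Significance uses a
Sidak threshold `1 − (1−α)^(1/n_tests)`, by default over markers × traits,
optionally per trait.  Significant markers are chained into peaks by
single linkage with a 5 Mb merge distance — a significant marker within
5 Mb of *any* member joins the peak (an alternative summit-distance rule
would split long chains; single linkage matches the "within 5 Mb of
adjacent peaks" reading most directly).  Every significant marker is
seeded, not only local maxima; with sparse maps the two coincide.  The
peak locates at its smallest p-value, ties broken to the lowest position.
A peak is *cis* when any member marker lies within 500 kb upstream of the
transcript start to 500 kb downstream of the 3′ end; since the window is
symmetric this is the interval `[start − 500 kb, end + 500 kb]` for both
strands (strand is still recorded and validated).  Coordinates are 1-based
inclusive throughout, matching VCF; BED input is converted on read.

## Hardy–Weinberg diagnostics

Per marker, a 1-df Pearson chi-square against HWE expectations at the
sample allele frequency, and the exact test enumerating heterozygote
counts conditional on the allele counts (probabilities summed over
configurations no more likely than the observed one, in log space).
Monomorphic markers return (χ² = 0, p = 1) by convention.  Genome-wide
scans flag markers at the Sidak-corrected level; pooling diverged
subpopulations produces a heterozygote deficit (Wahlund effect) that
floods the scan, while the unmixed subpopulations show only the expected
false positives.

## Numerical choices and degenerate inputs

* Missing data: NaN internally; complete-case per test (pairwise for the
  simple fit, triple-wise for the corrected fit); `n_used` is reported.
* Perfect fits (zero residual) report `p` clamped to the smallest positive
  float rather than 0, keeping `p ∈ (0, 1]`; a constant trait gives
  `b = 0, p = 1`.
* Joint genotype tables clamp −1e−17-scale rounding noise at Lewontin
  boundaries to 0 and renormalise.
* The noncentral-t tail falls back to its Normal(ncp, 1) limit where
  scipy loses precision at large degrees of freedom.
* Monomorphic test markers are an error ("zero marker variance"), not a
  silent zero.

## Problem sizes used in the checks

The shipped verification suite uses 1,000 random parameter draws for the
exactness oracle, 1,000 replicates of n = 200 for size, 500 replicates for
each of five power scenarios, a single n = 50,000 sample for large-sample
consistency, and 1,000 markers × 400 individuals for the HWE contrast —
sizes at which binomial/Monte-Carlo error bands are tight enough to be
informative while the whole suite runs in minutes on one core.
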