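# Methods

## Model

Microbial concentrations in a food lot are modelled as lognormal: the
base-10 logarithm *Y* of the concentration (log₁₀ CFU/g) is
Normal(μ, σ). The two parameters are estimated by maximizing the
censored-data likelihood in which

* a quantified sample contributes the normal density at its log value;
* an ND (below-LOQ) sample contributes P(Y < b), the normal CDF at its
  censoring bound *b*, so *m* ND samples contribute that probability to
  the *m*-th power (implemented as a weight);
* a semi-quantitative sample known only to lie in a band [l, u)
  contributes P(l ≤ Y < u), the difference of two CDFs.

All model work is done in base-10 logs. The normal family is
affine-equivariant across log bases, so nothing is lost relative to a
natural-log formulation, and base 10 matches both the decade bins of
survey tables and the universal "log CFU/g" reporting convention.

ND is interpreted as sub-LOQ *presence* (a positive concentration below
the LOQ), not as a true zero. Fully censored (100% ND) datasets are
rejected with a structured error: they do not identify both parameters
of a continuous model and belong to presence/absence methodology, which
is out of scope (as are right-censored "too numerous to count" results).

## Data-reading conventions

Real plate-count tables are discrete artifacts, and two conventions
control how they enter the likelihood. Both are explicit keyword
arguments of `fit_mle`; the defaults follow classic plate-count
digitization practice.

**Interval data** (`interval_method`):

* `"midpoint"` (default): each decade band is represented by its
  arithmetic mid concentration on the linear scale — 10–10² CFU/g
  enters as 55 CFU/g (log₁₀ 55 ≈ 1.740) — and treated as an exact
  observation. This is how semi-quantitative records are conventionally
  keyed into point-data MLE templates.
* `"likelihood"`: the band probability Φ((u−μ)/σ) − Φ((l−μ)/σ) is used
  exactly. This is the statistically correct treatment and the one that
  is consistent (bias vanishing with n) when data really are
  interval-censored; the midpoint convention carries a small systematic
  distortion that does not vanish with sample size.

**ND bound** (`nd_bound`):

* `"integer"` (default): the ND class is censored at LOQ − 1 CFU/g
  (log₁₀ 9 ≈ 0.954 for LOQ 10), reading "below 10 CFU/g" as "at most
  9 CFU/g" for integer colony-derived concentrations. Only applied when
  LOQ > 1; otherwise the bound is the LOQ itself.
* `"loq"`: censored exactly at the LOQ — correct when the underlying
  scale is continuous, as in the package's own simulations.

With the defaults, the four bundled case tables (decade bins, LOQ
10 CFU/g) refit to 2.34 ± 1.28, −2.76 ± 2.93, 2.57 ± 1.34 and
−0.44 ± 1.63 log CFU/g — exactly the values the tests assert. With the
exact interval likelihood the same tables give systematically different
optima (e.g. case 1 fits near 2.14 ± 1.18); the difference is a model
choice, not an optimization artifact, which is why both routes are kept
explicit rather than hidden behind one default.

Bins are half-open [lower, upper); the ND class is [0, LOQ). A
continuous model puts zero mass on boundary points, so the MLE is
insensitive to the open/closed choice; the convention only matters for
validation (non-overlap). Blank cells in published tables are zero
counts and are dropped. A quantified value *below* the declared LOQ is
rejected as a data-entry contradiction instead of being silently
censored.

## LOQ derivation

`compute_loq` maps a plating scheme to the concentration one colony
represents: ((sample_mass + diluent_volume)/sample_mass) ×
extra_dilution_factor / plated_volume, with a 1 ml plated volume by
default. It is homogeneous in (mass, volume), so 25 g + 225 ml and
1 g + 9 ml both give 10 CFU/g.

## Optimization and uncertainty

* Parametrization (μ, log σ) makes σ > 0 structural. The start point is
  a substitution summary (exact values; log₁₀(LOQ/2) for ND; log
  midpoints for bands; SD floored at 0.05), then a Nelder–Mead simplex
  (relative objective tolerance 1e-10, cap 2000 iterations) refined by
  BFGS. The fit is deterministic for a fixed dataset.
* Wald intervals: the Hessian of the log-likelihood at the MLE is taken
  in (μ, σ) by central finite differences with step 1e-5·max(1, |θ|)
  (the σ step additionally capped at 0.4 σ); the covariance is the
  inverse of the negated Hessian. If that matrix is not positive
  definite, standard errors are reported as unavailable with a
  diagnostic rather than silently clipped. In the uncensored limit the
  SEs reduce to the textbook σ̂/√n and σ̂/√(2n). Profile-likelihood and
  bootstrap intervals are non-goals.
* The SD uses the MLE (n-denominator) convention everywhere, including
  the direct QN_1/QN_2 summary path, so all four modes agree in the
  no-censoring limit; the n−1 convention would differ by a factor
  √(n/(n−1)).
* Reported percentiles are distribution percentiles μ ± 1.644854 σ —
  deliberately distinct from the parameter confidence intervals, and
  both are labelled in reports.
* Numerics: everything is computed in log space (the product form of
  the censored likelihood underflows doubles near m ≈ 1000, which case
  2 reaches); tail probabilities use `scipy.special.log_ndtr`, and band
  probabilities are mirrored into the nearer tail before the
  log1p(−exp(·)) subtraction so neither tail cancels. Contributions
  below log ≈ −745 (the smallest positive double) are legal during
  optimization; they simply signal a parameter region the optimizer
  will leave.
* Degenerate inputs: a dataset of identical exact values has no
  interior maximum in σ; it is summarized as (value, σ = 0) with a
  warning and no standard errors.

## Synthetic data

The simulator draws n log₁₀ values from Normal(μ*, σ*), censors below
log₁₀(LOQ), and either keeps detected values exactly (quantitative
mode) or tallies them into bins (interval mode; default five decade
bins above the LOQ, the layout of typical survey tables; draws above
the top edge are clamped into the top bin with a warning, mirroring the
finite bin range of real tables). Replicate r of a study uses seed
base + r, so studies are exactly repeatable. Substitution rules
(`ignore_nd`, `loq`, `half_loq`, `zero_excluded` — zero has no log, so
the zero rule excludes those samples from the log-scale summary) give
the naive comparators for bias contrasts.

What the generator does *not* emulate: Poisson colony-count noise on
top of the lognormal, between-lot heterogeneity, measurement rounding,
or plate-level TNTC truncation. Passing recovery tests therefore show
that the estimator handles *censoring* correctly, not that real
enumeration data are exactly lognormal.

Because the simulator censors exactly at the LOQ on a continuous scale,
recovery studies fit with `nd_bound="loq"` and the exact interval
likelihood; using the plate-count digitization defaults on simulated
data would mix two different data-generating stories.

Study sizes used in the test suite — 200 replicates of n = 2000 for the
bias studies, 20 random small datasets against an exhaustive 0.01-step
grid search, 10⁵ draws for censored-fraction calibration — were chosen
to keep Monte-Carlo error comfortably below the asserted margins.

## Known limitations

* Wald intervals are symmetric and can be poor for σ at small n or
  extreme censoring (case 2's 90% censoring stretches them).
* The midpoint convention is kept as the default for fidelity to how
  semi-quantitative tables are conventionally analyzed, not because it
  is statistically optimal; for new interval data collection the exact
  interval likelihood is the better choice.
* No qualitative (presence/absence) support; no zero-inflation or
  mixture structure; one distribution family (log₁₀-normal).
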