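# Methods

`countvar` assesses the variance structure of gene-level mRNA-Seq counts in
a two-group human study design, using per-gene generalized linear models
under three variance laws, dispersion estimation at three levels of
information sharing, and Pearson goodness-of-fit diagnostics. Because the
analyses run on simulated data, this note spells out both the models and
what the generator does and does not emulate.

## Count models

A count `y_gi` for gene g in subject i is modelled with a log link,

    log mu_gi = x_i' beta_g + o_i,

where `x_i` holds an intercept, a treatment-coded response-group indicator
and optionally treatment-coded blocking contrasts (flow cell, lane-pair
position, library-prep batch), and `o_i` is a normalization offset with its
coefficient fixed at 1. Three variance families are considered:

* **Poisson** — Var(y) = mu. Appropriate for technical replicates (two
  lanes of the same library).
* **Over-dispersed (quasi-)Poisson** — Var(y) = k mu. k is estimated per
  gene as the Pearson statistic of the Poisson fit divided by the residual
  degrees of freedom `n - (p+1)`.
* **Negative binomial** — Var(y) = mu + phi mu^2, the Gamma-Poisson
  mixture: within-subject counts are Poisson around a subject-level mean
  that is Gamma-distributed across subjects. `sqrt(phi)` is therefore the
  between-subject coefficient of variation of expression; phi = 0.131
  corresponds to a 36% subject CV.

Coefficients are estimated by Fisher scoring (IRLS) with working weights
`mu` (Poisson families) or `mu / (1 + phi mu)` (NB), vectorised across all
genes that share a design matrix. Convergence is declared when the relative
deviance change falls below 1e-8 (at most 50 iterations); non-converged
genes are flagged and returned, never dropped. The linear predictor is
clamped at +-30, which resolves separation (e.g. a response group with all
zero counts) at a fitted mean of ~1e-13; a Pearson contribution with a
zero observation against such a clamped-to-zero fitted mean is defined
as 0.

### Degrees-of-freedom conventions

The model degree of freedom `p` counts non-intercept columns: the group-only
model has p = 1, and with 13 flow-cell levels (12 contrasts) p = 13, with 4
lane-pair positions p = 4. The chi-square reference for the Pearson
goodness-of-fit statistic uses `df = n - p` (22 for the 23-subject group
model). Two estimators intentionally use the *full* residual df
`n - (p+1)`: the quasi-Poisson moment estimator of k, and the null
calibration study, where the only fitted quantity is the sample mean and the
reference is chi-square(n - 1). These conventions follow the study design
this package emulates and are asserted by tests.

## Normalization

Sequencing depth varies by a factor of ~3 across lanes, so counts are
modelled as rates via offsets `o_i = log c_i - mean_j log c_j`, with `c_i`
either the sample's total count or its upper-quartile (nearest-rank 75th
percentile) count computed over genes expressed anywhere in the dataset.
The nearest-rank rule (order statistic at `ceil(0.75 m)`) was chosen because
it is exactly reproducible across implementations; restriction to
dataset-expressed genes keeps the constant positive when many genes are
silent. Centring by the mean log-constant keeps the intercept on the count
scale and provably does not change fitted-mean ratios or Pearson statistics
(the intercept absorbs any constant shift; this is a tested property). The
upper quartile is preferred over the total because a handful of very
high-count genes dominate totals.

## Dispersion estimation

For a fixed design, the per-gene NB log-likelihood is profiled over beta
(IRLS refit at each candidate phi) and corrected with the Cox-Reid
adjustment, `APL_g(phi) = loglik_g(phi, beta_hat(phi)) - 0.5 log det X'WX`,
which accounts for the estimated mean parameters. Three estimators share
this objective:

* **per-gene** — phi_g maximises `APL_g`;
* **common** — a single phi maximises `sum_g APL_g`;
* **moderated** — phi_g maximises `APL_g(phi) + prior_n * mean-APL(phi)`,
  a weighted-likelihood empirical-Bayes compromise. `prior_n` is the weight
  of the shared curve in units of one gene's likelihood: 0 recovers the
  per-gene estimates exactly, and as `prior_n -> infinity` every gene
  converges to the common estimate. The default `prior_n = 3` shrinks a
  typical gene about 75% of the way to the common value; 3 outperforms the
  heavier choices 10 and 20 in mean-squared error on heterogeneous
  simulations here, consistent with the study this package emulates.

Using the *adjusted* profile likelihood for the per-gene estimator (rather
than the raw profile likelihood) is a deliberate unification: it makes the
moderation limits above exact rather than approximate, and it reduces the
downward bias of per-gene maximum likelihood at n = 23.

All searches run on log phi over [1e-6, 10]: an 81-point bracketing grid
followed by golden-section refinement to 1e-5 in log phi; a maximiser at the
lower edge is reported as the boundary value 0 (the correct estimate for an
under-dispersed gene). For the moderated search the shared `mean-APL`
curve is evaluated exactly (batched IRLS refits of every gene) at the 81
grid points and interpolated with a cubic spline during refinement; the
per-gene term is always exact. The spline's interpolation error moves the
infinite-prior limit by well under 1e-3 in phi.

The original study obtained its global and moderated estimates from a
quantile-adjusted conditional maximum likelihood scheme; numerical equality
with that tool is not claimed. The contract here is parameter recovery
(common phi within a few percent at G = 2000, n = 23) and the exact
moderation limits.

## Diagnostics

**Pearson GOF / QQ.** `X^2 = sum_i (y_i - yhat_i)^2 / Var(yhat_i)` with the
family-appropriate denominator, compared to chi-square(n - p) at plotting
positions `(i - 0.5) / G`. The top 1% of statistics (`ceil(0.01 G)`) and the
next 4% are flagged, matching the study's red/blue QQ annotation. Note that
the OD-Poisson GOF statistic is uninformative by construction: k is
estimated from the same Pearson statistic, so `X^2 / k = n - (p+1)`
identically.

**Technical-pair QC.** For two lanes with totals N1, N2, each gene's pair
total is split as `yhat_l = N_l (y1+y2) / (N1+N2)` and the Pearson statistic
referenced to chi-square(1); genes with zero pair totals are excluded and
counted. MVA coordinates use total-count scaling, restrict to genes positive
in both lanes (no pseudocounts), and smooth M over A with a centred moving
average spanning 5% of the points — a simple, deterministic stand-in for a
generic local smoother that affects no reported number. Spearman
correlations use midrank ties.

**Mean-variance characterisation.** Per gene and response group, the mean
and unbiased variance of scaled counts (counts divided by the sample's
upper-quartile constant and multiplied by the mean constant, keeping the
count scale). The two non-Poisson laws are fitted by through-origin least
squares: `k` from S^2 on x̄, and `phi` from (S^2 - x̄) on x̄^2. Curves are
also emitted on the SD scale for plotting.

## The synthetic-data generator

The generator emulates the structure of a 25-subject, 13-flow-cell human
mRNA-Seq study restricted to its retained unstimulated specimens:

* `replicate_study_design()` reproduces the retained layout deterministically:
  23 subjects (12 high, 11 low responders), 13 flow cells — ten with one
  subject per group, three with a single subject — four lane-pair position
  levels, six observed library batches, and the older base-calling software
  on flow cells 1-5. This yields exactly the study's model-df accounting
  (p = 1 / 4 / 13 / 6).
* Baseline means are log10-uniform over [0, 5] — the simplest law matching
  the observed five-orders-of-magnitude span; no parametric claim is made.
* Per-gene dispersions default to a mixture calibrated to the study's
  summaries (82% below 0.15, ~5% above 0.25 with an exponential right
  tail); point masses and two-point mixtures are available for parameter-
  recovery experiments.
* Subject multipliers are `Gamma(1/phi, phi)` (mean 1, variance phi), so
  subject-level lane-pair sums are exactly NB and `sqrt(phi)` is exactly the
  subject CV.
* Lane totals are uniform in [3.7, 7.2] million reads before the upgrade
  flow cell and [7.2, 10.7] million after (midpoint split of the stated
  range). Crucially, totals refer to a full `transcriptome_size = 17337`
  gene complement: a simulated subsample of genes keeps *per-gene* depth at
  study scale rather than inheriting the full lane total. This is what makes
  scaled-down runs faithful — with study-scale counts, per-gene dispersion
  estimates are noisy enough that moderation genuinely helps, as in the
  real data.
* Optional multiplicative (log-additive) flow-cell/batch effects, optional
  group fold changes, and an optional anomaly injection that zeroes a
  mid/high-expression gene block in both lanes of one subject (the analogue
  of the study's all-zero-subject artefact, which shows up as a spike of
  inflated moderated dispersions at mid/high means).
* One RNG stream (PCG64) seeded once; draws are ordered gene-major, so a
  seed fully determines the output byte-for-byte.

**What the generator does not emulate:** read-level artefacts (GC/positional
bias, mapping ambiguity), exon/isoform structure, library-size composition
effects, correlated gene-gene expression, and any real biological signal.
Passing tests therefore demonstrate that the estimators and diagnostics are
correct under the stated Gamma-Poisson model at study scale — not that real
data obey that model.

## The null calibration study

`validate_chisq_asymptotics` simulates null NB genes, computes `X^2` from
the sample mean and the *true* dispersion, and compares against
chi-square(n - 1). Defaults: G = 5000 genes, means log10-uniform on [0, 4]
(the adequately expressed lane-pair range; for sub-unit means the statistic
is dominated by discreteness rather than asymptotics), dispersions from the
study-like mixture. At n = 23 the mean of X^2 sits within 2% of 22 and the
KS distance to chi-square(22) is ~0.02; at n = 1000 the agreement is
essentially exact.

One caveat is documented rather than hidden: at n = 23 the *extreme* right
tail of the exact X^2 distribution is slightly heavy relative to
chi-square — the Gamma mixing inflates the kurtosis of the sample variance,
so for any phi > 0 the top order statistics run ~5-25% above the theoretical
quantiles (only the Poisson limit phi = 0 shows a deflated tail). The
deviation is tiny compared to the distributional changes the GOF comparison
is used to detect (factors of 100-1000 between variance models).

## Numerical and design choices

* Batched IRLS solves all genes' weighted least squares simultaneously
  (einsum-built normal equations, LAPACK batched solve, ridge of 1e-12 on
  the diagonal for degenerate all-zero genes).
* Blocking levels are ordered by sorted label with the first as reference;
  empty levels are pruned; a blocking factor confounded with group raises an
  error naming the aliased columns.
* Exclusion bookkeeping (failed lanes, dropped subjects) lives in a `status`
  column of the lane table; `sum_lane_pairs` is strict by default (errors on
  incomplete pairs) and can instead drop-and-log, which is how the emulated
  study handled its failed specimen.
* Analysis drivers default to 4000-gene simulations and the acceptance
  script uses 800-5000 genes per quantity; these sizes hold every reported
  estimate's Monte-Carlo error well inside its stated tolerance while a full
  run stays in the minutes range.

## Known limitations

* The moderated estimator's `prior_n` follows the weighted-likelihood
  convention described above; other tools tie the prior weight to different
  units, so `prior_n = 3` is comparable only qualitatively.
* Dispersion is modelled as mean-independent (the emulated study saw no
  mean trend); trended-dispersion fits are out of scope.
* No differential-expression testing, random-effects modelling, TMM/RPKM
  normalization, or read-level simulation.
* GOF is assessed via the Pearson statistic only; the residual deviance is
  known to behave poorly for these models and is deliberately not offered.
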