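# Methods

## The experimental design being modelled

The package targets a two-round split-plot greenhouse experiment.  A
whole-plot "early experience" factor with two levels — temporally
heterogeneous watering (alternating inundation and drought, `E_het`) vs
consistent moderate watering (`E_hom`) — is crossed with species.  After
the first round, 20 plants per species x early cell are harvested; the
rest are split across three late water treatments (inundation, moderate,
drought) with 10 replicates per species x early x late cell.  With the
default 8 species this gives 8 x 2 x (3 x 10 + 20) = 800 experimental
units, one plant per pot.  Before treatments begin, the longest leaf of
each plant is measured as its initial size (IS), which later serves as
the ANCOVA covariate.

At harvest, every leaf on the main stem is measured: the width of the
right and left half (midrib to margin) at the widest point, each read
M = 2 times in immediate succession with a digital caliper.  Mass traits
(shoot, root, total, root:shoot) are taken per plant.

## Generative model of the synthetic data

The generator exists so that every estimator in the chain can be checked
against known truth.  Its structure:

- **Leaf sides.** A leaf with true half-width $t$ has latent sides
  $R = t + d/2$, $L = t - d/2$, so leaf size $(R+L)/2$ recovers $t$
  exactly.  The signed asymmetry $d$ is drawn
  $N(\delta_{DA}, (\sigma_{fa} + \beta_{size} t)^2)$, plus an optional
  symmetric two-point mixture at $\pm\delta_{anti}$ emulating
  antisymmetry.  Each replicate reading adds independent
  $N(0, \sigma_{me}^2)$ caliper error.  Non-positive sides or readings
  are redrawn rather than truncated, so the asymmetry distribution is
  not biased for realistic scales.
- **Traits.** Mass traits are lognormal around species-scaled baselines
  (species effects lognormal, SD 0.2 on the log scale), with
  multiplicative treatment effects, a log-log slope of 0.5 on initial
  size, and inter-individual CV `cv_inter` (default 0.3).  Total mass is
  the exact sum of shoot and root; root:shoot the exact ratio.  Because
  shoot and root noise are independent, the realized CV of *total* mass
  is below `cv_inter` (about cv/√2 for comparable means); parameter-
  recovery checks therefore use the directly generated traits.
- **Leaves per plant** are uniform on a configured range (default 4–12;
  real counts are unknown, so this is an exposed placeholder).  Leaf
  sizes within a plant are lognormal around the plant mean with
  `cv_intra_leaf` (default 0.10).
- **Mortality** is Bernoulli per individual at rate 0.10 by default,
  reproducing the 720/800 survival of the motivating design; realized
  per-cell rates are reported.

Default magnitudes (half-width 10 mm, $\sigma_{fa}$ 0.3 mm,
$\sigma_{me}$ 0.05 mm, masses ~1–2 g) are chosen as field-realistic for
herbaceous species measured with a digital caliper: asymmetry a few
percent of leaf size, and replicate error an order of magnitude below
the true between-sides variation.  Magnitudes of measurement error and
leaf counts are not pinned down by any published value and are exposed
in `AsymmetryModel` / `DesignConfig`.

What the generator does **not** emulate: tank-level (whole-plot)
random effects, spatial or temporal correlation in the greenhouse,
species differences in asymmetry parameters, non-lognormal trait noise,
or trait-dependent mortality.  Passing tests therefore demonstrate that
the estimators recover the truth under the assumed independence
structure, not that the fixed-effects analysis is robust to split-plot
error correlation (see Limitations).

## Estimator and test conventions

- **Replicate handling.** FA1/FA2, CV and all trait analyses use
  replicate-mean sides ($\bar R, \bar L$); only the side x unit ANOVA
  consumes raw replicates, which is what makes the measurement-error
  mean square estimable.
- **FA2** uses $|R-L|/LS$ (the absolute convention); a signed variant is
  available where directional cancellation is wanted.
- **FA10.** For the balanced side x unit ANOVA,
  $E[MS_{sj}] = \sigma_{me}^2 + (M/2)\,\mathrm{Var}(R-L)$, so the
  between-sides variance net of measurement error is
  $\hat\sigma^2_{R-L} = 2\,(MS_{sj} - MS_m)/M$ and
  $FA_{10} = 0.798\,\hat\sigma_{R-L}$ — the factor 2 is required for
  FA10 to estimate the same quantity as FA1 (this is Palmer's FA10a;
  printed versions of the formula sometimes drop the 2).  A negative
  variance estimate (possible in small samples when the interaction sits
  below measurement error) is clamped to 0 and flagged rather than
  returned as missing, so group means stay computable; flag counts are
  reported.  FA10 is computed both per individual (its leaves as units,
  making an SE across individuals definable for group mean plots) and
  pooled per cell.
- **Moment tests.** $\gamma_1, \gamma_2$ are bias-corrected sample skew
  and excess kurtosis.  Each is tested against 0 with its exact
  normal-theory SE ($\sqrt{24n(n-1)^2/((n-3)(n-2)(n+3)(n+5))}$ for
  $\gamma_2$) and a normal reference; at n = 100 this holds two-sided
  size within half a point of nominal 5%, slightly closer than the
  large-sample $\sqrt{24/n}$ convention.  The antisymmetry
  *classification* additionally requires $\gamma_2 < 0$.
- **CV** is sample SD (n−1) over mean, computed on raw trait values:
  although mean comparisons are run on logs, the CV of logged data is
  not a coefficient of variation of the trait.  A `log_scale` switch
  implements the literal-log reading for sensitivity analysis.
- **CV equality.** Default is the Feltz-Miller (1996) asymptotic
  $D'AD$ chi-square test (type-I error ~4.9% at n = 50 per group in the
  calibration suite).  The `modified_slrt` option computes the normal-
  model likelihood-ratio statistic — group means profiled out in closed
  form under a common CV ($n c^2 \mu^2 + \mu\sum x - \sum x^2 = 0$) with
  a 1-D bounded search over the common CV — rescaled by its parametric-
  bootstrap null mean (a Bartlett-type correction, seeded and
  reproducible) before the chi-square comparison.
- **Adjusted means / PI.** ANCOVA `trait ~ late + IS` is fitted on log
  traits; adjusted means are evaluated at the covariate grand mean and
  back-transformed (geometric means) before the plasticity index is
  formed.  Back-transforming by default keeps PI on the trait scale,
  where a multiplicative treatment effect m implies
  $PI_{rel} = m - 1$ under the ratio variant; `back_transform=False`
  gives the log-scale index.  Both the ratio and the bounded sRDPI
  variants are labelled in output.  A constant covariate falls back to
  raw means with a warning rather than failing.
- **Effect tests** use Type III (partial) sums of squares with
  sum-to-zero coding, mirroring common GLM-software conventions; when
  empty cells make an interaction inestimable, the interaction order is
  reduced with a warning.  LSD comparisons are unprotected pairwise
  t-tests on the pooled residual MS with a compact letter display
  (insert-and-absorb); a pair at exactly p = alpha is *not* significant.
- **Correlations** among indices are computed across species-level
  points within treatment cells (8 points per cell at the default
  design).  Partial correlations use the residual (regress-out) method
  with p on n − k − 2 df; with no covariates this is exactly the plain
  Pearson correlation.  Stars follow * p < 0.10, ** p < 0.05,
  *** p < 0.01; no multiple-testing correction is applied by default.
  With fewer than 5 points rows are flagged `low_power`.
- **Randomness.** One run seed drives everything; the generator and the
  mortality draw use separate streams spawned from it, so stage-level
  reruns reproduce bit-for-bit.

## Problem sizes in the validation suite

The statistical guarantees are exercised at: 10^6 leaves for the
half-normal constant (tolerance ±0.002); 200 replicates of 500 leaves
for the FA10 measurement-error correction (±0.05); 2000 null replicates
at n = 100 for diagnostic calibration (5% ± 2 points) and 1000 for
antisymmetry power (≥ 80% at $\delta_{anti} = 1$); 200 simulated
800-pot experiments for plasticity recovery (±0.05 around the
multiplier-implied 0.5); 2000 replicates at n = 50 per group for the
CV-equality test size.  Linear-model outputs are matched to brute-force
least-squares and residual-correlation oracles at 1e-9 relative
tolerance.

## Known limitations

- The analyses are fixed-effects GLMs: tanks (whole plots) are not
  modelled as random effects, so p-values for the early-treatment factor
  inherit the usual split-plot anti-conservatism.  This mirrors standard
  practice in the motivating design rather than correcting it.
- FA indices beyond FA1/FA2/FA10 are not implemented.
- The CV-equality `modified_slrt` uses a bootstrap Bartlett correction
  rather than an analytic small-sample adjustment; with the default 400
  bootstrap draws its p-values carry Monte-Carlo noise of a few percent
  of their value.
- Species-level correlations at n = 8 points have low power; the
  `low_power` flag is informational, not a correction.
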