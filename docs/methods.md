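# Methods

## Model

`gaode` implements a generative averaged one-dependence estimator (AODE)
over continuous attributes. Training data for each class is summarized by

* one univariate Gaussian mixture per attribute — the marginal
  f(Xᵢ = xᵢ | class); and
* one bivariate Gaussian mixture per unordered attribute pair — the joint
  f(Xᵢ = xᵢ, Xⱼ = xⱼ | class).

Conditional densities f(Xᵢ | Xⱼ, class) are obtained by dividing the joint
by its *own implied marginal* in the conditioning coordinate (the mixture of
the components' univariate marginals with the same weights). Using the
joint's implied marginal rather than the separately fitted univariate
mixture guarantees each conditional integrates to one; the separately
fitted marginal appears only as the leading factor of each likelihood term.

The class likelihood of an instance is the sum over present attributes j of
f(xⱼ|class) · Πᵢ≠ⱼ f(xᵢ|xⱼ, class), with both the sum and the products
restricted to the present attributes. With exactly one present attribute
the product is empty and the likelihood is the marginal density. The sum is
used exactly as written (no 1/n averaging); consequence: likelihood scales
depend on how many attributes are present, so reliability scores should be
compared among instances with comparable missingness — the missingness
profile reports groups by exact missing-attribute set for this reason.

Posterior probabilities are prior-weighted likelihoods normalized across
classes (the binary case is ordinary Bayes' rule; more classes normalize
the same way). Priors default to uniform and can be overridden at
classification time; zero priors are allowed there (they pin the posterior)
but a trained model always stores strictly positive priors.

The reliability score is SRS = log₁₀ max_class L(class | x). It ignores
priors and normalization by construction: it measures the absolute density
fit of the instance under the best-fitting class, which is precisely the
information the normalized posterior discards. With a single attribute it
reduces to the max of the per-class log marginal densities; for a
single-class model with one bivariate joint it reduces to
log₁₀(2 · joint density), which makes closed-form checks easy: with the
standard bivariate ρ = 0.9 joint, the Mahalanobis terms at (1,1) and (1,−1)
are 0.2/0.19 and 3.8/0.19, so the score gap is (20 − 1.0526)/(2 ln 10) =
4.1144 log₁₀ units.

## Numerical choices

* All densities are evaluated in natural-log space with log-sum-exp over
  mixture components and over the AODE terms, then converted to base-10
  logs at the interface. A point 30 sd from a component mean still returns
  a finite log density.
* EM fitting uses scikit-learn's `GaussianMixture` with `reg_covar = 1e-6`,
  three seeded restarts per component count k ≥ 2, and BIC selection over
  k = 1..`max_components` (default 5). Ties in BIC resolve to the smaller k.
* Variances are floored at `1e-8 × (data range)²`; 2-D covariances are
  symmetrized and their smallest eigenvalue is lifted to the same floor.
  This prevents degenerate spikes on near-duplicate values.
* Marginal fits use all present values of the attribute; joint fits use
  pairwise-complete rows. Nothing is imputed.
* Optional standardization (off by default) centers/scales each attribute
  by training-set mean and sd over present values; the parameters are
  stored in the model and applied identically to application data.
* Posteriors are computed by softmax on log-likelihoods plus log priors; if
  every class underflows to −∞ (possible only for inputs overflowing the
  quadratic form), the row abstains with SRS = −∞ instead of emitting NaNs.
* Models serialize to versioned JSON at full double precision; the SHA-256
  of the canonical serialization is the model fingerprint embedded in
  result files. The shift test compares fingerprints and refuses to test
  scores from different models against each other.

## Statistical tests

* Welch's t (unequal variances, two-sided) via scipy; an error is raised if
  both samples have zero variance.
* Mann-Whitney U (two-sided, ties counted ½). For n·m ≤ 200 the p-value is
  exact: a dynamic program over doubled midranks counts the full tied-rank
  permutation distribution (counts stay below 2⁵³, so the arithmetic is
  exact); above that, scipy's tie- and continuity-corrected normal
  approximation is used. The exact branch is verified against brute-force
  enumeration of labelings in the test suite.
* The SRS ROC sweeps thresholds over all distinct scores; the trapezoid AUC
  equals U/(n·m) (ties ½) and this identity is asserted internally on every
  call.

## Synthetic scenarios

The generators define the study conditions the package is validated under;
all are pure functions of (parameters, seed).

* **Two-class 1-D** (`gen_1d_two_class`): N(−1, 0.2²) vs N(+1, 0.2²), 1000
  per class. The midpoint lies 25 within-class sd from either mean, so the
  closed-form SRS at x = 0 is −5.1288 against 0.2999 at the class means.
* **Two-attribute presets** (`preset_2d`): "X-like" (independent, separated
  classes), "Y-like" (overlapping classes with correlations ±0.9) and
  "Z-like" (bimodal vs broad) exercise the qualitative contrast between
  marginally typical and jointly typical instances. The exact parameter
  values are this package's own choices.
* **Three-class morphology-style table** (`gen_multiclass_unknown`): seven
  traits from a one-factor model (loading 0.3, noise sd 0.2 → within-class
  trait correlations ≈ 0.7, mimicking the strong correlations of seed
  morphology measurements), class means at −u, 0, +u along a positive
  direction u so class 1 is componentwise intermediate; 70 per class with a
  stratified 35/35 train/test split. Spacing 1.0 puts neighboring classes
  ≈ 2.8 within-class sd apart per trait.
* **22-attribute cohorts** (`gen_cohort_shift`): binary-class multivariate
  normals sharing a random (seed-fixed, rank-5) correlation matrix; the
  classes differ by 0.8 sd on 8 of 22 attributes. The training table has
  800 rows per class; each test cohort has 800 rows, class-balanced. The
  mismatched cohort is translated by `shift` (default 0.35 sd on every
  attribute — a modest systemic offset, like sex differences across a
  hematology panel) and its class separation is multiplied by
  `separation_scale` (< 1 reproduces the shrunken-separation failure mode).
* **Informative vs noise attributes** (`gen_informative_noise`): five
  informative attributes (tight per-class Gaussians, sd 0.4, class means
  ±0.5) and three noise attributes (N(0,1), identical for both classes),
  500 per class. The informative attributes being more *concentrated* per
  class than the noise attributes is what makes their absence costly: each
  present informative attribute contributes ≈ log₁₀(1/0.4) ≈ 0.4 more
  log-density than a noise attribute, so removing three informative
  attributes lowers the SRS by ≈ 1.2 on average relative to removing the
  three noise attributes.
* **Missingness injection** (`inject_missingness`): exact-set removal,
  k-random-from-candidates removal per row, or i.i.d. per-cell rate; a row
  may never lose all attributes.

What the generators deliberately do not emulate: heavy tails, skew,
discrete or bounded attributes, missingness that depends on the values
(MNAR), and class imbalance. Passing the validation suite shows the
machinery behaves correctly under its own Gaussian assumptions; it does not
certify performance on real data violating them.

## Validation protocol and problem sizes

The end-to-end checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use these sizes, chosen to make the expected
effects decisive at desk scale:

* Two-class 1-D: 20 training seeds, pointwise medians of the posterior
  curve on a 401-point grid over (−20, 20) and of the SRS at x ∈ {−1, 0, 1}.
  Medians over seeds are used because the SRS at the midpoint is evaluated
  25 fitted-sd from the nearest mean, where the log-density error is
  ≈ (z² − 1) × (relative sd-estimation error) — about ±0.24 log₁₀ per seed
  at n = 1000/class — and the max over the two classes adds a small upward
  bias; the median over 20 seeds tightens this to a usable check.
* Unknown-class: 20 seeds × 3 leave-one-class-out models,
  `max_components = 2`; the generated classes are single Gaussians with a
  single latent factor, and BIC at 35 training rows essentially never
  supports more components, so the cap only removes EM work.
* Cohort shift: 20 seeds with `max_components = 1` (multivariate-normal
  classes), plus 20 zero-shift seeds for null calibration.
* Missingness: 20 seeds, independent training and test draws, Welch test
  between the informative-removed and noise-removed groups.

Per-seed success criteria (median ordering, p-value thresholds, AUC > 0.9)
are required in at least 18 of 20 seeds, which tolerates the occasional
unlucky draw without hiding a systematic failure.

## Known limitations

* Pairwise joints capture only second-order structure per class; with many
  attributes or strong higher-order dependence, the one-dependence sum can
  miss structure (dimension reduction before modeling may serve better).
* The SRS cannot flag mismatch that moves instances of one class into
  regions where they look like valid members of *another* class — shrunken
  class separation degrades classification while leaving densities
  plausible.
* SRS scales shift with the number of present attributes; comparisons
  should hold missingness roughly constant (the missingness profile groups
  by exact pattern for this reason).
* No abstention threshold is defaulted: workable SRS cutoffs are
  application-specific and must come from the user.
* Attributes must be continuous; discrete or ordinal attributes are out of
  scope.
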