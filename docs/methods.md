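# Methods

## Relative quantitation model

GC-MS signal for a compound is assumed proportional to the mass reaching the
column. A split ratio `r` vents `r` parts per part on-column, so the
on-column fraction is `1/(1+r)`; the calibration line is forced through the
origin because signal must vanish when nothing reaches the column. The
ordinary least-squares slope of integral against on-column fraction is the
mass ionization coefficient (counts per unit split-normalized mass);
dividing by molar mass gives the molar coefficient used for closure. The
x-axis convention and the zero intercept are isolated in
`quant.on_column_fraction` / `quant.fit_standard_curve` so either choice can
be revisited without touching anything downstream. A standard series whose
fitted slope is not positive is flagged invalid and its compound excluded
from closure (only known, calibrated compounds are quantified; exclusions
are logged).

Quantitation-ion selection supports two orthogonality rules for coeluting
compounds: the operative tenfold test (target intensity at an ion ≥10× that
of every coeluter) and the share form (target's share of summed intensity
≥ `thres_ortho`, 0.9 ⇔ a ninefold margin). Tenfold is the default; ties
break to the lower m/z so selection is deterministic. If no ion passes, an
explicit unresolvable-coelution error names the compound pair — silent
misquantitation is never preferable.

The detection test asks, per compound, whether its mean mole fraction
exceeds zero: observations farther than six sample standard deviations from
the sample mean are removed in a single pass (leave-in statistics, not
iterated — the minimal deterministic reading), then a one-tailed one-sample
t-test is Holm-corrected across compounds at α = 0.05. Note a consequence of
leave-in statistics: a lone outlier can reach at most `(n−1)/√n` sample SDs,
so single-spike removal is only possible for n ≥ 37; the tests therefore
exercise the rule at n = 50, where a lone spike sits 6.93 SDs out. Compounds
with constant observations carry no sampling variance and are assigned p = 0
(mean > 0) or p = 1 (mean ≤ 0) rather than an undefined t statistic.

## Summary metrics

DBI and mean chain length are mole-fraction-weighted means over a basis
pool, by default the even-chain fatty acids with the pool renormalized to 1
so each metric is a true weighted mean; a flag widens the basis to all fatty
acids. Renormalization means fatty alcohols and OCFAs can never move DBI or
chain length under the default basis (a tested invariant). Saturation-class
totals partition the fatty-acid fraction (alcohols excluded), so
SFA + MUFA + PUFA + alcohol closes to 1.

## Phylogenetic regression

Residual correlation between tips i and j is `exp(−α·d_ij)`, the stationary
Ornstein–Uhlenbeck tip correlation, with `d_ij` the patristic distance.
Numerical and statistical choices:

- **Tree height is normalized to 1** before analysis, so α (inverse
  distance) is comparable across trees.
- **Individuals attach as terminal polytomies** at ε = 10⁻³ × tree height
  (configurable). ε = 0 would duplicate correlation rows (conspecifics
  perfectly correlated) and make the matrix singular, so it is rejected.
- **GLS is solved by Cholesky whitening plus QR** — the covariance matrix is
  never inverted explicitly. σ² is profiled analytically: the reported
  log-likelihood uses the ML variance (RSS/n), while coefficient covariance
  uses the unbiased variance (RSS/(n−p)) so slope t-tests carry n−2 degrees
  of freedom and the identity-correlation case reproduces ordinary
  least-squares standard errors exactly. Two-sided p-values throughout.
- **α is profiled per regression** over ln α ∈ [−6, 6] on a 13-point grid
  with golden-section refinement (tolerance 10⁻⁴ on ln α), and the identity
  correlation (α → ∞, an ordinary regression) is always evaluated as an
  explicit candidate, so zero phylogenetic signal is exactly reachable
  rather than approximated at the grid bound.
- Rank-deficient designs, non-positive-definite correlations, constant
  predictors and n < 3 are rejected with specific errors.

Slicing decorrelates the predictors: depth regressions use specimens at
≤7.5 °C, temperature regressions specimens at ≤200 m, both bounds inclusive
(a strict-bound flag exists). Specimens in neither slice are excluded from
environmental regressions but kept for summaries and intercorrelations.
Holm families are {responses in one panel} × predictor for the battery, all
rows of one species for per-species OLS, and all pairs for
intercorrelations. Per-species fits use ordinary regression (α fixed at the
identity limit): within a species there is no phylogenetic structure.

## Synthetic surveys

The generator emulates a ~105-specimen, 21-species survey spanning polar,
temperate and tropical water columns, with every ground-truth quantity
recorded before instrument noise.

- **Trees**: coalescent-style random binary ultrametric trees, height 1.
- **Water columns**: T(z) = T_deep + (T_surf − T_deep)·exp(−z/z_scale) per
  locale — monotone and bounded, matching the shape of real profiles
  without claiming oceanographic fidelity. Defaults: arctic (5 → −1 °C,
  z_scale 150 m), temperate (15 → 1.5 °C) and tropical (28 → 1.5 °C),
  rotated across species; within each species half the individuals are
  collected shallow and half deep, so the shallow-warm, shallow-cold and
  deep-cold strata — and hence both analysis slices — are always populated.
- **Compositions**: per compound, latent coordinate = baseline logit +
  species OU effect (one stationary multivariate-normal draw per compound
  from σ²·exp(−α·D), exact rather than path-simulated) + β_depth·(z/1000 −
  z₀) + β_temp·(T − T₀) + individual Normal(0, noise_sd); softmax maps each
  individual's latents to the simplex. The log-ratio link keeps profiles
  valid while environmental effects stay linear where the regression model
  assumes them.
- **Reference state**: baselines are anchored mid-survey (T₀ = 14 °C,
  z₀ = 1.5 km). Softmax is convex in each coordinate, so an effect anchored
  at one extreme of a 28 °C / 4 km range inflates the favored compound's
  share toward the other extreme and distorts class totals; centering keeps
  compositions near the baseline over the sampled range.
- **Effect sizes**: the survey being emulated does not report slopes in
  natural units, so the defaults are configuration, not constants. They
  were chosen once, via the softmax-link gradients of each summary metric,
  so that the emulated survey reproduces the reported direction and
  evidence strength of the headline effects at the study's sample size:
  unsaturation (DBI, driven by C18:1 with weaker PUFA terms) rises with
  depth; chain length rises with temperature through a mass-conserving
  C14:0 ↔ C18:0 exchange (β₁₄ = −1.6·β₁₈ balances the baseline fractions
  0.05/0.08 to first order); C17:0 exchanges against C17:1 with warmth; the
  C22:1 fatty alcohol declines with both depth and temperature. Defaults:
  σ_OU = 0.5, α = 2 (per unit tree height), individual noise SD = 0.1.
- **GC-MS fixtures**: standards at eight split ratios on exact lines through
  the origin (optional relative Gaussian noise); sample peak integrals equal
  true mole fraction × molar coefficient × a per-sample injection scale, so
  noise-free closure recovers the truth to machine precision. Synthetic
  electron-impact spectra anchor saturated FAMEs at m/z 74, monounsaturates
  at 55, polyunsaturates at 79 and alcohols at 83, with the molecular ion
  retained; the C20:5/C22:6 pair is marked coeluting and shares its base
  peak and a mid-mass fragment, forcing quantitation onto the molecular
  ions.

What the generator does **not** emulate — and therefore what passing tests
do not establish about field data: chromatographic artifacts (retention
drift, detector saturation, the antioxidant's oxidation products), dietary
or seasonal composition structure beyond the smooth OU + linear model,
non-monotone or laterally varying water columns, measurement error on depth
and temperature, and missing compounds below detection limits. Tests
demonstrate that the estimators recover what this model injects, not that
the model is the ocean.

## Problem sizes in tests and the acceptance script

Calibration studies use 200 replicates each: slope recovery at 20 taxa ×
10 individuals (the CI-coverage band 190 ± 10 of 200 is the binomial 95%
range at nominal coverage), familywise error at 12 taxa × 6 individuals on
fully null simulations. The GLS oracle comparison uses 100 random instances
at n ≤ 8 against an explicit dense-inverse implementation; Holm is checked
against a textbook step-down oracle on all permutations of random p-vectors
up to length 8. These sizes make the whole suite a desk-scale run while
keeping Monte-Carlo bands tight enough to detect real miscalibration.

## Known limitations

- The OU correlation with a single profiled α on the ε-expanded tree is a
  one-parameter approximation to the generating individual model (species
  OU plus i.i.d. individual noise implies a within-species correlation
  σ²/(σ² + noise²) that the expanded tree mimics only near the fitted α);
  CI coverage is nonetheless within the nominal band at the tested sizes.
- Holm guarantees familywise control within each family; across the seven
  battery families the union error rate is correspondingly larger. Family
  membership is configurable.
- Compositional closure induces spurious negative correlation among
  fractions; intercorrelations are reported as fitted, without a closure
  correction (log-ratio analysis of the latent space is available through
  the ground-truth tables for synthetic data).
- The α profile likelihood can be flat when n is small or phylogenetic and
  environmental structure are confounded; `alpha_hat` is reported so flat
  profiles are visible (values at the search bound or ∞ deserve caution).
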