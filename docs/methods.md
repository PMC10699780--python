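# Methods

## Scope and model overview

`reefres` analyzes how seabird-derived nutrient subsidies affect coral reef
recovery after a mass bleaching event, at three scales:

* **colony** — planar-area growth of tagged branching *Acropora* and its
  relationship to symbiont δ¹⁵N (the tracer of seabird nitrogen);
* **island** — a hidden-state reconstruction of monthly *Acropora* percent
  cover between the post-bleaching (April 2018) and recovered (May 2021)
  surveys;
* **community** — composition of the benthos over nine functional groups and
  its Bray-Curtis distance to the pre-bleaching (2015) baseline, plus
  recruit densities from quadrat counts.

Because the original field tables are not redistributable, the package ships
a first-class synthetic-data generator that emulates the study design; every
estimator is validated by parameter recovery against the generator's known
truth.

## Synthetic survey generator

**Design.** Twelve islands in three atolls, six per treatment (`seabird` =
rat-free, `rat` = rat-infested), assigned round-robin so each atoll holds
both treatments.  Natural colonies are tagged at 5 seabird and 4 rat islands
(5–7 per island); the transplant experiment uses two seabird/rat island
pairs within atolls, five fragments per origin×transplant cell per island
(each island hosts five same-origin and five cross-origin fragments).
Recruit surveys use 12 quadrats of 0.25 m² at 5 islands per treatment;
benthic surveys use four transects of 120 point intercepts at all 12
islands in 2015, 2018 and 2021.

**Growth.** Planar areas accumulate additively: `A[k+1] = A[k] + rate ×
days/365.25`, with the annualized rate lognormal.  Its expected log is

    ln(base) + ln(fold) · [seabird arm] + ln(2.1) · (δ¹⁵N − island-year mean)
    + atoll + island + colony + year + ε

with treatment folds 2.0 (transplant arms) and 2.4 (natural islands), and
bases of 42.5 cm²/yr (experimental fragments) and 58.8 cm²/yr = 4.9
cm²/month (natural colonies at rat islands, matching the island-scale
growth parameterization below).  Effects are injected on the log scale
because the study-scale estimands are fold-changes.  Variance components
(log scale): residual 0.30, colony 0.12, island 0.15 (natural mode only),
atoll 0.05, year 0.10.  These within-island scales are not reported by any
survey; they were chosen once as plausible for repeat coral growth
photography and are what the coverage tests certify — recovery under these
noise levels, not under field noise.

Two deliberate simplifications:

* Growth responds to the colony's *measured* contemporaneous δ¹⁵N deviation
  from its island-year mean nutrient status.  There is no separate assay
  error layer: adding one would make the measured isotope value an
  error-in-variables covariate and attenuate every recovered slope below
  the injected truth, defeating the generator's purpose as a
  known-truth testbed.
* The experimental mode carries no island-level random effect beyond the
  transplant treatment itself (fragments at an island share one reef
  patch); colony, atoll, year and residual terms remain.

**Isotopes.** Natural-island symbiont δ¹⁵N means are 7.2 ‰ (seabird) and
6.3 ‰ (rat) — a 0.9 ‰ treatment difference — with island jitter SD 0.2,
persistent colony deviations SD 0.35 and yearly wobble SD 0.1.  Transplant
cells follow fixed yearly median targets over experiment years 0/1/3:
rat→seabird rises 6.0 → 7.0 → 8.0, seabird→rat falls 7.3 → 6.1 → 5.5, and
same-island cells hold at 7.8 / 5.9, modeling acclimation as linear drift
between origin and destination means (the data constrain only the medians,
not the functional form).

**Recruits.** Counts are zero-inflated Poisson with structural-zero
probability 0.5 (reproducing the observation that half the islands yielded
no *Acropora* recruits) and the Poisson mean inflated by 1/(1−0.5), so the
marginal mean equals density × quadrat area exactly.  Default *Acropora*
densities: 0.52 (seabird) and 0.68 (rat) recruits m⁻² yr⁻¹; an "other"
genus fills the total to 2.8 m⁻² yr⁻¹.

**Benthos.** Each island-year draws its composition from a Dirichlet
centred on the treatment-year profile (concentration 150, giving realistic
island-to-island scatter); transects are multinomial over that composition.
The default profiles are anchored to the reported category medians: hard
coral ≈31 % pre-bleach falling to ≈18–21 % and recovering by 2021; a
calcifying-algae (CCA + *Halimeda*) boom-and-bust at seabird islands;
pavement dominance at rat islands; a late rise in rubble.  These profiles
reproduce the ≈0.21 seabird-minus-rat difference in 2018 Bray-Curtis
distance to baseline.  They do not reproduce the reported *sign* of the
2021 difference (an island-level model estimate of −0.09): with
category-median anchors the seabird community remains slightly further from
baseline in 2021.  That contrast is outside what the generator calibrates.

**Cover endpoints.**  Per-island 2018 (C₁) and 2021 (M) *Acropora* cover
feed the reconstruction.  Treatment-level defaults are M = 18 % (seabird)
and 13 % (rat) — consistent with recovery to at-or-above pre-bleaching
cover — and C₁ = 1.1 % and 0.25 %, reflecting near-total loss of branching
*Acropora* on these shallow lagoonal reefs.  C₁ was calibrated once, before
the acceptance tests were written, so that the reconstruction under the
default rates and priors reproduces the reported recovery medians; the
calibration is flat over a wide C₁ range (0.9–1.3 % and 0.175–0.325 %), and
the defaults sit at the plateau centres.  Island endpoints spread
multiplicatively (×0.85 … ×1.15) with the M/C₁ ratio preserved, so the
median island carries the treatment value.

**Determinism.** Every table draws from a named substream derived from the
global seed via a CRC32 stream key (`config.substream`), so adding a table
never perturbs another's draws and identical configs are byte-identical.

## Hierarchical contrast estimator

A normal linear model with any number of random-intercept terms:

    y = Xβ + Σ_k Z_k u_k + ε,  ε ~ N(0, σ²),  u_k ~ N(0, σ_k²)

with β ~ N(0, 10²) (vague on the log/per-mil scales used), and σ, σ_k ~
half-normal(1) — weakly informative for outcomes of order 1.  The mean
layers are conjugate and Gibbs-sampled (blocked β via Cholesky, group
effects via `bincount` sums); the standard deviations take random-walk
Metropolis steps on the log scale (proposal SD 0.35, acceptance typically
0.2–0.7).  Defaults: 4 chains × 3000 iterations, 1000 burn-in.

Contrasts are treatment-coded with explicit interaction columns; a contrast
"averaged over" a second factor weights its levels equally.  Fold-changes
exponentiate the log-scale contrast; intervals are central posterior
quantiles.  Negative growth rates are legitimate output of
`planar_growth_rate` (shrinkage, partial mortality) but are excluded from
log-scale fits with the exclusion count reported on the estimate.

The growth-per-δ¹⁵N slope model deserves its own notes, because the naive
regression is confounded: the between-island δ¹⁵N gradient carries
island-scale treatment effects on growth, and natural and experimental
colonies share islands with opposite-sign offsets in both variables.  The
fit therefore conditions on colony type, island treatment and their
interaction as fixed effects, groups observations at the island×colony-type
sampling unit, and includes the site-mean δ¹⁵N as a contextual (Mundlak)
covariate so the reported slope is the within-site, colony-level effect.
Grouping for the other contrasts follows the survey structure: island
within atoll (isotopes); colony within atoll plus year (experimental
growth); colony within island within atoll plus year (natural growth).
Parameter recovery over 500 default-calibration datasets shows ≤3 % median
bias and 95–96 % coverage of nominal 95 % intervals for all five estimands
(the acceptance test recomputes this).

## Island-scale Gompertz reconstruction

The sampler is a forward (prior-predictive) simulation of the hierarchical
state-space model — there is no data-likelihood conditioning step, because
the survey endpoints enter as the anchor C₁ and the mean final cover Mμ.
Per chain-iteration it draws the four precisions from their gamma priors,
then per month draws M_t, G_t, R_t from their normals (negative draws
floored at 10⁻⁶ rather than rejected — rejection would distort the stated
distributions more at these precisions) and propagates

    C[t+1] ~ N(M_t · exp(−ln(M_t/C₁) · e^(−G_t (t+1))) + R_t, 1/Cτ) T(0,100)

via inverse-CDF truncated-normal sampling (`ndtr`/`ndtri`), keeping all
cover strictly inside (0, 100).  One Cτ draw serves a whole
chain-iteration.  The time grid is monthly, t = 0 at April 2018, T = 37
(May 2021).  Post-burn-in iterations across chains are pooled (8000 draws
at the defaults).

Design choices where the formulation was genuinely open:

* **Gompertz form.**  The default expectation is the
  initial-condition-anchored Gompertz (exponent −ln(M/C₁)·e^(−Gt)), which
  satisfies C(0) = C₁, has asymptote M + R, and reproduces the 8-vs-18
  month ordering under the default rates; an alternative literal variant
  with exponent −ln(ln(M/C₁)/G)·e^(−Gt) is available via `form="literal"`
  for comparison.
* **Units of G and R.**  G enters the exponent as its percent-cover
  form (cm² m⁻² month⁻¹ ÷ 100 → 0.4032 / 0.1764 month⁻¹); R is added
  directly on the percent-cover scale at its nominal cm²/month magnitude
  (0.173 / 0.227).  Both the raw and percent forms are stored on
  `RateParams` so either convention can be inspected.
* **Recruit area.**  4 cm² per recruit — back-solved exactly from the
  printed (annual density, monthly R) pairs and overridable.
* **Threshold.**  Recovery is 90 % of each draw's own mean final cover
  (`fraction × mean(M_t)`), reported as the first integer grid month at or
  above it (whole-month reporting); draws that never cross are censored at
  T, excluded from the median, and counted.  Treatment-level summaries pool
  island medians (median of medians) with intervals from the pooled
  crossing draws.
* **R is an additive per-evaluation offset**, not cumulatively integrated —
  it represents the standing contribution of recent recruitment to cover.

In the degenerate-prior limit (infinite precisions) the sampler collapses
exactly onto the deterministic Gompertz curve; the analytic crossing time
(1/G)·ln(ln(M/C₁)/ln(1/f)) is the test oracle, and the sampled recovery
month equals its ceiling on the grid.

## Benthic community statistics

Compositions pool point counts across an island-year's transects (the
per-transect compositions are retained for inspection); Bray-Curtis is
computed on these island-pooled proportions.  Recruit density per treatment
uses a stratified bootstrap: island density = counts/(quadrats × area); the
point estimate is the median of the bootstrap distribution of the mean
island density (islands resampled within treatment).  The interval is the
percentile interval of a *two-stage* hierarchical bootstrap — islands, then
quadrats within each resampled island — because with five islands of sparse,
skewed counts a single-stage percentile interval is severely anticonservative
(measured ≈0.82 coverage versus ≈0.95 for the two-stage interval).  A raw
median over five island densities is quantized to multiples of 1/3 m⁻² and
biased low for skewed counts, hence the bootstrap-median point estimate.

## Problem sizes and numerical notes

* Reconstruction: 4 chains × 3000 iterations (1000 burn-in) for 12 islands
  runs in about one second; contrast fits (n ≈ 40–100 observations) take
  ~0.1–0.3 s at 1200–3000 draws.
* The acceptance script summarizes the contrast and recruit estimators as
  medians over 60 and 300 seed-derived replicate datasets respectively:
  a single dataset at the study's sample sizes carries large sampling
  spread (e.g. SD ≈ 0.2 m⁻² for the recruit estimator), and the replicate
  median is the estimator's central recovery under the study conditions.
* Truncated-normal draws clip the uniform variate to [10⁻¹⁵, 1−10⁻¹⁵] and
  the result to (10⁻⁹, 100−10⁻⁹); in the noise-free limit in-range means
  pass through exactly, so the degenerate-prior equivalence holds to 10⁻⁹.
* Ties at the recovery threshold resolve to the earliest grid month
  (`argmax` over the boolean crossing matrix).
* `gompertz_expectation` returns M + R with a warning when C₁ ≥ M (island
  already at final cover); `closed_form_time_to_fraction` returns 0 when
  the threshold is below C₁.

## Limitations

* The generator reproduces the study's *effect structure*, not field data:
  no spatial structure within reefs, no seawater nitrate dynamics, no
  taxonomy below genus, no temporal autocorrelation in growth beyond the
  persistent colony deviation.  Passing recovery tests certify estimator
  calibration under the generator's noise model only.
* The reconstruction is a prior-predictive simulation parameterized from
  survey endpoints; it does not refit G and R from the colony tables
  (`recovery_rates` supplies them) and carries no between-island coupling.
* Posterior summaries use central quantile intervals, not highest-density
  intervals; for the unimodal, near-symmetric posteriors involved the
  difference is small.
* The multilevel beta/ZINB/skew-normal models used in the original survey
  analyses are intentionally out of scope; their estimands are served by
  the hierarchical normal contrasts and bootstrap estimators here.
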