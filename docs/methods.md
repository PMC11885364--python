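# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Models

### Width–weight and maturity

Weight follows the allometric power law fit on natural logs,
ln W = log a + b·ln DW + ε, ε ~ N(0, σ²), with DW in cm and W in kg.
Priors: b ~ N(3, 0.5) and log a ~ N(−5, 1) ("strong", centred on values
typical for mobulids), or the same means with sd 1 and 3 ("weaker");
σ² ~ half-Cauchy(0, 30 000). The half-Cauchy scale is enormous relative to
the ~0.2–0.3 log-scale residual variance, so it is effectively flat; it is
kept as stated rather than "fixed" so that prior sensitivity comparisons are
meaningful.

Maturity is a Bernoulli GLM, logit P(mature) = a + β·x, on age (years) or
disc width (cm). β ~ N(0, 10). The strong intercept prior is conditional:
a | β ~ N(−β·x50_guess, 10), which centres the ogive midpoint −a/β on a
configurable prior guess (defaults: 5.5 y for age, 200 cm for width, from
the regional literature). The published form of this prior references the
estimand itself and is ambiguous as printed; the conditional-centring
reading implemented here is a documented interpretation, not a claim about
the original code. The 50% point is summarised per draw as x50 = −a/β;
draws with β ≤ 0 flip sign, and the summary is flagged if more than 5% of
draws do so.

### Growth

Four mean functions on disc width (mm) at age t (years), all fit with
multiplicative lognormal error, ln DW ~ N(ln f(t), σ²):

* von Bertalanffy: f = DW∞ − (DW∞ − DW0)·e^(−kt)
* Gompertz: f = DW0·exp(ln(DW∞/DW0)(1 − e^(−gt)))
* logistic: f = DW∞·DW0·e^(gt) / (DW∞ + DW0(e^(gt) − 1))
* Lester biphasic: linear juvenile phase h(t − t1) for t ≤ T and a von
  Bertalanffy adult branch anchored so the phases meet at T. The published
  adult-branch equation reuses DW0 where the standard form has an age
  anchor; since the published biphasic fits did not converge and were never
  reported, the standard continuity-anchored form is implemented.

Priors (strong set, larger species): k or g ~ U(0, 2); DW0 ~ N(900, 200) mm;
DW∞ ~ N(κ·DWmax_ref, 100) mm with DWmax_ref the literature maximum size
(3500 mm / 1970 mm) and κ ~ gamma(1000, 990) hard-truncated to [0.7, 1.3]
(the truncation mechanism is a package choice; only the range is published);
σ² ~ half-Cauchy(0, 30 000). The joint prior is additionally truncated to
DW∞ > DW0 > 0. The empirical maximum-size→asymptotic-size allometry
DW∞ = 10^(0.044 + 0.9841·log10 DWmax) motivates κ's prior mean (ratios 1.01
and 1.02 at 350 and 197 cm).

Model comparison uses PSIS-LOO on the stored pointwise log-likelihood
(LOOIC = −2·elpd, with its se), with weights exp(−½ΔLOOIC)/Σ exp(−½Δ)
(pseudo-BMA without the Bayesian bootstrap; observations with Pareto
k > 0.7 are counted and reported). Fits are fingerprinted by their (age,
DW) arrays so models fit to different data cannot be compared silently.

Growth ages enter fits at 0.5-year resolution (the consensus-age scale);
the mortality pipeline rounds inverted ages to whole years.

### Demography (r_max)

The modified Euler-Lotka model with survival to maturity:
l_amat·b = e^(r·amat) − e^(−M)·e^(r·(amat−1)), l_amat = (e^(−M))^amat.
The last exponent is read as (α_mat − 1), which makes the α_mat = 1 case
collapse to the classic identity r = ln(1 + b) − M (used as a test oracle).
The root is found by Brent's method on r ∈ [−0.5, 1.5] (widened once, then a
hard error — never a silent boundary value) to 1e-8.

Inputs: b = 0.5·(l/i) from litter size and breeding interval (0.17–1 for
one pup every three years up to twins annually); M = ((α_max + α_mat)/2)⁻¹;
α_max from growth-curve longevity, 5ln2/k (age at 95% DW∞, von Bertalanffy)
or ln(99·DW∞)/g (age at 99% DW∞, logistic). The logistic formula is
unit-dependent and is evaluated with DW∞ in millimetres, which reproduces
the published longevities (69.3 and 64.3 y); DW0 cancels algebraically.

Monte Carlo: 10,000 independent uniform draws of b, α_mat, α_max; the
2.5/97.5 percentiles of M over those draws set the bounds of a symmetric
triangular distribution from which M is drawn (the mode is not recoverable
from the published description; the midpoint is the default and is
configurable, and the 5/95 percentile variant is exposed). r_max is solved
per draw; medians and 95th-percentile intervals are reported.

### Mortality and exploitation

Chapman-Robson on the recoded ages x = age − first_used_age:
S = T/(N + T − 1), Z = −ln S. The default first used age is the modal
(peak) age + 1, the recommended convention for fishery catch curves; the
peak itself is selectable. The small-sample bias correction
Z − (N−1)(N−2)/(N(T+1)(N+T−1)) with the overdispersion-robust se
√((1−e^(−Z))²/(N·e^(−Z))) is the default; the uncorrected estimator with
the delta-method se is available side by side. A = 1 − e^(−Z).

F and E are propagated by paired draws — one Z ~ N(Z, se) and one
M ~ U(bounds) per iteration, F = Z − M, E = F/Z — because the paired design
reproduces the published medians; the published 95th percentiles of F imply
a wider spread whose distributional origin cannot be recovered from the
text, so percentiles of F/E are reported but not asserted. Negative Z draws
are retained (negative E percentiles are representable) and counted.
P(E > 0.5) uses a strict inequality.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Age structure**: discrete geometric over integer ages from the recruit
  age, P(age = recruit + x) ∝ e^(−Z·x), truncated at max_age — the
  discrete-exponential population every catch-curve estimator assumes. A
  configurable pre-recruit fraction (default 0.15) mixes in uniform younger
  ages so synthetic catch curves have an ascending limb.
* **Sizes**: the species growth curve times e^ε, ε ~ N(0, σ²_log), with
  σ²_log at the fitted residual-variance scale (0.12 / 0.10). Sizes are not
  truncated at the species maximum, so a thin upper tail beyond the largest
  observed animals is expected.
* **Weights**: the power law on realised sizes with lognormal error
  (variance 0.27 / 0.23).
* **Maturity**: Bernoulli from the age ogive; sex from the profile's sex
  ratio.
* **Age reads**: per reader × section, true age + N(0, error_sd²), rounded
  to the nearest 0.5 year and floored at 0. No reader-error distribution is
  published; the normal model is a stand-in and its sd a free test
  parameter (default 0.5 y).

Bundled species profiles carry the fitted posterior means as generator
truth (von Bertalanffy k = 0.05, DW0 = 1166.53 mm, DW∞ = 3502.95 mm and
Z = 0.215 for the spinetail profile; logistic g = 0.19, DW0 = 870.21 mm,
DW∞ = 2022.11 mm and Z = 0.232 for the bentfin profile), so
parameter-recovery tests exercise the realistic regime.

What passing tests therefore show: the estimators are correct and
well-calibrated for a population that exactly meets their assumptions
(closed population, constant recruitment, knife-edge selectivity,
independent lognormal size error, unbiased readers). What they do not show:
robustness to gear selectivity that varies with size, to non-annual band
deposition, to reader bias, or to spatial/temporal population structure —
none of which the generator emulates. A visible consequence: inverting a
slow growth curve on noisy sizes flattens the reconstructed age structure,
so the default demo pipeline's Z estimate sits well below the generating
Z; the estimator-level recovery tests use noise-free sizes to isolate the
catch-curve machinery, which then recovers Z within 2 se.

## Computation

All fits use the affine-invariant ensemble sampler (emcee; 80/20 mixture of
differential-evolution and snooker moves, 32 walkers, 4000 steps with 1500
burn-in and thinning 2 by default), vectorised log posteriors, and
arviz diagnostics on the walker ensemble: the contract is R̂ < 1.05 and
ESS > 400, enforced with a hard `ConvergenceError` naming the worst
parameter. σ² is sampled on the log scale (with the Jacobian, leaving the
stated half-Cauchy prior on σ² itself) so chains mix even when the
posterior concentrates near zero variance; regression fits start from the
OLS solution jittered at the scale of its standard errors. Exactly
degenerate inputs (a single age, one maturity class, all fish in one age
class) raise errors rather than returning boundary values.

Problem sizes used in the test suite — 10,000 Monte Carlo draws, 79-point
growth samples (20 recovery replicates), a 20-point dataset for the exact
leave-one-out cross-check — match the scale of the analyses the package
targets while keeping the full suite to a few minutes.

## Known limitations

* The r_max model is unstructured (no Leslie matrix); it is not comparable
  to age-structured life-table estimates and is intended for data-poor
  settings.
* Fits pool sexes and locations; no sex- or site-stratified growth.
* The M mode inside its triangular bounds, the exclusive-vs-cumulative
  reading of PA ± 1, and the sd-vs-CI-of-mean reading of the limits of
  agreement are each ambiguous in the source material; both variants are
  exposed where relevant, with the defaults documented above.
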