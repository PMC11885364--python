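# devilray

Demographic analysis toolkit for data-poor devil ray (*Mobula*) fisheries.

Devil rays are among the most intrinsically sensitive chondrichthyans to
fishing: a single pup per litter every one to three years, slow growth, and
late maturity. Assessing whether observed fishery catch is sustainable
requires stitching together several estimators, each of which this package
implements as a tested, reusable module:

* **synthetic_data** — a specimen/age-read generator with the statistical
  structure the downstream analyses assume (exponential age structure under
  total mortality *Z* with knife-edge recruitment, growth-curve sizes with
  multiplicative lognormal error, allometric weights, logistic maturity,
  paired reader band counts), so every stage is testable without field data.
* **aging_agreement** — consensus ages from paired vertebral band counts,
  Bland–Altman bias regression and limits of agreement, and the standard
  precision metrics (APE, CV, PA, PA ± 1 year).
* **size_weight_maturity** — Bayesian log-linear disc-width–weight regression
  (ln *W* = log *a* + *b* ln *DW*) and Bayesian logistic maturity ogives with
  per-draw age/size-at-50%-maturity summaries.
* **growth** — Bayesian multi-model growth fitting (von Bertalanffy,
  Gompertz, logistic, biphasic Lester) on log-scale disc-width-at-age, with
  an asymptotic-size prior built from literature maximum size through a
  truncated-gamma hyperparameter κ, and PSIS-LOO (LOOIC) model comparison.
* **demography** — the modified Euler-Lotka solver for the maximum intrinsic
  rate of population increase,

  ```
  l_amat · b = exp(r_max · α_mat) − exp(−M) · exp(r_max · (α_mat − 1)),
  l_amat = exp(−M · α_mat),   M = ((α_max + α_mat)/2)⁻¹,
  ```

  with 10,000-draw Monte Carlo propagation of the uncertainty in *b*,
  α_mat, α_max (uniform) and *M* (symmetric triangular on the derived 95%
  bounds).
* **mortality** — Chapman-Robson catch-curve estimation of *Z* (peak-plus-one
  convention, bias-corrected), annual mortality *A* = 1 − e^(−Z), and paired
  Monte Carlo distributions of fishing mortality *F* = *Z* − *M* and the
  exploitation ratio *E* = *F*/*Z*, with sustainability flags against
  *r*_max (≙ *F*_extinct) and the *E* = 0.5 (*F* = *M*) reference point.
* **pipeline / cli** — a `devilray` command that chains
  simulate → consensus ages → agreement → fits → model choice → r_max →
  mortality → report behind one config and seed, with a hash-checked
  manifest so reruns are no-ops.

## Worked example

```
devilray all --species mobular --seed 3 --out run1 --n-specimens 150
```

simulates a 150-animal spinetail devil ray fishery sample and runs the full
analysis. The printed report (from an actual run) ends with:

```
r_max median: 0.110 /yr (95th percentiles 0.039, 0.168)
Z: 0.100 /yr (95% CI (0.082, 0.117)), annual mortality A = 9.5%
F median: 0.050 /yr; E median: 0.50; P(E > 0.5) = 0.51

median F = 0.050 /yr vs r_max = 0.110 /yr (below r_max)
P(E > 0.5) = 0.51 (most draws above the F = M optimum)
```

Reading it: the life-history Monte Carlo says this population can grow at
most ~11% per year at low density; the catch curve built from inverting the
fitted growth model on the simulated sizes estimates total mortality
*Z* ≈ 0.10/yr (size-from-age noise flattens the age structure relative to
the generating *Z* = 0.215 — see `docs/methods.md`); subtracting natural
mortality leaves a median fishing mortality of 0.05/yr, below *r*_max, and an
exploitation ratio straddling the *F* = *M* optimum. With real landed-catch
data the same pipeline (minus the `simulate` stage) consumes specimen and
age-read CSVs in the documented dialect.

Library use mirrors the CLI:

```python
from devilray import LifeHistoryRanges, rmax_monte_carlo
draws = rmax_monte_carlo(LifeHistoryRanges.mobular(), n_draws=10_000, seed=1)
print(draws.summary())   # {'rmax_median': 0.109, ...}
```

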