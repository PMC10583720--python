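# crossfx

Cross controlled/natural direct effects with two binary mediators:
g-formula point estimation, tight nonparametric bounds, and bootstrap
inference.

## The problem

With a single mediator, the classic direct-effect estimands are the
controlled direct effect (CDE: the mediator fixed at a constant level for
everyone) and the natural direct effect (NDE: the mediator held at the
value each subject would have had under a reference exposure). With **two**
mediators M1 and M2 — for example, memory B-cell response and circulating
antibody titre after vaccination — one can *cross* the two types of
control: fix one mediator and let the other take its natural,
subject-specific counterfactual level. Effects of this kind ask questions
such as *"what would vaccination do if antibodies were removed but B-cells
kept their natural post-vaccination distribution?"* — the formal analogue
of knockout/infusion experiments in vaccine immunology.

`crossfx` implements the five cross contrasts

| estimand name | contrast |
|---|---|
| `crossA_M1nat`             | ΔE{Y(x→x′, M1(x1), m2)} |
| `crossA_M2nat`             | ΔE{Y(x→x′, m1, M2(x2))} |
| `crossB_M2ctrl_inner`      | ΔE{Y(x→x′, m1, M2(x2, m1′))} |
| `crossB_M2nat_inner_nat`   | ΔE{Y(x→x′, m1, M2(x2, M1(x3)))} |
| `crossB_bothnat_inner_ctrl`| ΔE{Y(x→x′, M1(x1), M2(x2, m1′))} |

under two causal structures: variant **A** (the mediators do not affect
each other) and variant **B** (sequential mediators, M1 → M2; the
`crossB_*` estimands only exist here). Binary X, M1, M2, Y; continuous
mediators are dichotomized first.

Two complementary analyses are provided:

* **Point identification (g-formula).** Absent residual confounding of the
  mediators and outcome, each nested mean is identified by standardizing
  outcome-model predictions over the relevant mediator law and the
  empirical covariate distribution, e.g.

  ```
  E{Y(x, m1, M2(x2, m1'))}
    = n⁻¹ Σᵢ Σⱼ P̂(Y=1 | Cᵢ, x, m1, M2=j) · P̂(M2=j | Cᵢ, x2, m1')
  ```

  with saturated (stratified-frequency) models when there are no
  covariates and logistic regressions (all two-way interactions by
  default) when there are.

* **Partial identification (bounds).** Under arbitrary residual
  confounding of (M1, M2, Y) — X randomized — each estimand is bounded by
  the min/max of a linear program over the canonical response-function
  distribution q (the Balke–Pearl construction: 4 × 16 × 256 = 16 384
  profiles under variant B, 4 × 4 × 256 = 4096 under A), subject to the 16
  observed probabilities p_{y m1 m2·x} = P(Y=y, M1=m1, M2=m2 | X=x).
  For the canonical level settings (1 vs 0 contrast, all other levels 0)
  the tight bounds are also evaluated in closed form as a max/min of a few
  linear expressions in those 16 probabilities; the LP engine generalizes
  them to arbitrary levels and serves as their independent cross-check.

Inference for both estimates and bound endpoints uses the percentile
nonparametric bootstrap.

## Worked example

Simulate a 5 000-subject two-arm vaccine trial (binary disease outcome;
B-cell response dichotomized at 1, antibody titre at 1000) and analyse the
direct effect of vaccination with antibodies removed and B-cells at their
natural unvaccinated level, ΔE{Y(1→0, M1(0), 0)}:

```sh
crossfx simulate covid --n 5000 --seed 7 --out trial.csv
crossfx effects --data trial.csv --dag B --estimand crossA_M1nat --boot 500 --seed 1
crossfx bounds  --data trial.csv --dag B --estimand crossA_M1nat --method both
```

The `effects` report (abridged):

```json
"estimate": -0.07528538266294432,
"bootstrap": {"ci_lower": -0.09532132859234076, "ci_upper": -0.0546163324287872}
```

Under no residual confounding, removing antibodies while holding B-cells
at their natural placebo-arm level, vaccination still lowers disease risk
by 7.5 percentage points (95% CI −9.5 to −5.5) — protection not mediated
by antibody titre. The `bounds` report:

```json
"symbolic": {"lower": -0.18020504731861192, "upper": 0.9018138801261829},
"lp":       {"lower": -0.180205047318612,   "upper": 0.9018138801261831}
```

Allowing arbitrary unmeasured mediator–outcome confounding, the data alone
only constrain this effect to [−0.18, 0.90]: the closed-form and LP bounds
agree to solver precision, and the interval (which must cover 0) shows how
much the point estimate leans on the no-residual-confounding assumption.

The same analyses are available as library calls (`fit_models` /
`estimate_effect`, `solve_bounds`, `bounds_result1`…`bounds_result4`,
`bootstrap`); `generate_npsem` simulates binary structural-equation data
from an explicit response-profile distribution together with the exact
ground-truth value of every estimand, which is how the test suite verifies
tightness, validity, unbiasedness, and bootstrap coverage end to end.

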