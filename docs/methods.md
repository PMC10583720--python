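# Methods

This note documents the models, conventions, and design choices behind
`crossfx`. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Causal model

Four binary variables: exposure X, mediators M1 and M2, outcome Y, with
optional measured covariates C and an unmeasured confounder set U common
to M1, M2, and Y. Two DAG variants are supported: **A**, in which the
mediators do not affect each other, and **B**, in which M1 affects M2
(sequential mediators). Each variable is a deterministic response function
of its parents and its error; the cross-direct-effect estimands are
contrasts of nested potential outcomes in which one mediator is controlled
at a constant level and the other takes a natural (counterfactual)
level — see the README table for the five contrasts and their names.

One representational convention matters: under variant B the "natural M2
at exposure x2" carries M1's natural value at the same exposure, so the
estimand written ΔE{Y(x→x′, m1, M2(x2))} is evaluated as
ΔE{Y(x→x′, m1, M2(x2, M1(x2)))}. Under variant A the inner argument does
not exist. `make_effect` resolves this automatically from the DAG tag.

## Point estimation (g-formula)

Each nested mean is standardized over the relevant mediator law and the
empirical distribution of C (always the sample distribution; no model for
C). Three conditional models are fitted: Y | C, X, M1, M2; M1 | C, X; and
M2 | C, X (variant A) or M2 | C, X, M1 (variant B).

* Without covariates the default is **saturated** models — stratified
  empirical frequencies — making the plug-in fully nonparametric. An
  empty conditioning stratum raises an explicit `EmptyStratumError` when
  (and only when) an estimator queries it; nothing is smoothed silently.
* With covariates the default is logistic regression with all two-way
  interactions among covariates, treatment, and mediators (`"two_way"`;
  `"main_effects"` is available). Non-convergence or separation triggers
  a warning and a fallback to stratified frequencies.
* The total effect without covariates is the difference of raw arm means
  of Y (the randomized-trial estimator); with covariates it is the full
  g-formula standardization with the mediator laws factored per DAG.
* Contrasts with the same exposure in both arms return exactly 0.0
  without computation.

Exact-recovery property (verified in the tests): on the full enumeration
of any unconfounded response-profile distribution — generated via
rational (dyadic) conditional laws so the finite dataset embodies the
distribution exactly — saturated plug-in estimates equal the enumeration
ground truth to 1e-10.

## Bounds

**Response-function partition.** With all variables binary and X
randomized (marginally or within strata of a categorical C, in which case
the user filters rows and reruns), all confounding of (M1, M2, Y) reduces
to a joint distribution q over response-function profiles. A variable
with k binary parents has 2^(2^k) possible response functions: 4 for M1,
4 (variant A) or 16 (variant B) for M2, 256 for Y — 4096 and 16 384 joint
profiles respectively. The enumeration order is frozen: M1-function index
slowest, then M2, then Y; within a variable, functions are ordered by
their truth table read as a binary integer (inputs lexicographic, x
slowest, first input = most significant bit). q vectors are therefore
portable across runs and implementations.

**LP engine.** The 16 observable probabilities are linear in q (one
0/1 incidence row per probability; each profile hits exactly one cell per
arm), and every estimand's objective is linear in q because nested
counterfactuals are deterministic per profile — inner natural arguments
resolve through the profile's own response functions, so counterfactuals
that share M1 (the total effect) are coherent automatically. Tight bounds
are the min/max of the objective over {q ≥ 0, Aq = p}, solved with HiGHS
in double precision (equality feasibility tolerance 1e-9). The 16
equalities are kept as stated (not reduced to 14 independent ones);
redundancy is harmless to the solver and keeps A·q = p literal. Any valid
per-arm table is feasible (the model is saturated), so a non-optimal
status is reported as an error, never worked around. The LP for the total
effect collapses to a point — the identified arm-mean difference — which
the tests assert.

**Closed forms.** For the canonical level setting (exposure 1 vs 0, all
controlled/inner levels 0) the tight bounds of four estimands (and, by
the variant-A mediator symmetry, a fifth obtained by relabelling) are
evaluated directly as a max of 3–5 linear lower expressions and a min of
3–5 linear upper expressions in the 16 probabilities. Expressions are
stored as parsed coefficient data, unit-tested term by term. Equivalence
with the LP to 1e-6, and validity (the q-implied true effect inside every
interval to 1e-8), are asserted over 200 Dirichlet-sampled compatible
distributions per variant in the acceptance tests. Other level settings
have no closed form here and route to the LP engine with a notice.
Intervals are never clipped to [−1, 1]: an excursion beyond it would
signal an invalid input and should be visible.

## Bootstrap

Percentile (quantile) bootstrap, rows resampled with replacement at the
record level; defaults B = 1000, level 0.95 (the simulation study uses
B = 500). Unstratified resampling by default with a stratify-by-arm
option; quantiles use linear interpolation of order statistics (numpy
default, R type 7). Replicates on which the statistic is undefined (an
empty arm or stratum) are redrawn up to a retry cap, then surfaced as an
error. Bound endpoints are bootstrapped as a pair over one resample
stream; each endpoint's interval is its marginal percentile interval.
The replicate vector is exposed for post-processing; BCa or
boundary-adapted intervals are out of scope (the percentile interval is
known to be unreliable when the true effect sits near a bound's boundary).

## Synthetic data

**Vaccine-trial mechanism** (defaults of `CovidParams`): X ~ Bern(0.5);
B-cell response M1 ~ Normal(0.5 + 1.0·X, variance 1); antibody titre
M2 = exp(Z), Z ~ Normal(6.5 + 0.5·X, sd 0.3); disease
Y ~ Bern(0.1) under X = 0 and, under X = 1,

    Y ~ Bern( 0.1 · { exp(−0.87 · M2 / 900) − 0.03 · M1 − 0.2 } ),

risks clipped to [0, 1] with clips counted (a warning fires above 10%;
with large titres the unclipped expression goes slightly negative for
roughly a sixth of the vaccinated arm). The braces place the antibody
titre **inside** the exponential: the variant with the titre outside
(`exponent_form="literal"`, retained as an option) produces values far
above 1 for titres around e^7 and cannot be a probability. Mediators are
dichotomized at M1 ≥ 1 and M2 ≥ 1000 (ties map to 1; the tie side is
configurable). One master seed is split into four substreams (X, M1, M2,
Y) so changing one component's parameters leaves the others' draws
untouched. At these defaults the implied overall vaccine efficacy,
measured by simulation at n = 10^6 in the acceptance checks, is ≈ 0.89.

**Response-profile generator.** `generate_npsem` draws a profile per
record from an explicit q, an exposure from Bern(p_treat), and emits the
profile's realized observation; the returned `SyntheticTruth` carries the
exact estimand values implied by q. Unconfounded means q is an outer
product of the three variables' marginal response distributions (checked
to 1e-12); helpers build such marginals from independent Bernoulli
outputs per parent configuration, from symmetric Dirichlet draws, or as
mixtures. The reference "strongly confounded" q is a 50/50 mixture of two
product components — a latent class that shifts mediator prevalence and
baseline outcome risk together — chosen so that the g-formula functional
applied to the implied observed table differs from the true effects by
0.013–0.022 across the five estimands (an analytic property of the
configuration, not a simulation outcome).

What these generators do *not* emulate: covariate-driven confounding of
the exposure (X is always randomized), missing data, measurement error in
the mediators, non-binary outcomes, and intermediate confounders
(exposure-affected mediator–outcome confounders, under which natural
effects are generally not identified). Passing tests therefore speak to
the estimators' and bounds' behaviour under the stated model, not to
robustness against those features of real data.

## Simulation study (reduced scale)

The acceptance tests run 200 replications of n = 5000 records, B = 500
bootstrap replicates, variant B, at a fixed unconfounded q (product of
symmetric-Dirichlet(1) marginals; every observable stratum has mass
≥ 0.04, so saturated plug-ins are well defined in essentially all
resamples): all five cross-effect estimators show |mean bias| < 0.01 and
percentile-CI coverage of the truth within 95% ± 3%. The same pipeline at
the strongly confounded q shows bias exceeding twice the Monte-Carlo
error for every estimand and degraded coverage. Problem sizes (200 draws
per variant for the bounds sweep, 200 × 500 for the study) are the
package's chosen verification scale — large enough for 1.5-point
Monte-Carlo error on a coverage proportion.

## Known limitations

* Closed-form bounds cover only the canonical level settings; other
  levels are numeric-only (LP).
* Bounds assume randomized X; measured covariates enter the bounds only
  via stratified reruns, not inside the LP.
* All-binary variables; dichotomization loses information in ways not
  quantified here.
* Percentile bootstrap near the boundary of the parameter space (effects
  close to the bound endpoints, or probabilities near 0/1) can
  under-cover; no boundary-adapted alternative is implemented.
* The vaccine-trial risk formula involves a documented repair of its
  typeset form (see above); its implied VE is ≈ 0.89, not exactly 0.92.
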