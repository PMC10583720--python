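"""Synthetic data generators with exact ground truth.

Two families of generators are provided:

* :func:`generate_covid_trial` — a two-arm vaccine-trial mechanism with a
  continuous memory B-cell response (M1), a log-normal circulating antibody
  titre (M2), and a Bernoulli disease outcome whose vaccine-arm risk falls
  with antibody level; the mediators are dichotomized (M1 at 1, M2 at 1000)
  for the binary analysis.  At the defaults the implied overall vaccine
  efficacy 1 - E{Y(1)}/E{Y(0)} is roughly 0.9.

* :func:`generate_npsem` — binary structural-equation data driven by an
  explicit response-profile distribution q (see :mod:`crossfx.lp_bounds`),
  with or without residual confounding, together with the exact values of
  every canonical estimand implied by q.  Unconfounded means q factors into
  independent marginals for the three response functions, in which case the
  g-formula identifies all cross effects; a confounded q is any joint
  distribution that does not factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .distributions import BinaryDataset, dichotomize
from .estimands import CROSS_EFFECT_NAMES, Dag, canonical_levels, make_effect
from .exceptions import CodingError
from .lp_bounds import (
    ProfileDistribution,
    enumerate_profiles,
    realized_observation,
    true_effects_from_q,
)

__all__ = [
    "CovidParams",
    "generate_covid_trial",
    "NpsemConfig",
    "SyntheticTruth",
    "generate_npsem",
    "summarize_trial",
    "TrialSummary",
    "response_marginal_from_probs",
    "product_q",
    "unconfounded_q",
    "strongly_confounded_q",
    "dataset_from_cell_counts",
]


# ---------------------------------------------------------------------------
# COVID-like vaccine trial


@dataclass(frozen=True)
class CovidParams:
    """Parameters of the vaccine-trial mechanism.

    X ~ Bernoulli(p_treat); M1 ~ Normal(m1_mean_base + m1_effect * X, m1_var);
    M2 = exp(Z), Z ~ Normal(logm2_mean_base + logm2_effect * X, logm2_sd);
    Y ~ Bernoulli(placebo_risk) under X = 0 and, under X = 1, Bernoulli of

        risk_scale * { exp(-ab_coef * M2 / ab_denom) - bcell_coef * M1 - risk_offset }

    (``exponent_form="exp_of_neg_ab_times_m2_over_denom"``, the default: the
    antibody titre sits inside the exponential so protection saturates with
    titre).  The alternative ``"literal"`` form,
    risk_scale * { exp(-ab_coef/ab_denom) * M2 - ... }, places the titre
    outside the exponential; with titres around e^7 it produces values far
    above 1 and is retained only for transparency.  Risks are clipped to
    [0, 1] and clips are counted.
    """

    p_treat: float = 0.5
    m1_mean_base: float = 0.5
    m1_effect: float = 1.0
    m1_var: float = 1.0
    logm2_mean_base: float = 6.5
    logm2_effect: float = 0.5
    logm2_sd: float = 0.3
    risk_scale: float = 0.1
    ab_coef: float = 0.87
    ab_denom: float = 900.0
    bcell_coef: float = 0.03
    risk_offset: float = 0.2
    placebo_risk: float = 0.1
    m1_cut: float = 1.0
    m2_cut: float = 1000.0
    exponent_form: str = "exp_of_neg_ab_times_m2_over_denom"

    def __post_init__(self):
        for name in ("m1_var", "logm2_sd", "risk_scale", "ab_denom"):
            if getattr(self, name) <= 0:
                raise CodingError(f"{name} must be positive")
        if not 0 < self.p_treat < 1:
            raise CodingError("p_treat must be in (0, 1)")
        if self.exponent_form not in ("exp_of_neg_ab_times_m2_over_denom", "literal"):
            raise CodingError(f"unknown exponent_form {self.exponent_form!r}")

    def vaccine_risk(self, m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
        """Unclipped vaccine-arm disease risk given the continuous mediators."""
        if self.exponent_form == "literal":
            ab_term = np.exp(-self.ab_coef / self.ab_denom) * m2
        else:
            ab_term = np.exp(-self.ab_coef * m2 / self.ab_denom)
        return self.risk_scale * (ab_term - self.bcell_coef * m1 - self.risk_offset)


def generate_covid_trial(
    n: int,
    params: Optional[CovidParams] = None,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, BinaryDataset]:
    """Simulate the vaccine trial; returns (continuous records, binary data).

    The continuous frame has columns X, M1, M2, Y plus the realized risk;
    the binary dataset applies the dichotomization cuts (>= threshold maps
    to 1).  One master seed is split into independent substreams for X, M1,
    M2, and Y, so changing one component's parameters leaves the other
    streams untouched.
    """
    if n < 1:
        raise CodingError("n must be >= 1")
    params = params or CovidParams()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)]
    rng_x, rng_m1, rng_m2, rng_y = streams

    x = (rng_x.random(n) < params.p_treat).astype(np.int8)
    m1 = rng_m1.normal(params.m1_mean_base + params.m1_effect * x, np.sqrt(params.m1_var))
    m2 = np.exp(rng_m2.normal(params.logm2_mean_base + params.logm2_effect * x, params.logm2_sd))

    raw_risk = np.where(x == 1, params.vaccine_risk(m1, m2), params.placebo_risk)
    risk = np.clip(raw_risk, 0.0, 1.0)
    n_clipped = int(np.count_nonzero(raw_risk != risk))
    if n_clipped > 0.10 * n:
        warnings.warn(
            f"dgp-clipping: {n_clipped}/{n} risks clipped to [0, 1]",
            stacklevel=2,
        )
    y = (rng_y.random(n) < risk).astype(np.int8)

    continuous = pd.DataFrame({"X": x, "M1": m1, "M2": m2, "risk": risk, "Y": y})
    binary = BinaryDataset(
        x=x,
        m1=dichotomize(m1, params.m1_cut),
        m2=dichotomize(m2, params.m2_cut),
        y=y,
    )
    return continuous, binary


# ---------------------------------------------------------------------------
# response-profile NPSEM generators


def response_marginal_from_probs(probs: Sequence[float]) -> np.ndarray:
    """Distribution over a variable's 2^k response functions implied by
    independent Bernoulli outputs at its k lexicographic inputs.

    ``probs[j]`` is P(output = 1 at input j); the weight of function f is
    the product of the matching Bernoulli probabilities of its truth table.
    """
    probs = np.asarray(probs, float)
    if ((probs < 0) | (probs > 1)).any():
        raise CodingError("probs must lie in [0, 1]")
    k = probs.size
    n_fun = 2 ** k
    w = np.ones(n_fun)
    for j in range(k):
        bit = (np.arange(n_fun) >> (k - 1 - j)) & 1
        w *= np.where(bit == 1, probs[j], 1.0 - probs[j])
    return w


def product_q(
    qm1: np.ndarray, qm2: np.ndarray, qy: np.ndarray, dag: Union[Dag, str]
) -> ProfileDistribution:
    """Joint q as the outer product of the three marginal response
    distributions (the unconfounded case)."""
    dag = Dag(dag)
    space = enumerate_profiles(dag)
    qm1, qm2, qy = (np.asarray(v, float) for v in (qm1, qm2, qy))
    if qm1.size != 4 or qm2.size != space.n_m2_functions or qy.size != 256:
        raise CodingError(
            f"marginal sizes must be 4, {space.n_m2_functions}, 256 for variant {dag.value}"
        )
    q = (qm1[:, None, None] * qm2[None, :, None] * qy[None, None, :]).ravel()
    return ProfileDistribution(q / q.sum(), dag)


def unconfounded_q(
    dag: Union[Dag, str],
    concentration: float = 1.0,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> ProfileDistribution:
    """Random unconfounded q: independent symmetric-Dirichlet marginals for
    the three response-function variables, combined as a product."""
    dag = Dag(dag)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    space = enumerate_profiles(dag)
    parts = []
    for size in (4, space.n_m2_functions, 256):
        g = rng.gamma(concentration, 1.0, size=size)
        parts.append(g / g.sum())
    return product_q(*parts, dag=dag)


def mixture_q(
    components: Sequence[ProfileDistribution], weights: Sequence[float]
) -> ProfileDistribution:
    """Mixture of profile distributions; mixing over distinct product
    components is the canonical way to induce residual confounding."""
    weights = np.asarray(weights, float)
    if abs(weights.sum() - 1.0) > 1e-12 or (weights < 0).any():
        raise CodingError("mixture weights must be a probability vector")
    dag = components[0].dag
    q = np.zeros_like(components[0].q)
    for w, comp in zip(weights, components):
        if comp.dag is not dag:
            raise CodingError("mixture components must share a DAG variant")
        q += w * comp.q
    return ProfileDistribution(q, dag)


def strongly_confounded_q(dag: Union[Dag, str] = Dag.B) -> ProfileDistribution:
    """A reference strongly confounded q: an even mixture of two unconfounded
    components in which a latent class shifts mediators and outcome together.

    In the low class both mediators are rare and the outcome responds mostly
    to the exposure; in the high class mediators are common and the baseline
    outcome risk is high.  Marginalizing over the class correlates the
    mediator and outcome response functions, so the g-formula plug-in is
    biased while the bounds remain valid.
    """
    dag = Dag(dag)

    def component(pm1, pm2_b, py_fn):
        qm1 = response_marginal_from_probs(pm1)
        if dag is Dag.B:
            qm2 = response_marginal_from_probs(pm2_b)
        else:
            qm2 = response_marginal_from_probs(pm2_b[:2])
        # y inputs (x, m1, m2) lexicographic
        py = [py_fn(x, m1, m2) for x in (0, 1) for m1 in (0, 1) for m2 in (0, 1)]
        return product_q(qm1, qm2, response_marginal_from_probs(py), dag=dag)

    low = component(
        pm1=(0.2, 0.5),
        pm2_b=(0.15, 0.4, 0.35, 0.6),  # inputs (x, m1)
        py_fn=lambda x, m1, m2: 0.08 + 0.04 * m1 + 0.04 * m2 + 0.05 * x,
    )
    high = component(
        pm1=(0.6, 0.9),
        pm2_b=(0.55, 0.8, 0.75, 0.95),
        py_fn=lambda x, m1, m2: 0.55 + 0.05 * m1 + 0.05 * m2 - 0.25 * x,
    )
    return mixture_q([low, high], [0.5, 0.5])


@dataclass(frozen=True)
class NpsemConfig:
    """Configuration for :func:`generate_npsem`.

    Either pass an explicit ``q`` or let one be drawn: unconfounded (product
    of Dirichlet marginals) when ``confounded`` is False, a joint Dirichlet
    over all profiles when True.
    """

    dag: Dag = Dag.B
    n: int = 5000
    p_treat: float = 0.5
    confounded: bool = False
    q: Optional[ProfileDistribution] = None
    concentration: float = 1.0
    q_seed: Optional[int] = None

    def resolve_q(self) -> ProfileDistribution:
        if self.q is not None:
            if self.q.dag is not Dag(self.dag):
                raise CodingError("q.dag disagrees with config.dag")
            return self.q
        if self.confounded:
            rng = np.random.default_rng(self.q_seed)
            space = enumerate_profiles(self.dag)
            g = rng.gamma(self.concentration, 1.0, size=space.n_profiles)
            return ProfileDistribution(g / g.sum(), Dag(self.dag))
        return unconfounded_q(self.dag, self.concentration, self.q_seed)


@dataclass
class SyntheticTruth:
    """A generating q with the exact estimand values it implies."""

    q: ProfileDistribution
    dag: Dag
    effects: Dict[str, float] = field(default_factory=dict)


def _truth_from_q(q: ProfileDistribution) -> SyntheticTruth:
    dag = q.dag
    names = [n for n in CROSS_EFFECT_NAMES if dag is Dag.B or not n.startswith("crossB_")]
    names.append("total_effect")
    effects = {
        name: true_effects_from_q(q, make_effect(name, canonical_levels(name), dag))
        for name in names
    }
    return SyntheticTruth(q=q, dag=dag, effects=effects)


def generate_npsem(
    config: NpsemConfig, seed: Optional[int] = None
) -> Tuple[BinaryDataset, SyntheticTruth]:
    """Simulate binary NPSEM data from a response-profile distribution.

    Per record: a profile is drawn from q, exposure from
    Bernoulli(p_treat), and (M1, M2, Y) are the profile's realized
    observation under that exposure.  The returned truth holds the exact
    canonical-level estimand values implied by q.
    """
    q = config.resolve_q()
    space = enumerate_profiles(q.dag)
    rng = np.random.default_rng(seed)
    profiles = rng.choice(space.n_profiles, size=config.n, p=q.q)
    x = (rng.random(config.n) < config.p_treat).astype(np.int8)
    m1 = np.empty(config.n, np.int8)
    m2 = np.empty(config.n, np.int8)
    y = np.empty(config.n, np.int8)
    for xv in (0, 1):
        sel = x == xv
        am1, am2, ay = realized_observation(space, xv)
        m1[sel] = am1[profiles[sel]]
        m2[sel] = am2[profiles[sel]]
        y[sel] = ay[profiles[sel]]
    return BinaryDataset(x, m1, m2, y), _truth_from_q(q)


def dataset_from_cell_counts(counts: np.ndarray) -> BinaryDataset:
    """Expand integer cell counts (indexed [y, m1, m2, x]) into records.

    Together with a rational q this produces the *exact* finite-sample
    embodiment of a distribution (full enumeration), on which saturated
    plug-in estimators recover the q-implied truth without sampling error.
    """
    counts = np.asarray(counts)
    if counts.shape != (2, 2, 2, 2) or (counts < 0).any():
        raise CodingError("counts must be a nonnegative (2,2,2,2) array")
    if not np.allclose(counts, np.round(counts)):
        raise CodingError("counts must be integers")
    counts = np.round(counts).astype(np.int64)
    xs, m1s, m2s, ys = [], [], [], []
    for y in (0, 1):
        for m1 in (0, 1):
            for m2 in (0, 1):
                for x in (0, 1):
                    c = counts[y, m1, m2, x]
                    xs.append(np.full(c, x, np.int8))
                    m1s.append(np.full(c, m1, np.int8))
                    m2s.append(np.full(c, m2, np.int8))
                    ys.append(np.full(c, y, np.int8))
    return BinaryDataset(
        np.concatenate(xs), np.concatenate(m1s), np.concatenate(m2s), np.concatenate(ys)
    )


@dataclass
class TrialSummary:
    """Event and cell tabulation of a binary trial dataset."""

    n: int
    n_by_arm: np.ndarray
    events_by_arm: np.ndarray
    cell_counts: np.ndarray  # [y, m1, m2, x]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_by_arm": self.n_by_arm.tolist(),
            "events_by_arm": self.events_by_arm.tolist(),
            "cell_counts": self.cell_counts.tolist(),
        }


def summarize_trial(data: BinaryDataset) -> TrialSummary:
    """Tabulate per-arm sizes, event counts, and the 16 joint cells."""
    counts = data.cell_counts() if len(data) else np.zeros((2, 2, 2, 2), np.int64)
    return TrialSummary(
        n=len(data),
        n_by_arm=counts.sum(axis=(0, 1, 2)),
        events_by_arm=counts[1].sum(axis=(0, 1)),
        cell_counts=counts,
    )
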