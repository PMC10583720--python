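"""Tight numeric bounds via the canonical response-function partition.

Under residual confounding of (M1, M2, Y), none of the cross-direct effects
is point identified.  Following the Balke–Pearl construction, all unmeasured
confounding between the post-treatment variables can be reduced to a joint
distribution q over *response-function profiles*: each variable's structural
equation, given its error, is one of the finitely many maps from parent
values to {0,1}.  A binary variable with k binary parents has 2^(2^k) such
maps, so

* variant A (parents: M1<-X, M2<-X, Y<-(X,M1,M2)):  4 * 4 * 256 = 4096 profiles;
* variant B (M2 additionally <- M1):               4 * 16 * 256 = 16384 profiles.

The 16 observable probabilities p_{y m1 m2 . x} are linear in q, every
nested counterfactual mean is linear in q, and tight bounds on any estimand
are the min/max of its objective over the polytope {q >= 0, A q = p}.  This
module is both the general bounds engine (any estimand, any level setting)
and the independent oracle for the transcribed symbolic bounds.

Enumeration order (frozen so q vectors are portable): the M1-function index
varies slowest, then the M2-function index, then the Y-function index.
Within each variable, functions are ordered by their truth table read as a
binary integer, inputs in lexicographic order with x slowest and the first
input's output as the most significant bit.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.optimize import linprog

from .distributions import ObservedDistribution
from .estimands import (
    Controlled,
    Dag,
    EffectSpec,
    NaturalM1,
    NaturalM2,
    NaturalM2GivenM1,
    NaturalM2NaturalM1,
    PotentialOutcomeSpec,
)
from .exceptions import CodingError, DagCompatibilityError, LPFailureError
from .symbolic_bounds import BoundsInterval

__all__ = [
    "ResponseProfileSpace",
    "ProfileDistribution",
    "LPProblem",
    "enumerate_profiles",
    "realized_observation",
    "counterfactual_value",
    "build_lp",
    "solve_bounds",
    "sample_compatible_distribution",
    "marginalize_q",
    "true_effects_from_q",
]


def _truth_tables(n_inputs: int) -> np.ndarray:
    """All 2^n_inputs-entry truth tables, shape (2^(2^k) ... ) flattened.

    Row f holds the outputs at the lexicographically ordered inputs; the
    first input's output is the most significant bit of f.
    """
    n_fun = 2 ** n_inputs
    tables = np.zeros((n_fun, n_inputs), dtype=np.int8)
    for j in range(n_inputs):
        tables[:, j] = (np.arange(n_fun) >> (n_inputs - 1 - j)) & 1
    return tables


@dataclass(frozen=True)
class ResponseProfileSpace:
    """Enumeration of all response-function profiles for one DAG variant."""

    dag: Dag
    m1_tables: np.ndarray  # (4, 2): value at x
    m2_tables: np.ndarray  # A: (4, 2) value at x; B: (16, 2, 2) value at (x, m1)
    y_tables: np.ndarray   # (256, 2, 2, 2): value at (x, m1, m2)
    i_m1: np.ndarray
    i_m2: np.ndarray
    i_y: np.ndarray

    @property
    def n_profiles(self) -> int:
        return self.i_m1.size

    @property
    def n_m2_functions(self) -> int:
        return self.m2_tables.shape[0]


@functools.lru_cache(maxsize=None)
def enumerate_profiles(dag: Union[Dag, str]) -> ResponseProfileSpace:
    """Build (and cache) the profile space for a DAG variant."""
    dag = Dag(dag)
    m1_tables = _truth_tables(2)  # inputs x = 0, 1
    if dag is Dag.A:
        m2_tables = _truth_tables(2)
    else:
        # inputs (x, m1) lexicographic with x slowest: (0,0),(0,1),(1,0),(1,1)
        m2_tables = _truth_tables(4).reshape(16, 2, 2)
    y_tables = _truth_tables(8).reshape(256, 2, 2, 2)
    n_m2 = m2_tables.shape[0]
    idx = np.indices((4, n_m2, 256))
    return ResponseProfileSpace(
        dag=dag,
        m1_tables=m1_tables,
        m2_tables=m2_tables,
        y_tables=y_tables,
        i_m1=idx[0].ravel(),
        i_m2=idx[1].ravel(),
        i_y=idx[2].ravel(),
    )


@dataclass
class ProfileDistribution:
    """A probability vector q over the profiles of one DAG variant."""

    q: np.ndarray
    dag: Dag

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.dag = Dag(self.dag)
        space = enumerate_profiles(self.dag)
        if self.q.shape != (space.n_profiles,):
            raise CodingError(
                f"q must have length {space.n_profiles} for variant {self.dag.value}"
            )
        if (self.q < -1e-15).any():
            raise CodingError("q must be nonnegative")
        if abs(self.q.sum() - 1.0) > 1e-9:
            raise CodingError(f"q must sum to 1, got {self.q.sum()!r}")


def realized_observation(
    space: ResponseProfileSpace, x: int, profile: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The observation (m1, m2, y) each profile produces under exposure x.

    With ``profile`` given, returns scalars for that single profile;
    otherwise vectorized over all profiles.
    """
    i_m1 = space.i_m1 if profile is None else space.i_m1[profile]
    i_m2 = space.i_m2 if profile is None else space.i_m2[profile]
    i_y = space.i_y if profile is None else space.i_y[profile]
    m1 = space.m1_tables[i_m1, x]
    if space.dag is Dag.A:
        m2 = space.m2_tables[i_m2, x]
    else:
        m2 = space.m2_tables[i_m2, x, m1]
    y = space.y_tables[i_y, x, m1, m2]
    return m1, m2, y


def counterfactual_value(
    space: ResponseProfileSpace, po: PotentialOutcomeSpec, profile: Optional[int] = None
) -> np.ndarray:
    """Evaluate the nested counterfactual Y(x, <m1 arg>, <m2 arg>) per profile.

    The nesting resolves inner arguments through the profile's own response
    functions, so counterfactuals that share M1 (e.g. the total effect) are
    automatically coherent within a profile.
    """
    po.check_dag(space.dag)
    i_m1 = space.i_m1 if profile is None else space.i_m1[profile]
    i_m2 = space.i_m2 if profile is None else space.i_m2[profile]
    i_y = space.i_y if profile is None else space.i_y[profile]

    a1 = po.m1_arg
    if isinstance(a1, Controlled):
        m1 = np.broadcast_to(np.int8(a1.level), np.shape(i_m1))
    else:
        m1 = space.m1_tables[i_m1, a1.x1]

    a2 = po.m2_arg
    if isinstance(a2, Controlled):
        m2 = np.broadcast_to(np.int8(a2.level), np.shape(i_m1))
    elif isinstance(a2, NaturalM2):
        m2 = space.m2_tables[i_m2, a2.x2]
    elif isinstance(a2, NaturalM2GivenM1):
        m2 = space.m2_tables[i_m2, a2.x2, a2.m1]
    elif isinstance(a2, NaturalM2NaturalM1):
        inner_m1 = space.m1_tables[i_m1, a2.x3]
        m2 = space.m2_tables[i_m2, a2.x2, inner_m1]
    else:  # pragma: no cover - exhaustive by type
        raise DagCompatibilityError(f"unknown M2 argument {a2!r}")

    return space.y_tables[i_y, po.x, m1, m2]


def objective_vector(space: ResponseProfileSpace, spec: EffectSpec) -> np.ndarray:
    """Per-profile contribution of the contrast: treated minus control."""
    if Dag(spec.dag) is not space.dag:
        raise DagCompatibilityError(
            f"spec is for variant {spec.dag.value}, space for {space.dag.value}"
        )
    return counterfactual_value(space, spec.treated).astype(float) - counterfactual_value(
        space, spec.control
    ).astype(float)


def _constraint_matrix(space: ResponseProfileSpace) -> np.ndarray:
    """0/1 incidence A with 16 rows ordered by (x, y, m1, m2) lexicographic."""
    n = space.n_profiles
    A = np.zeros((16, n))
    for x in (0, 1):
        m1, m2, y = realized_observation(space, x)
        code = y.astype(np.int64) * 4 + m1.astype(np.int64) * 2 + m2.astype(np.int64)
        A[x * 8 + code, np.arange(n)] = 1.0
    return A


@functools.lru_cache(maxsize=None)
def _cached_constraint_matrix(dag: Dag) -> np.ndarray:
    return _constraint_matrix(enumerate_profiles(dag))


def _rhs(dist: ObservedDistribution) -> np.ndarray:
    """The 16 probabilities in the constraint row order (x, y, m1, m2)."""
    rhs = np.empty(16)
    for x in (0, 1):
        # arm() is (y, m1, m2) lexicographic, matching the row code above
        rhs[x * 8 : x * 8 + 8] = dist.arm(x)
    return rhs


@dataclass
class LPProblem:
    """A bounds LP: optimize c.q subject to A q = rhs, q >= 0."""

    objective: np.ndarray
    constraints: np.ndarray
    rhs: np.ndarray
    dag: Dag

    def to_dict(self) -> dict:
        """Plain JSON-able form; the incidence matrix as sparse triplets."""
        rows, cols = np.nonzero(self.constraints)
        return {
            "dag": self.dag.value,
            "c": self.objective.tolist(),
            "A": {
                "shape": list(self.constraints.shape),
                "rows": rows.tolist(),
                "cols": cols.tolist(),
                "values": self.constraints[rows, cols].tolist(),
            },
            "rhs": self.rhs.tolist(),
        }


def build_lp(dist: ObservedDistribution, spec: EffectSpec, dag: Union[Dag, str]) -> LPProblem:
    """Assemble the LP whose min/max over q are the tight bounds for ``spec``."""
    dag = Dag(dag)
    space = enumerate_profiles(dag)
    return LPProblem(
        objective=objective_vector(space, spec),
        constraints=_cached_constraint_matrix(dag),
        rhs=_rhs(dist),
        dag=dag,
    )


def solve_bounds(
    dist: ObservedDistribution,
    spec: EffectSpec,
    dag: Union[Dag, str],
    solver_tol: float = 1e-9,
) -> BoundsInterval:
    """Tight bounds for any estimand by solving the two LPs with HiGHS.

    The response-function model is saturated, so every valid per-arm
    probability table is feasible; a non-optimal solver status therefore
    signals numerical trouble and raises :class:`LPFailureError`.
    """
    problem = build_lp(dist, spec, dag)
    endpoints = []
    for sign in (1.0, -1.0):
        res = linprog(
            sign * problem.objective,
            A_eq=problem.constraints,
            b_eq=problem.rhs,
            bounds=(0, None),
            method="highs",
            options={"primal_feasibility_tolerance": solver_tol},
        )
        if res.status != 0:
            raise LPFailureError(
                f"LP solve failed (status {res.status}): {res.message}", diagnostics=res
            )
        endpoints.append(sign * res.fun)
    lower, upper = endpoints
    return BoundsInterval(lower=float(lower), upper=float(upper), method="lp")


def marginalize_q(q: ProfileDistribution) -> ObservedDistribution:
    """The observed 16-entry table implied by a profile distribution."""
    space = enumerate_profiles(q.dag)
    p = np.zeros((2, 2, 2, 2))
    for x in (0, 1):
        m1, m2, y = realized_observation(space, x)
        code = y.astype(np.int64) * 4 + m1.astype(np.int64) * 2 + m2.astype(np.int64)
        p[:, :, :, x] = np.bincount(code, weights=q.q, minlength=8).reshape(2, 2, 2)
    return ObservedDistribution(p)


def sample_compatible_distribution(
    dag: Union[Dag, str],
    concentration: float = 1.0,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> Tuple[ObservedDistribution, ProfileDistribution]:
    """Draw a model-compatible observed table by sampling q ~ Dirichlet.

    Returns both the marginal table and the generating q, so validity
    (truth inside the bounds) can be checked exactly.
    """
    if concentration <= 0:
        raise CodingError("concentration must be positive")
    dag = Dag(dag)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    space = enumerate_profiles(dag)
    # gamma-normalization form of a symmetric Dirichlet draw
    g = rng.gamma(concentration, 1.0, size=space.n_profiles)
    q = ProfileDistribution(g / g.sum(), dag)
    return marginalize_q(q), q


def true_effects_from_q(
    q: ProfileDistribution, spec: EffectSpec, dag: Optional[Union[Dag, str]] = None
) -> float:
    """Exact ground-truth value of an estimand under a known q."""
    if dag is not None and Dag(dag) is not q.dag:
        raise DagCompatibilityError("dag argument disagrees with q.dag")
    space = enumerate_profiles(q.dag)
    return float(np.dot(q.q, objective_vector(space, spec)))
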