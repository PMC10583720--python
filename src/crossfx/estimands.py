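"""Cross-direct-effect estimands for two (possibly sequential) binary mediators.

With one mediator the classic contrasts are the controlled direct effect
(mediator fixed at a constant level for everyone) and the natural direct
effect (mediator held at the value each subject would have had under a
reference exposure).  With two mediators one can *cross* the two types of
control: fix one mediator and hold the other at its natural, subject-specific
counterfactual level.  This module gives those estimands a first-class
representation.

Two causal structures are distinguished:

* variant ``A`` — the mediators do not affect each other;
* variant ``B`` — the first mediator ``M1`` affects the second ``M2``
  (sequential mediators), which creates additional estimands whose inner
  ``M1`` argument may itself be controlled or natural.

Each estimand is a contrast of two potential-outcome means that differ only
in the outer exposure level (the total effect, where every argument tracks
the exposure, is the one exception).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Union

from .exceptions import DagCompatibilityError, UnderspecifiedEffectError

__all__ = [
    "Dag",
    "Controlled",
    "NaturalM1",
    "NaturalM2",
    "NaturalM2GivenM1",
    "NaturalM2NaturalM1",
    "PotentialOutcomeSpec",
    "EffectSpec",
    "EFFECT_NAMES",
    "CROSS_EFFECT_NAMES",
    "canonical_levels",
    "make_effect",
    "relabel_mediators",
]


class Dag(str, Enum):
    """DAG variant: ``A`` = mediators mutually unaffected, ``B`` = M1 -> M2."""

    A = "A"
    B = "B"


def _as_dag(dag: Union[Dag, str]) -> Dag:
    return Dag(dag)


def _check_binary(value: int, what: str) -> int:
    if value not in (0, 1):
        raise UnderspecifiedEffectError(f"{what} must be 0 or 1, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class Controlled:
    """Mediator fixed to a constant ``level`` for every subject."""

    level: int

    def __post_init__(self):
        _check_binary(self.level, "controlled level")


@dataclass(frozen=True)
class NaturalM1:
    """M1 held at its natural value under exposure ``x1``: M1(x1)."""

    x1: int

    def __post_init__(self):
        _check_binary(self.x1, "x1")


@dataclass(frozen=True)
class NaturalM2:
    """M2 at its natural value under exposure ``x2``: M2(x2).  Variant A only
    (under B the natural value of M2 also depends on M1)."""

    x2: int

    def __post_init__(self):
        _check_binary(self.x2, "x2")


@dataclass(frozen=True)
class NaturalM2GivenM1:
    """M2 at its natural value under exposure ``x2`` with M1 controlled at
    ``m1``: M2(x2, m1).  Variant B only."""

    x2: int
    m1: int

    def __post_init__(self):
        _check_binary(self.x2, "x2")
        _check_binary(self.m1, "inner controlled m1")


@dataclass(frozen=True)
class NaturalM2NaturalM1:
    """M2 at its natural value under exposure ``x2`` with M1 at its natural
    value under ``x3``: M2(x2, M1(x3)).  Variant B only."""

    x2: int
    x3: int

    def __post_init__(self):
        _check_binary(self.x2, "x2")
        _check_binary(self.x3, "x3")


M1Arg = Union[Controlled, NaturalM1]
M2Arg = Union[Controlled, NaturalM2, NaturalM2GivenM1, NaturalM2NaturalM1]


@dataclass(frozen=True)
class PotentialOutcomeSpec:
    """One nested potential outcome Y(x, <m1 argument>, <m2 argument>)."""

    x: int
    m1_arg: M1Arg
    m2_arg: M2Arg

    def __post_init__(self):
        _check_binary(self.x, "x")

    def requires_dag_b(self) -> bool:
        return isinstance(self.m2_arg, (NaturalM2GivenM1, NaturalM2NaturalM1))

    def check_dag(self, dag: Union[Dag, str]) -> None:
        dag = _as_dag(dag)
        if self.requires_dag_b() and dag is not Dag.B:
            raise DagCompatibilityError(
                "an M2 argument with an inner M1 argument requires the "
                "sequential-mediator variant B"
            )
        if isinstance(self.m2_arg, NaturalM2) and dag is not Dag.A:
            raise DagCompatibilityError(
                "a natural M2(x2) argument without an inner M1 argument is "
                "only defined under variant A"
            )


@dataclass(frozen=True)
class EffectSpec:
    """A contrast E{Y(x, ...)} - E{Y(x', ...)} of two potential outcomes.

    For the cross effects the two arms differ only in the outer exposure;
    for the total effect every exposure argument switches with the arm.
    """

    name: str
    dag: Dag
    treated: PotentialOutcomeSpec
    control: PotentialOutcomeSpec

    def __post_init__(self):
        self.treated.check_dag(self.dag)
        self.control.check_dag(self.dag)
        if self.name != "total_effect":
            if (self.treated.m1_arg, self.treated.m2_arg) != (
                self.control.m1_arg,
                self.control.m2_arg,
            ):
                raise UnderspecifiedEffectError(
                    "cross-effect arms must differ only in the exposure"
                )

    @property
    def is_null_contrast(self) -> bool:
        """True when both arms set the exposure to the same level."""
        return self.treated == self.control


#: Names of the five cross estimands plus the total effect.  ``crossA_*``
#: estimands exist under both variants; ``crossB_*`` require variant B.
CROSS_EFFECT_NAMES = (
    "crossA_M1nat",
    "crossA_M2nat",
    "crossB_M2ctrl_inner",
    "crossB_M2nat_inner_nat",
    "crossB_bothnat_inner_ctrl",
)
EFFECT_NAMES = CROSS_EFFECT_NAMES + ("total_effect",)

_REQUIRED_LEVELS = {
    "crossA_M1nat": ("x", "xp", "x1", "m2"),
    "crossA_M2nat": ("x", "xp", "m1", "x2"),
    "crossB_M2ctrl_inner": ("x", "xp", "m1", "x2", "m1p"),
    "crossB_M2nat_inner_nat": ("x", "xp", "m1", "x2", "x3"),
    "crossB_bothnat_inner_ctrl": ("x", "xp", "x1", "x2", "m1p"),
    "total_effect": ("x", "xp"),
}


def canonical_levels(name: str) -> dict:
    """Default level map: exposure contrast 1 vs 0, all other levels 0.

    These are the level settings of the printed bound results and of the
    reference contrasts used throughout the test harness.
    """
    levels = {k: 0 for k in _REQUIRED_LEVELS[name]}
    levels["x"] = 1
    return levels


def _pick(levels: Mapping[str, int], name: str, effect: str) -> int:
    if name not in levels:
        raise UnderspecifiedEffectError(
            f"estimand {effect!r} requires level {name!r}; got {sorted(levels)}"
        )
    return _check_binary(levels[name], name)


def _po(name: str, levels: Mapping[str, int], dag: Dag, x: int) -> PotentialOutcomeSpec:
    if name == "crossA_M1nat":
        return PotentialOutcomeSpec(
            x,
            NaturalM1(_pick(levels, "x1", name)),
            Controlled(_pick(levels, "m2", name)),
        )
    if name == "crossA_M2nat":
        x2 = _pick(levels, "x2", name)
        m1 = Controlled(_pick(levels, "m1", name))
        if dag is Dag.A:
            return PotentialOutcomeSpec(x, m1, NaturalM2(x2))
        # Under B the natural value of M2 at exposure x2 carries M1's natural
        # value at the same exposure: M2(x2) == M2(x2, M1(x2)).
        return PotentialOutcomeSpec(x, m1, NaturalM2NaturalM1(x2, x2))
    if name == "crossB_M2ctrl_inner":
        return PotentialOutcomeSpec(
            x,
            Controlled(_pick(levels, "m1", name)),
            NaturalM2GivenM1(_pick(levels, "x2", name), _pick(levels, "m1p", name)),
        )
    if name == "crossB_M2nat_inner_nat":
        return PotentialOutcomeSpec(
            x,
            Controlled(_pick(levels, "m1", name)),
            NaturalM2NaturalM1(_pick(levels, "x2", name), _pick(levels, "x3", name)),
        )
    if name == "crossB_bothnat_inner_ctrl":
        return PotentialOutcomeSpec(
            x,
            NaturalM1(_pick(levels, "x1", name)),
            NaturalM2GivenM1(_pick(levels, "x2", name), _pick(levels, "m1p", name)),
        )
    if name == "total_effect":
        if dag is Dag.A:
            return PotentialOutcomeSpec(x, NaturalM1(x), NaturalM2(x))
        return PotentialOutcomeSpec(x, NaturalM1(x), NaturalM2NaturalM1(x, x))
    raise UnderspecifiedEffectError(
        f"unknown estimand {name!r}; valid names: {list(EFFECT_NAMES)}"
    )


def make_effect(name: str, levels: Mapping[str, int], dag: Union[Dag, str]) -> EffectSpec:
    """Build a validated :class:`EffectSpec` from an estimand name.

    Parameters
    ----------
    name
        One of :data:`EFFECT_NAMES`.
    levels
        Map from level symbols (``x``, ``xp``, ``x1``, ``x2``, ``x3``,
        ``m1``, ``m2``, ``m1p``) to 0/1 values; the required symbols depend
        on the estimand.
    dag
        DAG variant; ``crossB_*`` names (and inner-M1 forms generally)
        require variant ``B``.
    """
    dag = _as_dag(dag)
    if name not in _REQUIRED_LEVELS:
        raise UnderspecifiedEffectError(
            f"unknown estimand {name!r}; valid names: {list(EFFECT_NAMES)}"
        )
    if name.startswith("crossB_") and dag is not Dag.B:
        raise DagCompatibilityError(
            f"estimand {name!r} requires the sequential-mediator variant B"
        )
    x = _pick(levels, "x", name)
    xp = _pick(levels, "xp", name)
    return EffectSpec(
        name=name,
        dag=dag,
        treated=_po(name, levels, dag, x),
        control=_po(name, levels, dag, xp),
    )


def relabel_mediators(spec: EffectSpec) -> EffectSpec:
    """Exchange the roles of M1 and M2 in an estimand (variant A only).

    When the mediators do not affect each other the model is symmetric in
    (M1, M2), so any result about Y(x, M1(x1), m2) transfers to
    Y(x, m2', M2(x1)) by relabelling.  Applying the operation twice returns
    the original estimand.
    """
    if spec.dag is not Dag.A:
        raise DagCompatibilityError(
            "mediator relabelling relies on the M1/M2 symmetry of variant A"
        )

    def swap(po: PotentialOutcomeSpec) -> PotentialOutcomeSpec:
        m1, m2 = po.m1_arg, po.m2_arg
        new_m1: M1Arg
        new_m2: M2Arg
        new_m1 = Controlled(m2.level) if isinstance(m2, Controlled) else NaturalM1(m2.x2)
        new_m2 = Controlled(m1.level) if isinstance(m1, Controlled) else NaturalM2(m1.x1)
        return PotentialOutcomeSpec(po.x, new_m1, new_m2)

    name_map = {
        "crossA_M1nat": "crossA_M2nat",
        "crossA_M2nat": "crossA_M1nat",
    }
    return EffectSpec(
        name=name_map.get(spec.name, spec.name),
        dag=spec.dag,
        treated=swap(spec.treated),
        control=swap(spec.control),
    )
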