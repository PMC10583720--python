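"""Closed-form tight bounds for the canonical cross-direct-effect contrasts.

For the reference level setting (exposure contrast 1 vs 0, every controlled
and inner level at 0) the tight bounds have closed forms: the lower bound is
the maximum, and the upper bound the minimum, of a handful of linear
expressions in the 16 observed probabilities p_{y m1 m2 . x}.  The four
published displays covered here are

* result 1 — dE{Y(1->0, M1(0), 0)}        (valid under variant A or B);
* result 2 — dE{Y(1->0, 0, M2(0, 0))}     (variant B);
* result 3 — dE{Y(1->0, M1(0), M2(0,0))}  (variant B);
* result 4 — dE{Y(1->0, 0, M2(0, M1(0)))} (variant B);
* result 1 applied after exchanging the mediator labels gives
  dE{Y(1->0, 0, M2(0))} under variant A (M1/M2 symmetry).

Expressions are stored as data (parsed coefficient tables), so each term can
be unit-tested and reused by reporting code.  Other level settings have no
closed form here and are served by the LP engine (:mod:`crossfx.lp_bounds`),
which is also the oracle these expressions are tested against.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .distributions import ObservedDistribution

__all__ = [
    "LinearExpression",
    "BoundsInterval",
    "bounds_result1",
    "bounds_result2",
    "bounds_result3",
    "bounds_result4",
    "bounds_result1_swapped",
    "SYMBOLIC_RESULTS",
]

_TERM_RE = re.compile(r"([+-])\s*(\d+(?:\.\d+)?)?\s*(?:p(\d)(\d)(\d)\.(\d))?")


@dataclass(frozen=True)
class LinearExpression:
    """intercept + sum of coef * p_{y m1 m2 . x} terms."""

    intercept: float
    coefficients: Dict[Tuple[int, int, int, int], float] = field(default_factory=dict)
    source: str = ""

    @classmethod
    def parse(cls, text: str) -> "LinearExpression":
        """Parse a display line like ``-1 + p000.0 + 2p010.0 - p110.1``.

        ``pabc.x`` denotes p_{y=a, m1=b, m2=c | X=x}.
        """
        intercept = 0.0
        coefs: Dict[Tuple[int, int, int, int], float] = {}
        s = text.replace(" ", "")
        if s and s[0] not in "+-":
            s = "+" + s
        pos = 0
        while pos < len(s):
            m = _TERM_RE.match(s, pos)
            if not m or m.end() == pos:
                raise ValueError(f"cannot parse bound expression at {s[pos:]!r}")
            sign = 1.0 if m.group(1) == "+" else -1.0
            num = float(m.group(2)) if m.group(2) else 1.0
            if m.group(3) is not None:
                key = (int(m.group(3)), int(m.group(4)), int(m.group(5)), int(m.group(6)))
                coefs[key] = coefs.get(key, 0.0) + sign * num
            else:
                intercept += sign * num
            pos = m.end()
        return cls(intercept=intercept, coefficients=coefs, source=text)

    def evaluate(self, dist: ObservedDistribution) -> float:
        val = self.intercept
        for (y, m1, m2, x), c in self.coefficients.items():
            val += c * dist.p[y, m1, m2, x]
        return float(val)


@dataclass
class BoundsInterval:
    """A [lower, upper] interval with the indices of the active expressions."""

    lower: float
    upper: float
    active_lower: Optional[int] = None
    active_upper: Optional[int] = None
    method: str = "symbolic"

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float, tol: float = 0.0) -> bool:
        return self.lower - tol <= value <= self.upper + tol


def _parse_all(lines: Sequence[str]) -> Tuple[LinearExpression, ...]:
    return tuple(LinearExpression.parse(t) for t in lines)


# Transcribed bound displays.  Term notation: pabc.x = p{Y=a, M1=b, M2=c | X=x}.

RESULT1_LOWER = _parse_all([
    "-1 - p100.0 + p010.0 + p110.1 - p001.0 - p101.0",
    "-2 + 2p000.0 + p100.0 + p100.1 + p010.0 + p001.0 + p101.0",
    "-1 + p000.0 + p010.0",
])
RESULT1_UPPER = _parse_all([
    "1 + p000.0 - p010.1 - p110.0 + p001.0 + p101.0",
    "1 - p100.0 - p110.0",
    "2 - p000.0 - p000.1 - 2p100.0 - p110.0 - p001.0 - p101.0",
])

RESULT2_LOWER = _parse_all([
    "-2 + p000.0 + 2p001.0 + p101.0 + p101.1",
    "-2 + 2p000.0 + p100.0 + p100.1 + p001.0",
    "-1 + p000.0 + p001.0",
])
RESULT2_UPPER = _parse_all([
    "2 - p100.0 - p001.0 - p001.1 - 2p101.0",
    "1 - p100.0 - p101.0",
    "2 - p000.0 - p000.1 - 2p100.0 - p101.0",
])

RESULT3_LOWER = _parse_all([
    "-2 + p000.0 + 2p001.0 + p101.0 + p101.1",
    "-2 + 2p000.0 + p100.0 + p100.1 + p001.0",
    "-1 + p000.0 + p001.0",
    "-1 + p000.0 - p000.1 - p100.1 + p010.0 - p010.1 - p110.1"
    " + p001.0 - p001.1 - p101.1 - p011.1",
    "-2 + p000.0 + p110.1 + p001.0 + p011.0",
])
RESULT3_UPPER = _parse_all([
    "2 - p100.0 - p001.0 - p001.1 - 2p101.0",
    "2 - p100.0 - p110.0 - p101.0 - p011.1",
    "1 + p000.0 + p010.0 - p010.1 + p110.0 + p001.0 + p011.0",
    "1 - p100.0 - p101.0",
    "2 - p000.0 - p000.1 - 2p100.0 - p101.0",
])

RESULT4_LOWER = _parse_all([
    "-1 - p100.0 - p010.0 - p110.0 + p001.0 + p101.1",
    "-2 + 2p000.0 + p100.0 + p100.1 + p010.0 + p110.0 + p001.0",
    "-1 + p000.0 + p001.0",
])
RESULT4_UPPER = _parse_all([
    "1 + p000.0 + p010.0 + p110.0 - p001.1 - p101.0",
    "1 - p100.0 - p101.0",
    "2 - p000.0 - p000.1 - 2p100.0 - p010.0 - p110.0 - p101.0",
])


def _evaluate(
    dist: ObservedDistribution,
    lowers: Sequence[LinearExpression],
    uppers: Sequence[LinearExpression],
) -> BoundsInterval:
    lo_vals = [e.evaluate(dist) for e in lowers]
    up_vals = [e.evaluate(dist) for e in uppers]
    i_lo = int(np.argmax(lo_vals))
    i_up = int(np.argmin(up_vals))
    return BoundsInterval(
        lower=lo_vals[i_lo],
        upper=up_vals[i_up],
        active_lower=i_lo,
        active_upper=i_up,
        method="symbolic",
    )


def bounds_result1(dist: ObservedDistribution) -> BoundsInterval:
    """Bounds for dE{Y(1->0, M1(0), 0)} — M1 natural at 0, M2 held at 0.

    Valid and tight under either DAG variant.
    """
    return _evaluate(dist, RESULT1_LOWER, RESULT1_UPPER)


def bounds_result2(dist: ObservedDistribution) -> BoundsInterval:
    """Bounds for dE{Y(1->0, 0, M2(0, 0))} under variant B."""
    return _evaluate(dist, RESULT2_LOWER, RESULT2_UPPER)


def bounds_result3(dist: ObservedDistribution) -> BoundsInterval:
    """Bounds for dE{Y(1->0, M1(0), M2(0, 0))} under variant B."""
    return _evaluate(dist, RESULT3_LOWER, RESULT3_UPPER)


def bounds_result4(dist: ObservedDistribution) -> BoundsInterval:
    """Bounds for dE{Y(1->0, 0, M2(0, M1(0)))} under variant B."""
    return _evaluate(dist, RESULT4_LOWER, RESULT4_UPPER)


def bounds_result1_swapped(dist: ObservedDistribution) -> BoundsInterval:
    """Bounds for dE{Y(1->0, 0, M2(0))} under variant A.

    Obtained by evaluating the result-1 expressions on the distribution with
    the M1 and M2 indices exchanged (mediator symmetry of variant A).
    """
    return _evaluate(dist.swap_mediators(), RESULT1_LOWER, RESULT1_UPPER)


#: Registry mapping a result tag to (function, estimand name, levels, dag tag).
#: Levels are the canonical setting of :func:`crossfx.estimands.canonical_levels`.
SYMBOLIC_RESULTS = {
    "result1": (bounds_result1, "crossA_M1nat", "B"),
    "result1_dagA": (bounds_result1, "crossA_M1nat", "A"),
    "result1_swapped": (bounds_result1_swapped, "crossA_M2nat", "A"),
    "result2": (bounds_result2, "crossB_M2ctrl_inner", "B"),
    "result3": (bounds_result3, "crossB_bothnat_inner_ctrl", "B"),
    "result4": (bounds_result4, "crossB_M2nat_inner_nat", "B"),
}
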