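"""Nonparametric bootstrap inference for point estimates and bound endpoints.

Records are resampled with replacement at the row level (unstratified by
default; optionally within treatment arms), the statistic is recomputed on
each replicate, and percentile (quantile) intervals are reported.  Quantiles
use linear interpolation of order statistics (numpy's default, R type 7) so
intervals are reproducible across implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np

from .distributions import BinaryDataset, estimate_observed_distribution
from .estimands import Dag, EffectSpec
from .exceptions import CrossFxError, DegenerateResamplesError

__all__ = ["BootstrapResult", "bootstrap", "bound_cis"]


@dataclass
class BootstrapResult:
    """Point estimate, replicate draws, and a percentile confidence interval."""

    point: float
    replicates: np.ndarray
    ci_lower: float
    ci_upper: float
    level: float
    B: int
    seed: Optional[int]

    def summary(self) -> dict:
        return {
            "point": self.point,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "level": self.level,
            "B": self.B,
            "replicate_mean": float(np.mean(self.replicates)),
            "replicate_sd": float(np.std(self.replicates, ddof=1)) if self.B > 1 else 0.0,
        }


def _percentile_ci(replicates: np.ndarray, level: float) -> Tuple[np.ndarray, np.ndarray]:
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(replicates, alpha, axis=0)
    hi = np.quantile(replicates, 1.0 - alpha, axis=0)
    return lo, hi


def bootstrap(
    data: BinaryDataset,
    statistic: Callable[[BinaryDataset], Union[float, np.ndarray]],
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    stratify_by_arm: bool = False,
    max_retries: int = 100,
) -> Union[BootstrapResult, Tuple[BootstrapResult, ...]]:
    """Percentile bootstrap of an arbitrary statistic of the data.

    ``statistic`` may return a scalar (one :class:`BootstrapResult`) or a
    1-d vector (a tuple of results, one per component, computed from the
    same resamples).  A replicate on which the statistic raises a
    :class:`CrossFxError` (e.g. an empty arm or stratum) is redrawn, up to
    ``max_retries`` times in total; exhausting the budget raises
    :class:`DegenerateResamplesError`.  Fully reproducible given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    n = len(data)
    rng = np.random.default_rng(seed)
    point = np.asarray(statistic(data), dtype=float)
    scalar = point.ndim == 0

    if stratify_by_arm:
        arm_idx = [np.flatnonzero(data.x == 0), np.flatnonzero(data.x == 1)]

    def resample_index():
        if stratify_by_arm:
            return np.concatenate(
                [idx[rng.integers(0, idx.size, idx.size)] for idx in arm_idx]
            )
        return rng.integers(0, n, n)

    replicates = np.empty((B,) + point.shape)
    retries = 0
    for b in range(B):
        while True:
            try:
                replicates[b] = np.asarray(statistic(data.subset(resample_index())), float)
                break
            except CrossFxError as exc:
                retries += 1
                if retries > max_retries:
                    raise DegenerateResamplesError(
                        f"statistic failed on {retries} resamples; last error: {exc}"
                    ) from exc

    lo, hi = _percentile_ci(replicates, level)
    if scalar:
        return BootstrapResult(
            float(point), replicates, float(lo), float(hi), level, B, seed
        )
    return tuple(
        BootstrapResult(
            float(point[k]), replicates[:, k], float(lo[k]), float(hi[k]), level, B, seed
        )
        for k in range(point.shape[0])
    )


def bound_cis(
    data: BinaryDataset,
    spec: EffectSpec,
    dag: Union[Dag, str],
    method: str = "symbolic",
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    stratify_by_arm: bool = False,
) -> Tuple[BootstrapResult, BootstrapResult]:
    """Bootstrap the lower and upper bound endpoints of an estimand.

    The two endpoint functionals are bootstrapped as a pair over one stream
    of resamples (each endpoint's interval is its own marginal percentile
    interval, identical in law to bootstrapping them separately).
    ``method`` selects the closed-form expressions (``"symbolic"``, only for
    the canonical level settings) or the LP engine (``"lp"``, any estimand).
    """
    from . import lp_bounds, symbolic_bounds
    from .estimands import canonical_levels

    dag = Dag(dag)
    if method == "lp":
        def endpoints(d: BinaryDataset) -> np.ndarray:
            dist = estimate_observed_distribution(d)
            bi = lp_bounds.solve_bounds(dist, spec, dag)
            return np.array([bi.lower, bi.upper])
    elif method == "symbolic":
        from .estimands import make_effect

        match = None
        for _tag, (fn, name, dagtag) in symbolic_bounds.SYMBOLIC_RESULTS.items():
            if (
                name == spec.name
                and Dag(dagtag) is dag
                and make_effect(name, canonical_levels(name), dag) == spec
            ):
                match = fn
                break
        if match is None:
            raise CrossFxError(
                "no closed-form bound expressions for this estimand/levels; "
                "use method='lp'"
            )

        def endpoints(d: BinaryDataset) -> np.ndarray:
            bi = match(estimate_observed_distribution(d))
            return np.array([bi.lower, bi.upper])
    else:
        raise ValueError(f"method must be 'symbolic' or 'lp', got {method!r}")

    lower_res, upper_res = bootstrap(
        data, endpoints, B=B, level=level, seed=seed, stratify_by_arm=stratify_by_arm
    )
    return lower_res, upper_res
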