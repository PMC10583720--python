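"""Point identification of cross-direct effects by the g-formula.

Absent residual confounding, every nested counterfactual mean in the effect
registry is identified by standardizing outcome-model predictions over the
relevant mediator law and the empirical covariate distribution, e.g.

    E{Y(x, m1, M2(x2, m1'))}
      = n^-1 sum_i sum_j P(Y=1 | C_i, x, m1, M2=j) P(M2=j | C_i, x2, m1'),

and analogously for the other argument patterns.  Three conditional models
are needed: Y | C, X, M1, M2;  M1 | C, X;  and M2 | C, X (variant A) or
M2 | C, X, M1 (variant B).  Without covariates, saturated models (stratified
empirical frequencies) make the plug-in fully nonparametric; with
covariates, logistic regressions are fitted (by default with all two-way
interactions among covariates, treatment, and mediators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Union

import numpy as np
import pandas as pd

from .distributions import BinaryDataset, ObservedDistribution, estimate_observed_distribution
from .estimands import (
    Controlled,
    Dag,
    EffectSpec,
    NaturalM1,
    NaturalM2,
    NaturalM2GivenM1,
    NaturalM2NaturalM1,
    PotentialOutcomeSpec,
    canonical_levels,
    make_effect,
    CROSS_EFFECT_NAMES,
)
from .exceptions import DagCompatibilityError, EmptyStratumError

__all__ = [
    "ModelSet",
    "fit_models",
    "po_mean",
    "po_mean_a",
    "po_mean_b",
    "po_mean_c",
    "po_mean_d",
    "estimate_effect",
    "effects_from_table",
]


def _check_stratum(value: np.ndarray, what: str) -> np.ndarray:
    if np.isnan(value).any():
        raise EmptyStratumError(f"saturated model queried in empty stratum: {what}")
    return value


@dataclass
class ModelSet:
    """Fitted conditional models plus the empirical covariate sample.

    ``predict_*`` callables return one probability per covariate-sample row
    (a single row when there are no covariates); plug-in means average over
    those rows, which realizes standardization over the empirical law of C.
    """

    dag: Dag
    predict_y: Callable[[int, int, int], np.ndarray]
    predict_m1: Callable[[int], np.ndarray]
    predict_m2: Callable[..., np.ndarray]  # (x) under A, (x, m1) under B
    covariate_sample: pd.DataFrame
    arm_y_means: Optional[np.ndarray] = None  # empirical E[Y | X=x], x = 0, 1
    model_form: str = "saturated"

    @classmethod
    def from_table(cls, table: Union[ObservedDistribution, np.ndarray], dag: Union[Dag, str]):
        """Saturated models implied directly by a 16-cell probability table.

        Conditionals with empty conditioning strata come out NaN and raise
        :class:`EmptyStratumError` when queried.
        """
        dag = Dag(dag)
        p = table.p if isinstance(table, ObservedDistribution) else np.asarray(table, float)
        with np.errstate(invalid="ignore", divide="ignore"):
            joint_m = p.sum(axis=0)  # [m1, m2, x]
            py = p[1] / joint_m  # P(Y=1 | m1, m2, x)
            m1_marg = p.sum(axis=(0, 2))  # [m1, x]
            pm1 = m1_marg[1] / m1_marg.sum(axis=0)  # P(M1=1 | x)
            if dag is Dag.B:
                pm2 = joint_m[:, 1, :] / joint_m.sum(axis=1)  # P(M2=1 | m1, x)
            else:
                m2_marg = p.sum(axis=(0, 1))  # [m2, x]
                pm2 = m2_marg[1] / m2_marg.sum(axis=0)  # P(M2=1 | x)
            y_arm = (p[1].sum(axis=(0, 1))) / p.sum(axis=(0, 1, 2))

        def predict_y(x, m1, m2):
            return _check_stratum(np.array([py[m1, m2, x]]), f"(x={x}, m1={m1}, m2={m2})")

        def predict_m1(x):
            return _check_stratum(np.array([pm1[x]]), f"M1 | x={x}")

        if dag is Dag.B:
            def predict_m2(x, m1):
                return _check_stratum(np.array([pm2[m1, x]]), f"M2 | x={x}, m1={m1}")
        else:
            def predict_m2(x, m1=None):
                return _check_stratum(np.array([pm2[x]]), f"M2 | x={x}")

        return cls(
            dag=dag,
            predict_y=predict_y,
            predict_m1=predict_m1,
            predict_m2=predict_m2,
            covariate_sample=pd.DataFrame(index=[0]),
            arm_y_means=np.asarray(y_arm, float),
            model_form="saturated",
        )


def _logistic_fit(df: pd.DataFrame, outcome: str, rhs_terms: list, form: str):
    """Fit a logistic regression, falling back to saturated frequencies on
    separation or non-convergence."""
    import statsmodels.formula.api as smf

    if form == "two_way":
        rhs = "(" + " + ".join(rhs_terms) + ")**2" if len(rhs_terms) > 1 else rhs_terms[0]
    else:
        rhs = " + ".join(rhs_terms)
    formula = f"{outcome} ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            model = smf.logit(formula, data=df).fit(disp=0, maxiter=200)
            if not model.mle_retvals.get("converged", True):
                raise RuntimeError("non-convergence")
            return model
        except Exception as exc:  # separation / singular design / non-convergence
            warnings.simplefilter("default")
            warnings.warn(
                f"logistic model for {outcome} did not converge ({exc}); "
                "falling back to stratified frequencies",
                stacklevel=2,
            )
            return None


def fit_models(
    data: BinaryDataset,
    dag: Union[Dag, str],
    model_form: Optional[str] = None,
) -> ModelSet:
    """Fit the three conditional models the g-formula needs.

    ``model_form`` is one of ``"saturated"`` (stratified frequencies; only
    legal without covariates), ``"main_effects"``, or ``"two_way"`` (all
    pairwise interactions among covariates, treatment, and mediators).  The
    default is saturated without covariates and two-way with them.
    """
    dag = Dag(dag)
    has_cov = data.covariates is not None and len(data.covariate_names) > 0
    if model_form is None:
        model_form = "two_way" if has_cov else "saturated"
    if model_form == "saturated":
        if has_cov:
            raise DagCompatibilityError(
                "saturated models are only supported without covariates; "
                "use 'main_effects' or 'two_way'"
            )
        dist = estimate_observed_distribution(data)
        return ModelSet.from_table(dist, dag)

    df = data.to_dataframe()
    cov_names = data.covariate_names
    fallback = ModelSet.from_table(estimate_observed_distribution(data), dag)

    my = _logistic_fit(df, "Y", ["X", "M1", "M2"] + cov_names, model_form)
    mm1 = _logistic_fit(df, "M1", ["X"] + cov_names, model_form)
    m2_rhs = ["X", "M1"] if dag is Dag.B else ["X"]
    mm2 = _logistic_fit(df, "M2", m2_rhs + cov_names, model_form)

    cov_sample = df[cov_names].copy() if cov_names else pd.DataFrame(index=range(len(df)))

    def predict_y(x, m1, m2):
        if my is None:
            return np.repeat(fallback.predict_y(x, m1, m2), len(cov_sample))
        ex = cov_sample.assign(X=x, M1=m1, M2=m2)
        return np.asarray(my.predict(ex))

    def predict_m1(x):
        if mm1 is None:
            return np.repeat(fallback.predict_m1(x), len(cov_sample))
        return np.asarray(mm1.predict(cov_sample.assign(X=x)))

    if dag is Dag.B:
        def predict_m2(x, m1):
            if mm2 is None:
                return np.repeat(fallback.predict_m2(x, m1), len(cov_sample))
            return np.asarray(mm2.predict(cov_sample.assign(X=x, M1=m1)))
    else:
        def predict_m2(x, m1=None):
            if mm2 is None:
                return np.repeat(fallback.predict_m2(x), len(cov_sample))
            return np.asarray(mm2.predict(cov_sample.assign(X=x)))

    arm_means = np.array([
        data.y[data.x == 0].mean() if (data.x == 0).any() else np.nan,
        data.y[data.x == 1].mean() if (data.x == 1).any() else np.nan,
    ])
    return ModelSet(
        dag=dag,
        predict_y=predict_y,
        predict_m1=predict_m1,
        predict_m2=predict_m2,
        covariate_sample=cov_sample,
        arm_y_means=arm_means,
        model_form=model_form,
    )


# ---------------------------------------------------------------------------
# plug-in potential-outcome means


def po_mean_a(models: ModelSet, x: int, x1: int, m2: int) -> float:
    """E{Y(x, M1(x1), m2)}: average outcome predictions over the law of
    M1 at exposure x1, then over the covariate sample."""
    w1 = models.predict_m1(x1)
    val = models.predict_y(x, 1, m2) * w1 + models.predict_y(x, 0, m2) * (1.0 - w1)
    return float(np.mean(val))


def po_mean_b(models: ModelSet, x: int, m1: int, x2: int, m1_prime: Optional[int] = None) -> float:
    """E{Y(x, m1, M2(x2, m1'))} under variant B; with ``m1_prime=None``,
    E{Y(x, m1, M2(x2))} under variant A."""
    if models.dag is Dag.B:
        if m1_prime is None:
            raise DagCompatibilityError("variant B requires the inner m1' level for M2")
        w2 = models.predict_m2(x2, m1_prime)
    else:
        if m1_prime is not None:
            raise DagCompatibilityError("variant A's M2 law takes no m1 argument")
        w2 = models.predict_m2(x2)
    val = models.predict_y(x, m1, 1) * w2 + models.predict_y(x, m1, 0) * (1.0 - w2)
    return float(np.mean(val))


def po_mean_c(models: ModelSet, x: int, m1: int, x2: int, x3: int) -> float:
    """E{Y(x, m1, M2(x2, M1(x3)))} under variant B: marginalize the inner
    natural M1 out of the M2 law."""
    if models.dag is not Dag.B:
        raise DagCompatibilityError("inner natural M1 requires variant B")
    wm1 = models.predict_m1(x3)
    w2 = wm1 * models.predict_m2(x2, 1) + (1.0 - wm1) * models.predict_m2(x2, 0)
    val = models.predict_y(x, m1, 1) * w2 + models.predict_y(x, m1, 0) * (1.0 - w2)
    return float(np.mean(val))


def po_mean_d(models: ModelSet, x: int, x1: int, x2: int, m1_prime: int) -> float:
    """E{Y(x, M1(x1), M2(x2, m1'))} under variant B: outer M1 natural at x1
    and M2 natural at (x2, m1'), drawn independently."""
    if models.dag is not Dag.B:
        raise DagCompatibilityError("the inner controlled m1' form requires variant B")
    w1 = models.predict_m1(x1)
    w2 = models.predict_m2(x2, m1_prime)
    val = 0.0
    for m1, wa in ((1, w1), (0, 1.0 - w1)):
        for m2, wb in ((1, w2), (0, 1.0 - w2)):
            val = val + models.predict_y(x, m1, m2) * wa * wb
    return float(np.mean(val))


def _te_mean(models: ModelSet, x: int) -> float:
    """E{Y(x)} by full standardization (shared natural M1 feeding M2)."""
    w1 = models.predict_m1(x)
    val = 0.0
    for m1, wa in ((1, w1), (0, 1.0 - w1)):
        if models.dag is Dag.B:
            w2 = models.predict_m2(x, m1)
        else:
            w2 = models.predict_m2(x)
        for m2, wb in ((1, w2), (0, 1.0 - w2)):
            val = val + models.predict_y(x, m1, m2) * wa * wb
    return float(np.mean(val))


def po_mean(models: ModelSet, po: PotentialOutcomeSpec) -> float:
    """Dispatch a potential-outcome mean to the matching plug-in form."""
    po.check_dag(models.dag)
    a1, a2 = po.m1_arg, po.m2_arg
    if isinstance(a1, NaturalM1) and isinstance(a2, Controlled):
        return po_mean_a(models, po.x, a1.x1, a2.level)
    if isinstance(a1, Controlled) and isinstance(a2, NaturalM2):
        return po_mean_b(models, po.x, a1.level, a2.x2, None)
    if isinstance(a1, Controlled) and isinstance(a2, NaturalM2GivenM1):
        return po_mean_b(models, po.x, a1.level, a2.x2, a2.m1)
    if isinstance(a1, Controlled) and isinstance(a2, NaturalM2NaturalM1):
        return po_mean_c(models, po.x, a1.level, a2.x2, a2.x3)
    if isinstance(a1, NaturalM1) and isinstance(a2, NaturalM2GivenM1):
        return po_mean_d(models, po.x, a1.x1, a2.x2, a2.m1)
    if isinstance(a1, NaturalM1) and isinstance(a2, NaturalM2NaturalM1):
        if a1.x1 == a2.x3 == po.x and a2.x2 == po.x:
            return _te_mean(models, po.x)
        raise DagCompatibilityError(
            "both-natural potential outcomes are only supported with all "
            "exposure arguments equal (the total-effect component)"
        )
    if isinstance(a1, NaturalM1) and isinstance(a2, NaturalM2):
        if a1.x1 == po.x and a2.x2 == po.x:
            return _te_mean(models, po.x)
        raise DagCompatibilityError(
            "both-natural potential outcomes are only supported with all "
            "exposure arguments equal (the total-effect component)"
        )
    raise DagCompatibilityError(f"unsupported argument pattern ({a1!r}, {a2!r})")


def estimate_effect(spec: EffectSpec, models: ModelSet) -> float:
    """Plug-in estimate of a contrast: treated mean minus control mean.

    For the total effect without covariates the raw arm means of Y are used
    (equivalent to standardization under a saturated model, and exactly the
    randomized-trial estimator).
    """
    if Dag(spec.dag) is not models.dag:
        raise DagCompatibilityError(
            f"spec is for variant {spec.dag.value}, models for {models.dag.value}"
        )
    if spec.is_null_contrast:
        return 0.0
    no_cov = models.covariate_sample.shape[1] == 0
    if spec.name == "total_effect" and no_cov and models.arm_y_means is not None:
        return float(models.arm_y_means[spec.treated.x] - models.arm_y_means[spec.control.x])
    return po_mean(models, spec.treated) - po_mean(models, spec.control)


def effects_from_table(
    table: Union[ObservedDistribution, np.ndarray],
    dag: Union[Dag, str] = Dag.B,
    include_total: bool = True,
) -> Dict[str, float]:
    """All canonical-level cross effects (and the TE) from a 16-cell table.

    This is the saturated no-covariate plug-in in closed form; it is the
    fast path used by bootstrap statistics.
    """
    dag = Dag(dag)
    models = ModelSet.from_table(table, dag)
    names = [n for n in CROSS_EFFECT_NAMES if dag is Dag.B or not n.startswith("crossB_")]
    if include_total:
        names.append("total_effect")
    out = {}
    for name in names:
        spec = make_effect(name, canonical_levels(name), dag)
        out[name] = estimate_effect(spec, models)
    return out
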