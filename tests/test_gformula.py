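import numpy as np
import pytest

from crossfx.distributions import BinaryDataset, estimate_observed_distribution
from crossfx.estimands import Dag, canonical_levels, make_effect, relabel_mediators
from crossfx.exceptions import DagCompatibilityError
from crossfx.gformula import (
    ModelSet,
    effects_from_table,
    estimate_effect,
    fit_models,
    po_mean_a,
    po_mean_b,
    po_mean_c,
)
from crossfx.lp_bounds import marginalize_q, true_effects_from_q
from crossfx.synthetic_data import (
    dataset_from_cell_counts,
    product_q,
    response_marginal_from_probs,
    unconfounded_q,
)

ALL_NAMES = (
    "crossA_M1nat",
    "crossA_M2nat",
    "crossB_M2ctrl_inner",
    "crossB_M2nat_inner_nat",
    "crossB_bothnat_inner_ctrl",
)


def _quarter_q(dag=Dag.B):
    """An unconfounded q with dyadic (quarter-valued) conditional laws, so the
    implied observed table is exactly representable by 64 records per arm."""
    pm1 = (0.25, 0.75)
    pm2 = (0.25, 0.5, 0.5, 0.75) if dag is Dag.B else (0.25, 0.5)
    py = (0.25, 0.5, 0.25, 0.75, 0.5, 0.25, 0.75, 0.5)
    return product_q(
        response_marginal_from_probs(pm1),
        response_marginal_from_probs(pm2),
        response_marginal_from_probs(py),
        dag=dag,
    )


def _enumeration_dataset(q):
    dist = marginalize_q(q)
    counts = dist.p * 64
    assert np.allclose(counts, np.round(counts), atol=1e-9)
    return dataset_from_cell_counts(np.round(counts).astype(int))


class TestSaturatedModels:
    def test_saturated_equals_stratified_frequencies(self, uniform_dataset):
        models = fit_models(uniform_dataset, Dag.B)
        assert models.model_form == "saturated"
        for x in (0, 1):
            for m1 in (0, 1):
                for m2 in (0, 1):
                    assert models.predict_y(x, m1, m2)[0] == pytest.approx(0.5)

    def test_constant_outcome(self):
        data = dataset_from_cell_counts(
            np.array([np.zeros((2, 2, 2)), np.ones((2, 2, 2))], dtype=int)
        )
        models = fit_models(data, Dag.B)
        assert models.predict_y(1, 0, 1)[0] == 1.0

    def test_mediator_irrelevant_outcome_gives_arm_mean(self):
        # P(Y=1 | x, m1, m2) = 0.75 if x else 0.25, for every (m1, m2)
        counts = np.zeros((2, 2, 2, 2), int)
        counts[1, :, :, 1] = 3
        counts[0, :, :, 1] = 1
        counts[1, :, :, 0] = 1
        counts[0, :, :, 0] = 3
        data = dataset_from_cell_counts(counts)
        models = fit_models(data, Dag.B)
        assert po_mean_a(models, 1, 0, 0) == pytest.approx(0.75)
        assert po_mean_b(models, 0, 1, 1, 0) == pytest.approx(0.25)

    def test_degenerate_mediator_reduces_sum(self):
        q = _quarter_q()
        models = ModelSet.from_table(marginalize_q(q), Dag.B)
        # forcing pM1 = 1 is the m1 = 1 slice
        w = models.predict_m1(1)[0]
        lhs = po_mean_a(models, 1, 1, 0)
        rhs = w * models.predict_y(1, 1, 0)[0] + (1 - w) * models.predict_y(1, 0, 0)[0]
        assert lhs == pytest.approx(rhs)
        # inner natural M1 degenerate at x3 with pM1(x3) recovers po_mean_b mix
        pm13 = models.predict_m1(0)[0]
        c = po_mean_c(models, 1, 0, 0, 0)
        b1 = po_mean_b(models, 1, 0, 0, 1)
        b0 = po_mean_b(models, 1, 0, 0, 0)
        assert c == pytest.approx(pm13 * b1 + (1 - pm13) * b0)


class TestExactRecovery:
    def test_full_enumeration_recovers_truth(self):
        q = _quarter_q()
        data = _enumeration_dataset(q)
        models = fit_models(data, Dag.B, "saturated")
        for name in ALL_NAMES + ("total_effect",):
            spec = make_effect(name, canonical_levels(name), Dag.B)
            est = estimate_effect(spec, models)
            assert est == pytest.approx(true_effects_from_q(q, spec), abs=1e-10)

    def test_table_route_recovers_truth_random_unconfounded_q(self):
        q = unconfounded_q(Dag.B, seed=3)
        eff = effects_from_table(marginalize_q(q), Dag.B)
        for name, est in eff.items():
            spec = make_effect(name, canonical_levels(name), Dag.B)
            assert est == pytest.approx(true_effects_from_q(q, spec), abs=1e-10)

    def test_null_contrast_is_exactly_zero(self):
        q = unconfounded_q(Dag.B, seed=4)
        models = ModelSet.from_table(marginalize_q(q), Dag.B)
        spec = make_effect("crossA_M1nat", {"x": 1, "xp": 1, "x1": 0, "m2": 0}, Dag.B)
        assert estimate_effect(spec, models) == 0.0


class TestSymmetry:
    def test_variant_a_relabel_matches_mediator_swap(self):
        q = unconfounded_q(Dag.A, seed=6)
        dist = marginalize_q(q)
        spec = make_effect("crossA_M1nat", canonical_levels("crossA_M1nat"), Dag.A)
        est = estimate_effect(spec, ModelSet.from_table(dist, Dag.A))
        swapped_est = estimate_effect(
            relabel_mediators(spec), ModelSet.from_table(dist.swap_mediators(), Dag.A)
        )
        assert est == pytest.approx(swapped_est, abs=1e-12)

    def test_effects_bounded(self):
        q = unconfounded_q(Dag.B, seed=8)
        for est in effects_from_table(marginalize_q(q), Dag.B).values():
            assert -1.0 <= est <= 1.0


class TestCovariateModels:
    @pytest.fixture()
    def covariate_data(self):
        rng = np.random.default_rng(21)
        n = 800
        c = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n)
        m1 = (rng.random(n) < 0.3 + 0.3 * x + 0.1 * c).astype(int)
        m2 = (rng.random(n) < 0.2 + 0.2 * x + 0.2 * m1).astype(int)
        y = (rng.random(n) < 0.2 + 0.2 * x + 0.2 * m2 + 0.1 * c).astype(int)
        import pandas as pd

        return BinaryDataset(x, m1, m2, y, pd.DataFrame({"c": c}))

    def test_two_way_is_default_with_covariates(self, covariate_data):
        models = fit_models(covariate_data, Dag.B)
        assert models.model_form == "two_way"
        assert len(models.covariate_sample) == len(covariate_data)
        p = models.predict_y(1, 0, 1)
        assert ((0 <= p) & (p <= 1)).all()

    def test_two_way_estimate_close_to_saturated_for_noise_covariate(self):
        # when the covariate carries no signal, two-way logistic predictions
        # should nearly reproduce the saturated (stratified) plug-in
        rng = np.random.default_rng(30)
        n = 1500
        x = rng.integers(0, 2, n)
        m1 = (rng.random(n) < 0.3 + 0.3 * x).astype(int)
        m2 = (rng.random(n) < 0.2 + 0.2 * x + 0.2 * m1).astype(int)
        y = (rng.random(n) < 0.2 + 0.2 * x + 0.2 * m2).astype(int)
        import pandas as pd

        noise = pd.DataFrame({"c": rng.integers(0, 2, n)})
        spec = make_effect("crossB_M2ctrl_inner", canonical_levels("crossB_M2ctrl_inner"), Dag.B)
        with_cov = estimate_effect(
            spec, fit_models(BinaryDataset(x, m1, m2, y, noise), Dag.B, "two_way")
        )
        no_cov = estimate_effect(spec, fit_models(BinaryDataset(x, m1, m2, y), Dag.B))
        assert with_cov == pytest.approx(no_cov, abs=0.05)

    def test_saturated_with_covariates_rejected(self, covariate_data):
        with pytest.raises(DagCompatibilityError):
            fit_models(covariate_data, Dag.B, "saturated")
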