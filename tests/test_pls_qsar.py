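"""PLS regression: oracles, cross-validation, prediction, contribution map."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repelqsar.dataset_io import ActivityVector
from repelqsar.molgraph import parse_smiles
from repelqsar.atomic_fields import compute_fields
from repelqsar.pls_qsar import (
    PLSModel,
    crossval_q2,
    factor_dynamics,
    field_contributions,
    fit_pls,
    predict,
)
from repelqsar.supergraph import build_msg, descriptor_matrix


def _frame(arr, prefix="v"):
    cols = [f"v{j:03d}|Q" for j in range(arr.shape[1])]
    idx = [f"c{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=idx, columns=cols)


def _activity(values):
    return ActivityVector(
        ids=tuple(f"c{i}" for i in range(len(values))),
        values=tuple(float(v) for v in values),
        direction="lower_med_more_active",
    )


class TestFitPls:
    def test_full_rank_pls_equals_ordinary_least_squares(self, rng):
        """With k = rank, PLS1 reproduces the OLS fit (normal-equations oracle)."""
        X = rng.normal(size=(8, 4))
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ beta + 1.0
        Xf, yv = _frame(X), _activity(y)
        model = fit_pls(Xf, yv, 4)
        # independent oracle: normal equations on centered data
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        fitted_ols = Xc @ b_ols + y.mean()
        assert np.abs(model.fitted.to_numpy() - fitted_ols).max() < 1e-8
        assert model.r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_informative_column_recovers_sign(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, rng.normal(size=30) * 1e-12])
        y = -2.5 * x + rng.normal(size=30) * 0.01
        model = fit_pls(_frame(X), _activity(y), 1)
        assert model.coef_original[0] < 0

    def test_k_capped_at_rank_with_warning(self, rng, caplog):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model = fit_pls(_frame(X), _activity(y), 10)
        assert model.n_factors == min(5 - 1, 3)

    def test_constant_columns_dropped(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.14)])
        model = fit_pls(_frame(X), _activity(rng.normal(size=20)), 1)
        assert len(model.column_names) == 1

    def test_deterministic(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        m1 = fit_pls(_frame(X), _activity(y), 3)
        m2 = fit_pls(_frame(X), _activity(y), 3)
        assert np.array_equal(m1.coef_scaled, m2.coef_scaled)

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        m = fit_pls(_frame(X), _activity(y), 2)
        back = PLSModel.from_json(m.to_json())
        assert np.allclose(back.coef_scaled, m.coef_scaled)
        assert back.column_names == m.column_names
        assert np.allclose(back.predict_rows(_frame(X)), m.predict_rows(_frame(X)))


class TestCrossval:
    def test_noiseless_linear_data_predicts_out_of_fold(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, -1.0, 2.0]) + 0.5
        q2 = crossval_q2(_frame(X), _activity(y), 3)
        assert q2 > 0.99

    def test_pure_noise_gives_nonpositive_q2_in_expectation(self, rng):
        """Permutation oracle: shuffled activities must not look predictive."""
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8)
        q2s = []
        for _ in range(200):
            perm = rng.permutation(len(y))
            q2s.append(
                crossval_q2(_frame(X), _activity(y[perm]), 2, n_repeats=2, seed=3)
            )
        assert np.mean(q2s) <= 0.0

    def test_bit_reproducible_given_seed(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        a = crossval_q2(_frame(X), _activity(y), 2, seed=11)
        b = crossval_q2(_frame(X), _activity(y), 2, seed=11)
        assert a == b

    def test_leave_fraction_bounds(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            crossval_q2(_frame(X), _activity(rng.normal(size=20)), 2,
                        leave_fraction=0.7)


class TestFactorDynamics:
    def test_r2_nondecreasing_in_k(self, headline_dynamics):
        r2 = headline_dynamics.table["R2"].to_numpy()
        assert np.all(np.diff(r2) >= -1e-10)

    def test_rank2_signal_selects_two_factors(self, rng):
        t1, t2 = rng.normal(size=(2, 60))
        load = rng.normal(size=(2, 10))
        X = np.outer(t1, load[0]) + np.outer(t2, load[1])
        y = 2.0 * t1 - 1.0 * t2
        fd = factor_dynamics(_frame(X), _activity(y), k_max=6)
        assert fd.selected_k == 2

    def test_k_max_validation(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            factor_dynamics(_frame(X), _activity(rng.normal(size=10)), k_max=1)


@pytest.fixture(scope="module")
def small_world():
    smiles = {
            "a": "CCCCCC(=O)N(C)CC",
            "b": "CCCCC(=O)N(C)CC",
            "c": "CCCC(=O)N(C)CC",
            "d": "CCCCCC(=O)N(CC)CC",
            "e": "CCCCCC(=O)N(C)CCC",
            "f": "CCCCCCC(=O)N(C)CC",
            "g": "CC(C)CC(=O)N(C)CC",
            "h": "CCCCCC(=O)N(C)CCCC",
            "i": "CCC(=O)N(C)CC",
        "j": "CCCCCCCC(=O)N(C)CC",
    }
    graphs = [parse_smiles(s, i) for i, s in smiles.items()]
    fvs = {g.id: compute_fields(g) for g in graphs}
    sg, maps = build_msg(graphs)
    X, _ = descriptor_matrix(sg, maps, fvs)
    rng = np.random.default_rng(0)
    y = ActivityVector(
        ids=tuple(smiles),
        values=tuple(rng.normal(size=len(smiles))),
        direction="lower_med_more_active",
    )
    model = fit_pls(X, y, 3)
    return smiles, graphs, fvs, sg, model


class TestPredict:
    def test_training_compound_prediction_equals_fitted_value(self, small_world):
        smiles, graphs, fvs, sg, model = small_world
        g = graphs[0]
        pred = predict(model, sg, g, fvs[g.id])
        assert pred.log10_med == pytest.approx(model.fitted[g.id], abs=1e-9)
        assert pred.med == pytest.approx(10 ** model.fitted[g.id])
        assert pred.out_of_msg_fraction == 0.0
        assert pred.med > 0

    def test_out_of_domain_molecule_flagged_but_predicted(self, small_world):
        _, _, _, sg, model = small_world
        g = parse_smiles("OCC(O)C(O)CO", "polyol")  # nothing like the amides
        fv = compute_fields(g)
        pred = predict(model, sg, g, fv)
        assert np.isfinite(pred.med)
        assert pred.out_of_msg_fraction > 0.0


class TestContributionMap:
    def test_unit_total_absolute_impact(self, headline_model, msg_and_mappings):
        sg, _ = msg_and_mappings
        cmap = field_contributions(headline_model, sg)
        assert cmap.total_abs() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_coefficients_yield_zero_map(self, msg_and_mappings):
        sg, _ = msg_and_mappings
        m = PLSModel(
            n_factors=1,
            column_names=("v000|Q",),
            means=np.zeros(1),
            scales=np.ones(1),
            coef_scaled=np.zeros(1),
            y_mean=0.0,
            all_columns=("v000|Q", "v001|Q"),
        )
        cmap = field_contributions(m, sg)
        assert (cmap.table["impact"] == 0).all()

    def test_sign_flip_into_activity_orientation(self, rng):
        # a column that raises log MED (lowers activity) must map to a
        # negative (blue) impact
        x = rng.normal(size=40)
        X = np.column_stack([x, rng.normal(size=40)])
        y = 3.0 * x
        model = fit_pls(_frame(X), _activity(y), 2)
        cmap = field_contributions(model, None)
        assert cmap.impact(0, "Q") < 0
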