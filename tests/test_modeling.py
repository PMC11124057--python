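"""Splits, custom scoring, TPE tuning, network training and ensembling."""

import math

import numpy as np
import pytest
from sklearn.linear_model import Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from desolv import tpe
from desolv.modeling import (
    Candidate,
    DEFAULT_HIDDEN_LAYERS,
    NetworkSpec,
    ScoreBreakdown,
    SplitSpec,
    build_ensemble,
    custom_score,
    rmsd,
    split_dataset,
    split_sizes,
    train_network,
    tune,
)


class TestSplit:
    def test_581_records_split_406_88_87(self):
        assert split_sizes(581, (0.70, 0.15, 0.15)) == (406, 88, 87)

    def test_small_split(self):
        assert split_sizes(10, (0.8, 0.1, 0.1)) == (8, 1, 1)

    def test_disjoint_exhaustive_and_deterministic(self):
        records = list(range(100))
        a = split_dataset(records, SplitSpec(seed=7))
        b = split_dataset(records, SplitSpec(seed=7))
        assert a == b
        merged = sorted(a[0] + a[1] + a[2])
        assert merged == records
        c = split_dataset(records, SplitSpec(seed=8))
        assert c != a

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], SplitSpec())


def _linear_data(n=120, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + noise * rng.normal(size=n)
    return X, y


class TestCustomScore:
    def test_perfect_model_on_noiseless_linear_data_scores_near_zero(self):
        X, y = _linear_data()
        model = Pipeline([("s", StandardScaler()), ("e", Ridge(1e-8))])
        br = custom_score(model, X, y, seed=0)
        assert br.base_error < 1e-6
        assert br.lca_penalty < 1e-6

    def test_lambda_zero_reduces_to_base_error(self):
        X, y = _linear_data(noise=0.3)
        model = Pipeline([("s", StandardScaler()), ("e", Ridge(1.0))])
        br = custom_score(model, X, y, lam=0.0, seed=0)
        assert br.total == br.base_error

    def test_memorizing_model_scores_worse_than_regularized(self):
        """1-NN has zero train error but poor generalisation: the LCA
        penalty must rank it below ridge on the same noisy data."""
        X, y = _linear_data(noise=0.5, seed=0)
        knn = Pipeline(
            [("s", StandardScaler()), ("e", KNeighborsRegressor(n_neighbors=1))]
        )
        ridge = Pipeline([("s", StandardScaler()), ("e", Ridge(1.0))])
        assert (
            custom_score(knn, X, y, seed=0).total
            > custom_score(ridge, X, y, seed=0).total
        )

    def test_degenerate_subset_rejected(self):
        X, y = _linear_data(n=5)
        model = Pipeline([("s", StandardScaler()), ("e", Ridge(1.0))])
        with pytest.raises(ValueError):
            custom_score(model, X, y)


class TestTPE:
    def test_single_trial_returns_those_params(self):
        space = [tpe.Real("p", 0.0, 1.0)]
        trials = tpe.minimize(lambda q: (q["p"] - 0.3) ** 2, space, 1, seed=0)
        assert len(trials) == 1
        assert 0.0 <= trials[0].params["p"] <= 1.0

    def test_quadratic_surface_minimizer_found_within_ten_percent(self):
        space = [tpe.Real("p", 0.0, 1.0)]
        trials = tpe.minimize(
            lambda q: (q["p"] - 0.3) ** 2, space, 200, seed=1
        )
        best = min(trials, key=lambda t: t.value)
        assert abs(best.params["p"] - 0.3) <= 0.03

    def test_identical_seeds_identical_trial_sequence(self):
        space = [
            tpe.Real("x", 1e-3, 1e3, log=True),
            tpe.Integer("k", 1, 10),
            tpe.Categorical("c", ("a", "b")),
        ]

        def obj(q):
            return math.log10(q["x"]) ** 2 + q["k"] + (q["c"] == "b")

        t1 = tpe.minimize(obj, space, 40, seed=5)
        t2 = tpe.minimize(obj, space, 40, seed=5)
        assert [t.params for t in t1] == [t.params for t in t2]

    def test_all_trials_failing_raises_with_diagnostics(self):
        def bad(q):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="failed"):
            tpe.minimize(bad, [tpe.Real("p", 0, 1)], 3, seed=0)


class TestTrainNetwork:
    def test_default_architecture_is_the_reference_one(self):
        assert NetworkSpec().hidden_layer_sizes == (64, 17, 45, 54, 18, 14, 45, 61)
        assert NetworkSpec().activation == "relu"
        assert NetworkSpec().solver == "lbfgs"

    def test_single_layer_fits_noiseless_line(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(200, 1))
        y = 2.0 * X[:, 0] + 1.0
        model = train_network(
            NetworkSpec(hidden_layer_sizes=(16,), alpha=1e-6, max_iter=4000), X, y
        )
        pred = model.predict(X)
        ss = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert ss > 0.999

    def test_huge_alpha_collapses_predictions_to_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 2))
        y = X[:, 0] * 3.0 + 5.0
        model = train_network(
            NetworkSpec(hidden_layer_sizes=(8,), alpha=1e6, max_iter=2000), X, y
        )
        pred = model.predict(X)
        assert np.std(pred) < 0.1 * np.std(y)

    def test_non_finite_inputs_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError):
            train_network(NetworkSpec(hidden_layer_sizes=(4,)), X, np.array([1.0, 2.0]))


class _FixedModel:
    def __init__(self, preds):
        self.preds = np.asarray(preds, dtype=float)

    def predict(self, X):
        return self.preds[: len(X)]


def _cand(name, preds):
    return Candidate(
        name, {}, ScoreBreakdown(0.0, 0.0, 1.0, 0.0, 0.0), _FixedModel(preds)
    )


class TestEnsemble:
    def test_single_candidate_gets_weight_one(self):
        y = np.array([1.0, 2.0, 3.0])
        ens = build_ensemble([_cand("a", y + 0.1)], np.zeros((3, 1)), y)
        assert np.allclose(ens.weights, [1.0])

    def test_zero_error_member_dominates_and_other_is_pruned(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        ens = build_ensemble(
            [_cand("perfect", y), _cand("poor", y + 2.0)],
            np.zeros((4, 1)),
            y,
        )
        assert len(ens.members) == 1
        assert ens.members[0].name == "perfect"
        assert np.allclose(ens.weights, [1.0])

    def test_identical_candidates_share_weight_equally(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        preds = y + 0.5
        ens = build_ensemble(
            [_cand("a", preds), _cand("b", preds)], np.zeros((4, 1)), y
        )
        assert np.allclose(ens.weights, [0.5, 0.5], atol=1e-6)

    def test_weights_on_simplex_and_above_prune_threshold(
        self, feature_table, targets, dataset
    ):
        records, _ = dataset
        X = feature_table.to_numpy()
        y = targets.to_numpy()
        cands, _ = tune(X[:300], y[:300], n_trials=12, seed=0)
        from desolv.modeling import fit_candidates

        fit_candidates(cands, X[:300], y[:300], seed=0)
        ens = build_ensemble(cands, X[300:400], y[300:400])
        assert np.all(ens.weights >= 0.01)
        assert np.isclose(ens.weights.sum(), 1.0)

    def test_ensemble_validation_rmsd_not_worse_than_best_member(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        cands = [
            _cand("a", y + rng.normal(0, 0.5, 50)),
            _cand("b", y + rng.normal(0, 0.3, 50)),
            _cand("c", y + rng.normal(0, 0.8, 50)),
        ]
        ens = build_ensemble(cands, np.zeros((50, 1)), y)
        best_single = min(rmsd(y, c.model.predict(np.zeros((50, 1)))) for c in cands)
        ens_rmsd = rmsd(y, ens.predict(np.zeros((50, 1))))
        assert ens_rmsd <= best_single + 1e-8

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            build_ensemble([], np.zeros((2, 1)), np.zeros(2))


class TestPredict:
    def test_one_row_per_compound_system_and_fusion_skip(
        self, engine, selection
    ):
        from desolv.modeling import predict_solubility
        from desolv.systems import SolventSystem

        systems = [
            SolventSystem.des("ChCl", "TEG", 2.0, x) for x in (0.8, 0.9, 1.0)
        ]

        class Mean:
            def predict(self, X):
                return np.full(len(X), -2.0)

        with pytest.warns(UserWarning, match="no fusion data"):
            out = predict_solubility(
                Mean(),
                ["solute0", "solute1", "not_a_drug"],
                systems,
                298.15,
                engine,
                selection,
            )
        assert len(out) == 2 * 3
        assert set(out.columns) == {
            "compound", "system_id", "x_star_DES", "T_K", "log10_x_pred",
        }
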