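"""Model tuning, training, ensembling and analog prediction.

The workflow mirrors a tuned-regressor ensemble protocol: candidate
regressors are tuned by TPE minimisation of a custom score that adds a
learning-curve-analysis (LCA) generalisability penalty to a
cross-validated MAE; the best candidate per family is refit and
combined into an ensemble whose nonnegative weights minimise the
validation RMSD, with members contributing less than 1% pruned.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from scipy.optimize import minimize as scipy_minimize

from . import tpe
from .features import DescriptorEngine, SelectionReport, build_feature_table
from .records import SolubilityRecord
from .systems import SolventSystem

#: Hidden-layer sizes of the reference MLP architecture.
DEFAULT_HIDDEN_LAYERS = (64, 17, 45, 54, 18, 14, 45, 61)

#: Full-scale maximum L-BFGS iterations of the reference protocol
#: (desk-scale default is 10_000).
FULL_SCALE_MAX_ITER = 928_539

ENSEMBLE_PRUNE_THRESHOLD = 0.01


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation fractions and shuffle seed."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be positive")
        if not math.isclose(sum(self.fractions), 1.0, abs_tol=1e-9):
            raise ValueError("fractions must sum to 1")


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Two-stage ceil rounding: test split off first, then validation.

    n_test = ceil(n f_test); n_val = ceil((n - n_test) f_val / (f_train
    + f_val)); the train set takes the remainder.  581 records at
    (0.70, 0.15, 0.15) give (406, 88, 87).
    """
    f_train, f_test, f_val = fractions
    n_test = math.ceil(n * f_test)
    n_val = math.ceil((n - n_test) * f_val / (f_train + f_val))
    n_train = n - n_test - n_val
    if min(n_train, n_test, n_val) < 1:
        raise ValueError(f"cannot split {n} records into three nonempty sets")
    return n_train, n_test, n_val


def split_dataset(
    records: Sequence, spec: SplitSpec = SplitSpec()
) -> tuple[list, list, list]:
    """Seeded shuffle into disjoint, exhaustive train/test/validation lists."""
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    n_train, n_test, n_val = split_sizes(n, spec.fractions)
    order = np.random.default_rng(spec.seed).permutation(n)
    items = [records[i] for i in order]
    return (
        items[:n_train],
        items[n_train : n_train + n_test],
        items[n_train + n_test :],
    )


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSpec:
    """Feed-forward network hyperparameters (reference defaults)."""

    hidden_layer_sizes: tuple[int, ...] = DEFAULT_HIDDEN_LAYERS
    activation: str = "relu"
    alpha: float = 0.045
    learning_rate_mode: str = "adaptive"
    solver: str = "lbfgs"
    max_iter: int = 10_000
    random_state: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


def train_network(
    spec: NetworkSpec, features: np.ndarray | pd.DataFrame, targets: np.ndarray | pd.Series
) -> Pipeline:
    """Fit the network on (features, targets); returns the fitted pipeline.

    Features are z-scored with statistics of the training data only (the
    scaler is part of the pipeline and fit here).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in features or targets")
    model = make_network(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def make_network(spec: NetworkSpec = NetworkSpec()) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPRegressor(
                    hidden_layer_sizes=spec.hidden_layer_sizes,
                    activation=spec.activation,
                    alpha=spec.alpha,
                    learning_rate=spec.learning_rate_mode,
                    solver=spec.solver,
                    max_iter=spec.max_iter,
                    random_state=spec.random_state,
                ),
            ),
        ]
    )


def default_search_space() -> list[tpe.Param]:
    """Desk-scale mixed search space: ridge and small-MLP families."""
    return [
        tpe.Categorical("family", ("ridge", "mlp")),
        tpe.Real("ridge_alpha", 1e-3, 1e3, log=True),
        tpe.Integer("mlp_width", 4, 64),
        tpe.Integer("mlp_depth", 1, 2),
        tpe.Real("mlp_alpha", 1e-4, 1.0, log=True),
    ]


def model_from_params(params: dict[str, Any], seed: int = 0, max_iter: int = 400):
    """Instantiate the (unfitted) scaled estimator a trial describes."""
    family = params["family"]
    if family == "ridge":
        est = Ridge(alpha=params["ridge_alpha"])
    elif family == "mlp":
        est = MLPRegressor(
            hidden_layer_sizes=(params["mlp_width"],) * params["mlp_depth"],
            activation="relu",
            alpha=params["mlp_alpha"],
            solver="lbfgs",
            max_iter=max_iter,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown model family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("est", est)])


# ---------------------------------------------------------------------------
# custom score with LCA penalty
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreBreakdown:
    """Auditable decomposition of the custom model score."""

    base_error: float
    lca_penalty: float
    lam: float
    lca_val_mae: float
    lca_gap: float

    @property
    def total(self) -> float:
        return self.base_error + self.lam * self.lca_penalty


def _fit_silent(model, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def custom_score(
    model,
    X: np.ndarray,
    y: np.ndarray,
    k_lca: int = 2,
    lam: float = 1.0,
    cv: int = 3,
    seed: int = 0,
) -> ScoreBreakdown:
    """Cross-validated MAE plus a learning-curve generalisability penalty.

    The learning curve is evaluated at ``k_lca`` training-set sizes
    between 50% and 100% of the LCA training partition (2 points during
    tuning, 20 for final audits).  The penalty is the held-out MAE at
    the largest size plus the train/held-out MAE gap there, so models
    that memorise score strictly worse than equally accurate ones that
    generalise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < max(cv * 2, 8):
        raise ValueError(f"training subset too small for scoring (n={n})")
    # base: k-fold cross-validated MAE
    maes = []
    for tr, te in KFold(cv, shuffle=True, random_state=seed).split(X):
        m = _fit_silent(clone(model), X[tr], y[tr])
        maes.append(mean_absolute_error(y[te], m.predict(X[te])))
    base = float(np.mean(maes))
    # LCA on a fixed 75/25 partition of the data
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_hold = max(2, n // 4)
    hold, pool = order[:n_hold], order[n_hold:]
    sizes = np.unique(
        np.round(np.linspace(0.5, 1.0, max(k_lca, 2)) * len(pool)).astype(int)
    )
    sizes = sizes[sizes >= 2]
    train_mae = val_mae = math.nan
    for m_size in sizes:
        subset = pool[:m_size]
        fitted = _fit_silent(clone(model), X[subset], y[subset])
        train_mae = mean_absolute_error(y[subset], fitted.predict(X[subset]))
        val_mae = mean_absolute_error(y[hold], fitted.predict(X[hold]))
    gap = max(0.0, val_mae - train_mae)
    penalty = val_mae + gap
    return ScoreBreakdown(base, penalty, lam, val_mae, gap)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------


@dataclass
class Candidate:
    name: str
    params: dict[str, Any]
    score: ScoreBreakdown
    model: Any = None  # fitted pipeline, set by fit_candidates


def tune(
    X: np.ndarray,
    y: np.ndarray,
    n_trials: int = 100,
    seed: int = 0,
    space: list[tpe.Param] | None = None,
    lam: float = 1.0,
    k_lca: int = 2,
    trial_max_iter: int = 150,
) -> tuple[list[Candidate], list[tpe.Trial]]:
    """TPE-tune the search space against the custom score.

    Returns the best candidate per model family (ranked by score) and
    the full trial history.
    """
    space = space or default_search_space()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    breakdowns: dict[int, ScoreBreakdown] = {}
    counter = {"i": 0}

    def objective(params: dict[str, Any]) -> float:
        model = model_from_params(params, seed=seed, max_iter=trial_max_iter)
        br = custom_score(model, X, y, k_lca=k_lca, lam=lam, seed=seed)
        breakdowns[counter["i"]] = br
        counter["i"] += 1
        return br.total

    trials = tpe.minimize(objective, space, n_trials=n_trials, seed=seed)
    best_by_family: dict[str, tpe.Trial] = {}
    for t in trials:
        if not math.isfinite(t.value):
            continue
        fam = t.params["family"]
        if fam not in best_by_family or t.value < best_by_family[fam].value:
            best_by_family[fam] = t
    ranked = sorted(best_by_family.values(), key=lambda t: t.value)
    candidates = [
        Candidate(t.params["family"], dict(t.params), breakdowns[t.number])
        for t in ranked
    ]
    return candidates, trials


def fit_candidates(
    candidates: list[Candidate],
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int = 0,
    max_iter: int = 2000,
) -> list[Candidate]:
    """Refit each tuned candidate on the full training partition."""
    for c in candidates:
        c.model = _fit_silent(
            model_from_params(c.params, seed=seed, max_iter=max_iter),
            np.asarray(X_train, dtype=float),
            np.asarray(y_train, dtype=float),
        )
    return candidates


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


def rmsd(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


@dataclass
class EnsembleModel:
    """Weighted combination of fitted regressors on the simplex.

    Weights are nonnegative, sum to 1 and are all >= 1% after pruning.
    """

    members: list[Candidate]
    weights: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds = np.stack([c.model.predict(X) for c in self.members])
        return self.weights @ preds

    def to_card(self) -> dict:
        return {
            "members": [
                {
                    "family": c.name,
                    "params": c.params,
                    "score": asdict(c.score) | {"total": c.score.total},
                    "weight": float(w),
                }
                for c, w in zip(self.members, self.weights)
            ]
        }


def optimize_simplex_weights(P: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Nonnegative weights summing to 1 minimising RMSD of P.T @ w vs y."""
    k = P.shape[0]
    if k == 1:
        return np.array([1.0])
    w0 = np.full(k, 1.0 / k)

    def loss(w):
        return float(np.mean((w @ P - y) ** 2))

    def grad(w):
        return 2.0 / len(y) * (P @ (w @ P - y))

    res = scipy_minimize(
        loss,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def build_ensemble(
    candidates: list[Candidate],
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> EnsembleModel:
    """Validation-RMSD-optimal ensemble with <1% members pruned.

    When one model dominates, the optimisation collapses onto it and
    the ensemble reduces to single-best selection.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    fitted = [c for c in candidates if c.model is not None]
    if not fitted:
        raise ValueError("candidates must be fitted before ensembling")
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    P = np.stack([c.model.predict(X_val) for c in fitted])
    w = optimize_simplex_weights(P, y_val)
    keep = w >= ENSEMBLE_PRUNE_THRESHOLD
    if not keep.any():
        keep[int(np.argmax(w))] = True
    members = [c for c, k in zip(fitted, keep) if k]
    w = w[keep]
    if len(members) > 1:
        # re-optimise on the surviving members so weights stay optimal
        w = optimize_simplex_weights(P[keep], y_val)
        again = w >= ENSEMBLE_PRUNE_THRESHOLD
        members = [c for c, k in zip(members, again) if k]
        w = w[again]
    w = w / w.sum()
    return EnsembleModel(members, w)


# ---------------------------------------------------------------------------
# analog prediction
# ---------------------------------------------------------------------------


def predict_solubility(
    model,
    compounds: Sequence[str],
    systems: Sequence[SolventSystem],
    T: float,
    engine: DescriptorEngine,
    selection: SelectionReport,
) -> pd.DataFrame:
    """Predicted log10 solubility for compounds across solvent systems.

    Compounds without fusion data cannot be featurised (the SLE
    descriptor requires melting data) and are skipped with a warning.
    One output row per (compound, system).
    """
    rows = []
    pseudo: list[SolubilityRecord] = []
    for comp in compounds:
        if comp not in engine.fusion:
            warnings.warn(
                f"skipping {comp}: no fusion data, SLE descriptor unavailable",
                stacklevel=2,
            )
            continue
        for sys_ in systems:
            pseudo.append(
                SolubilityRecord(
                    f"{comp}@{sys_.system_id}", comp, sys_, T, 0.5
                )
            )
            rows.append(
                {
                    "compound": comp,
                    "system_id": sys_.system_id,
                    "x_star_DES": sys_.x_star_des,
                    "T_K": T,
                }
            )
    out = pd.DataFrame(rows)
    if not len(out):
        return out.reindex(
            columns=["compound", "system_id", "x_star_DES", "T_K", "log10_x_pred"]
        )
    feats = build_feature_table(pseudo, engine, selection)
    out["log10_x_pred"] = model.predict(feats.to_numpy())
    return out


def save_model_card(path, ensemble: EnsembleModel, extra: dict | None = None) -> None:
    card = ensemble.to_card()
    card.update(extra or {})
    with open(path, "w") as fh:
        json.dump(card, fh, indent=2, default=str)
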