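"""Feature ranking, signature-size search and range-shift regression.

The model stage ranks cluster-representative features by one of four
methods (Spearman correlation, minimum-redundancy-maximum-relevance,
forward-selection linear regression, Lasso path order), then searches
signature sizes 1–10 under 3×3-fold cross-validation for each of four
learners (ordinary least squares, random forest, gradient-boosted trees,
RBF support-vector regression).  The signature with the lowest mean CV
RMSE is refit on the full training set.  A full grid is 5 feature sets ×
4 ranking methods × 4 learners = 80 configurations per data subset.

Hyperparameters are fixed (no tuning) for reproducibility; tree/boosting
sizes are configurable through :class:`LearnerParams` so studies can be
scaled down without touching the procedure.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import lasso_path
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .features import ClusterMap, cluster_features, feature_columns, filter_features
from .spectra import ValidationError

__all__ = [
    "RANKING_METHODS",
    "LEARNERS",
    "LearnerParams",
    "RankingResult",
    "Predictor",
    "SignatureModel",
    "GridResult",
    "rank_features",
    "cv_signature_search",
    "train_learner",
    "predict",
    "run_grid",
]

RANKING_METHODS: tuple[str, ...] = ("mrmr", "spearman", "forward_lr", "lasso")
LEARNERS: tuple[str, ...] = ("linear", "random_forest", "gradient_boosted_trees", "svm")

TARGET_COLUMN = "cavity_mm"


@dataclass(frozen=True)
class LearnerParams:
    """Fixed learner hyperparameters (no tuning)."""

    rf_trees: int = 500
    xgb_rounds: int = 500
    xgb_depth: int = 3
    xgb_learning_rate: float = 0.1
    svm_c: float = 1.0
    svm_epsilon: float = 0.1


@dataclass(frozen=True)
class RankingResult:
    """An ordering of the candidate features, best first."""

    method: str
    features: tuple[str, ...]
    scores: dict[str, float]


def _abs_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Spearman ρ| of each column of x with y (NaN-free input assumed)."""
    out = np.empty(x.shape[1])
    for i in range(x.shape[1]):
        rho = spearmanr(x[:, i], y).statistic
        out[i] = 0.0 if np.isnan(rho) else abs(rho)
    return out


def _order_desc(names: list[str], scores: np.ndarray) -> list[int]:
    """Indices by descending score, lexicographic names on ties."""
    return sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))


def _rank_mrmr(x: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[list[int], np.ndarray]:
    relevance = _abs_spearman(x, y)
    n = len(names)
    rho = spearmanr(x).statistic if n > 1 else np.array([[1.0]])
    rho = np.atleast_2d(np.nan_to_num(rho))
    if rho.shape != (n, n):
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    redundancy = np.abs(rho)
    selected: list[int] = []
    remaining = set(range(n))
    scores = np.empty(n)
    while remaining:
        if not selected:
            crit = {i: relevance[i] for i in remaining}
        else:
            crit = {
                i: relevance[i] - float(np.mean(redundancy[i, selected])) for i in remaining
            }
        best = min(crit, key=lambda i: (-crit[i], names[i]))
        scores[best] = crit[best]
        selected.append(best)
        remaining.discard(best)
    return selected, scores


def _rank_forward_lr(x: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[list[int], np.ndarray]:
    """Greedy least squares: repeatedly add the feature whose inclusion most
    reduces the residual sum of squares of an intercept-augmented OLS fit."""
    n_rows, n_feat = x.shape
    selected: list[int] = []
    remaining = set(range(n_feat))
    scores = np.empty(n_feat)
    rss_prev = float(((y - y.mean()) ** 2).sum())
    while remaining:
        best_i, best_rss = None, None
        for i in sorted(remaining, key=lambda i: names[i]):
            cols = selected + [i]
            design = np.column_stack([x[:, cols], np.ones(n_rows)])
            _, residual, rank, _ = np.linalg.lstsq(design, y, rcond=None)
            if residual.size and rank == design.shape[1]:
                rss = float(residual[0])
            else:
                coef = np.linalg.lstsq(design, y, rcond=None)[0]
                rss = float(((y - design @ coef) ** 2).sum())
            if best_rss is None or rss < best_rss - 1e-12:
                best_i, best_rss = i, rss
        scores[best_i] = rss_prev - best_rss
        rss_prev = best_rss
        selected.append(best_i)
        remaining.discard(best_i)
    return selected, scores


def _rank_lasso(x: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[list[int], np.ndarray]:
    """Order of first activation along a decreasing L1-regularisation path
    on standardised features; ties break by |coefficient| at the path end."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    yc = y - y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = lasso_path(xs, yc)
    active = np.abs(coefs) > 1e-12  # (n_features, n_alphas), alphas decreasing
    first = np.where(active.any(axis=1), active.argmax(axis=1), coefs.shape[1])
    end_coef = np.abs(coefs[:, -1])
    order = sorted(range(len(names)), key=lambda i: (first[i], -end_coef[i], names[i]))
    return order, -first.astype(float)


def rank_features(table: pd.DataFrame, method: str, seed: int = 0) -> RankingResult:
    """Rank candidate features on the training rows by ``method``.

    The table holds cluster-representative features plus the metadata
    block; the continuous target is the cavity thickness in mm.
    """
    if method not in RANKING_METHODS:
        raise ValidationError(f"unknown ranking method {method!r}")
    train = table[table["split"] == "train"] if "split" in table.columns else table
    names = feature_columns(train)
    if len(train) < 10:
        raise ValidationError(f"ranking needs >= 10 training rows, got {len(train)}")
    x = train[names].to_numpy(dtype=float)
    y = train[TARGET_COLUMN].to_numpy(dtype=float)
    if method == "spearman":
        scores = _abs_spearman(x, y)
        order = _order_desc(names, scores)
    elif method == "mrmr":
        order, scores = _rank_mrmr(x, y, names)
    elif method == "forward_lr":
        order, scores = _rank_forward_lr(x, y, names)
    else:
        order, scores = _rank_lasso(x, y, names)
    return RankingResult(
        method=method,
        features=tuple(names[i] for i in order),
        scores={names[i]: float(scores[i]) for i in range(len(names))},
    )


# ---------------------------------------------------------------------------
# learners


@dataclass
class Predictor:
    """A fitted regression model over a fixed signature."""

    kind: str
    signature: tuple[str, ...]
    state: object

    def _matrix(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            for name in self.signature:
                if name not in table.columns:
                    raise KeyError(f"missing signature column {name!r}")
            return table[list(self.signature)].to_numpy(dtype=float)
        x = np.asarray(table, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        return x

    def predict(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = self._matrix(table)
        if self.kind == "linear":
            coef, intercept = self.state
            return x @ coef + intercept
        if self.kind == "svm":
            scaler_mu, scaler_sd, est = self.state
            return est.predict((x - scaler_mu) / scaler_sd)
        return self.state.predict(x)

    def state_bytes(self) -> bytes:
        """Deterministic serialisation of the fitted state."""
        if self.kind == "linear":
            coef, intercept = self.state
            payload = ("linear", self.signature, coef.tobytes(), float(intercept))
        elif self.kind == "svm":
            mu, sd, est = self.state
            payload = (
                "svm",
                self.signature,
                mu.tobytes(),
                sd.tobytes(),
                est.support_vectors_.tobytes(),
                est.dual_coef_.tobytes(),
                est.intercept_.tobytes(),
            )
        elif self.kind == "gradient_boosted_trees":
            payload = ("xgb", self.signature, bytes(self.state.get_booster().save_raw(raw_format="json")))
        else:
            payload = ("rf", self.signature, pickle.dumps(self.state, protocol=5))
        return pickle.dumps(payload, protocol=5)


def train_learner(
    table: pd.DataFrame,
    signature: tuple[str, ...] | list[str],
    learner: str,
    seed: int = 0,
    params: LearnerParams = LearnerParams(),
) -> Predictor:
    """Fit one learner on all rows of ``table`` using ``signature``.

    linear: OLS (minimum-norm solution with a warning when the design is
    rank deficient); random forest and gradient-boosted trees with fixed
    sizes; SVM: RBF ε-regression on standardised features with kernel
    width 1/k (unit feature variance after standardisation).
    """
    signature = tuple(signature)
    if learner not in LEARNERS:
        raise ValidationError(f"unknown learner {learner!r}")
    for name in signature:
        if name not in table.columns:
            raise KeyError(f"missing signature column {name!r}")
    x = table[list(signature)].to_numpy(dtype=float)
    y = table[TARGET_COLUMN].to_numpy(dtype=float)
    if learner == "linear":
        design = np.column_stack([x, np.ones(len(y))])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            warnings.warn(
                "rank-deficient design; using the minimum-norm least-squares solution",
                stacklevel=2,
            )
        return Predictor("linear", signature, (coef[:-1], float(coef[-1])))
    if learner == "random_forest":
        est = RandomForestRegressor(n_estimators=params.rf_trees, random_state=seed, n_jobs=1)
        est.fit(x, y)
        return Predictor("random_forest", signature, est)
    if learner == "gradient_boosted_trees":
        est = XGBRegressor(
            n_estimators=params.xgb_rounds,
            max_depth=params.xgb_depth,
            learning_rate=params.xgb_learning_rate,
            objective="reg:squarederror",
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
        est.fit(x, y)
        return Predictor("gradient_boosted_trees", signature, est)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    est = SVR(kernel="rbf", C=params.svm_c, epsilon=params.svm_epsilon, gamma=1.0 / len(signature))
    est.fit((x - mu) / sd, y)
    return Predictor("svm", signature, (mu, sd, est))


def predict(model: "SignatureModel | Predictor", table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """One real-valued range-shift prediction (mm) per row; predictions are
    deliberately not clipped to the trained cavity range."""
    predictor = model.predictor if isinstance(model, SignatureModel) else model
    return predictor.predict(table)


# ---------------------------------------------------------------------------
# signature search


@dataclass
class SignatureModel:
    """A trained configuration: ranking, chosen signature and final model."""

    feature_set: str
    ranking_method: str
    learner: str
    signature: tuple[str, ...]
    cv_rmse: np.ndarray  # indexed by signature size - 1
    chosen_k: int
    predictor: Predictor
    seed: int
    n_train: int

    @property
    def config_name(self) -> str:
        return f"{self.feature_set}:{self.ranking_method}:{self.learner}"

    @property
    def best_cv_rmse(self) -> float:
        return float(self.cv_rmse[self.chosen_k - 1])

    def to_bytes(self) -> bytes:
        """Deterministic bundle serialisation (for provenance/diffing)."""
        return pickle.dumps(
            (
                self.feature_set,
                self.ranking_method,
                self.learner,
                self.signature,
                self.cv_rmse.tobytes(),
                self.chosen_k,
                self.seed,
                self.n_train,
                self.predictor.state_bytes(),
            ),
            protocol=5,
        )


def cv_signature_search(
    table: pd.DataFrame,
    ranking: RankingResult,
    learner: str,
    seed: int = 0,
    params: LearnerParams = LearnerParams(),
    max_size: int = 10,
    feature_set: str = "unknown",
) -> SignatureModel:
    """Choose the signature size by 3×3-fold cross-validated RMSE.

    For each size k = 1..``max_size`` the signature is the ranking's top-k;
    folds are stratified by cavity thickness and shared across sizes; the
    per-size score is the mean RMSE over the nine validation folds.  Ties
    resolve toward the smaller signature.  The final model is refit on all
    training rows with the chosen signature.
    """
    train = table[table["split"] == "train"] if "split" in table.columns else table
    y = train[TARGET_COLUMN].to_numpy(dtype=float)
    strata = pd.factorize(y)[0]
    cv = RepeatedStratifiedKFold(n_splits=3, n_repeats=3, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-class folds etc. are config errors upstream
        folds = [(tr, va) for tr, va in cv.split(np.zeros_like(strata), strata)]
    sizes = range(1, min(max_size, len(ranking.features)) + 1)
    cv_rmse = np.empty(len(sizes))
    for k in sizes:
        signature = ranking.features[:k]
        fold_rmse = []
        for tr, va in folds:
            model = train_learner(train.iloc[tr], signature, learner, seed=seed, params=params)
            pred = model.predict(train.iloc[va])
            fold_rmse.append(float(np.sqrt(np.mean((pred - y[va]) ** 2))))
        cv_rmse[k - 1] = float(np.mean(fold_rmse))
    chosen_k = int(np.argmin(cv_rmse)) + 1  # argmin takes the first (smallest k) on ties
    signature = ranking.features[:chosen_k]
    predictor = train_learner(train, signature, learner, seed=seed, params=params)
    return SignatureModel(
        feature_set=feature_set,
        ranking_method=ranking.method,
        learner=learner,
        signature=signature,
        cv_rmse=cv_rmse,
        chosen_k=chosen_k,
        predictor=predictor,
        seed=seed,
        n_train=len(train),
    )


# ---------------------------------------------------------------------------
# the configuration grid


@dataclass
class GridResult:
    """All trained configurations of one data subset."""

    models: list[SignatureModel]
    best: SignatureModel
    cluster_maps: dict[str, ClusterMap]
    drop_logs: dict[str, dict[str, str]]


def run_grid(
    tables: dict[str, pd.DataFrame],
    seed: int = 0,
    params: LearnerParams = LearnerParams(),
    ranking_methods: tuple[str, ...] = RANKING_METHODS,
    learners: tuple[str, ...] = LEARNERS,
    max_size: int = 10,
) -> GridResult:
    """Train every (feature set × ranking × learner) configuration.

    ``tables`` maps feature-set name to its normalised table.  Filtering
    and clustering run once per feature set (training rows only); rankings
    are shared across learners.  The best configuration is the one with
    the lowest chosen-signature CV RMSE (ties: lexicographic name).
    """
    models: list[SignatureModel] = []
    cluster_maps: dict[str, ClusterMap] = {}
    drop_logs: dict[str, dict[str, str]] = {}
    config_index = 0
    for set_name in tables:
        table = tables[set_name]
        filtered, log = filter_features(table)
        drop_logs[set_name] = log
        cmap = cluster_features(filtered)
        cluster_maps[set_name] = cmap
        meta_cols = [c for c in filtered.columns if c not in feature_columns(filtered)]
        reduced = filtered[meta_cols + cmap.representative_names]
        for method in ranking_methods:
            ranking = rank_features(reduced, method, seed=seed)
            for learner in learners:
                config_seed = (seed * 1000003 + config_index) % (2**31)
                config_index += 1
                models.append(
                    cv_signature_search(
                        reduced,
                        ranking,
                        learner,
                        seed=config_seed,
                        params=params,
                        max_size=max_size,
                        feature_set=set_name,
                    )
                )
    best = min(models, key=lambda m: (m.best_cv_rmse, m.config_name))
    return GridResult(models=models, best=best, cluster_maps=cluster_maps, drop_logs=drop_logs)
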