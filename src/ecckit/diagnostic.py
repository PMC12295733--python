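"""Diagnostic model harness: five classifiers, stratified 2:1 split,
ten-fold cross-validated grid search, held-out metrics, and Shapley-value
feature attribution.

Model families: random forest, logistic regression, Gaussian naive Bayes,
RBF support-vector machine, and k-nearest neighbors. The margin, linear and
neighbor models see train-standardized features (inside the CV pipeline, so
folds stay leak-free); tree and Bayes models see raw values. The family
with the highest mean cross-validated AUC on the training set is selected
and refit on the full training set.

Attribution is a Monte-Carlo estimate of interventional Shapley values:
feature orderings are sampled, the model is evaluated on a background
sample with features revealed one at a time in that order, and the marginal
probability changes are averaged. The telescoping construction makes the
per-sample attributions sum exactly to ``f(x) - E[f(background)]``. A
permutation-importance fallback is available and flagged in the report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "HarnessConfig",
    "MODEL_ORDER",
    "split_cohort",
    "train_compare",
    "evaluate",
    "shapley_values",
    "attribute",
    "run_harness",
]

MODEL_ORDER = ("random_forest", "logistic_regression", "naive_bayes", "svm", "knn")

DEFAULT_GRIDS: dict[str, dict] = {
    "random_forest": {"model__n_estimators": [100], "model__max_depth": [None, 5]},
    "logistic_regression": {"model__C": [0.01, 0.1, 1.0, 10.0]},
    "naive_bayes": {"model__var_smoothing": [1e-9, 1e-7]},
    "svm": {"model__estimator__C": [0.1, 1.0, 10.0]},
    "knn": {"model__n_neighbors": [3, 5, 7, 9]},
}

_NEEDS_SCALING = {"logistic_regression", "svm", "knn"}


@dataclass(frozen=True)
class HarnessConfig:
    split_ratio: float = 2.0 / 3.0
    cv_folds: int = 10
    seed: int = 0
    models: tuple[str, ...] = MODEL_ORDER
    grids: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    attribution_top_k: int = 10
    attribution_method: str = "shapley"      # "shapley", "permutation", or "none"
    shapley_permutations: int = 8
    shapley_background: int = 20

    def __post_init__(self):
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        unknown = set(self.models) - set(MODEL_ORDER)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")


def _make_pipeline(name: str, seed: int) -> Pipeline:
    if name == "random_forest":
        model = RandomForestClassifier(random_state=seed)
    elif name == "logistic_regression":
        model = LogisticRegression(max_iter=5000, random_state=seed)
    elif name == "naive_bayes":
        model = GaussianNB()
    elif name == "svm":
        # probability calibration wrapper: SVC alone gives no predict_proba
        model = CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed), ensemble=False, cv=3
        )
    elif name == "knn":
        model = KNeighborsClassifier()
    else:
        raise ValueError(f"unknown model {name!r}")
    scaler = StandardScaler() if name in _NEEDS_SCALING else "passthrough"
    return Pipeline([("scale", scaler), ("model", model)])


def split_cohort(X: pd.DataFrame, y: np.ndarray, config: HarnessConfig):
    """Stratified 2:1 train/test partition, reproducible from the seed."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples per class to split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=config.split_ratio, stratify=y, random_state=config.seed
    )
    return X_tr, X_te, y_tr, y_te


def train_compare(X_tr: pd.DataFrame, y_tr: np.ndarray, config: HarnessConfig):
    """Grid-search each model family over stratified k-fold CV AUC; select
    the best family (ties to the first-listed) and refit on all of train."""
    y_tr = np.asarray(y_tr)
    _, counts = np.unique(y_tr, return_counts=True)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class ({counts.min()}) cannot populate {config.cv_folds} "
            "stratified folds; use a larger cohort or fewer folds"
        )
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    rows, fitted = [], {}
    for name in config.models:
        search = GridSearchCV(
            _make_pipeline(name, config.seed),
            config.grids.get(name, {}),
            scoring="roc_auc",
            cv=cv,
            n_jobs=1,
            refit=True,
            # a family that cannot fit a degenerate fold (e.g. the SVM's
            # inner calibration split going single-class on rare events)
            # scores NaN and loses the comparison instead of aborting it
            error_score=np.nan,
        )
        search.fit(X_tr, y_tr)
        fitted[name] = search.best_estimator_
        rows.append(
            (
                name,
                float(search.best_score_),
                {k.removeprefix("model__"): v for k, v in search.best_params_.items()},
            )
        )
    cv_table = pd.DataFrame(rows, columns=["model", "cv_auc", "best_params"]).set_index("model")

    def _score(m):
        auc = cv_table.loc[m, "cv_auc"]
        return (auc if np.isfinite(auc) else -np.inf, -config.models.index(m))

    best_name = max(config.models, key=_score)
    return cv_table, best_name, fitted[best_name]


def evaluate(model, X_te: pd.DataFrame, y_te: np.ndarray) -> dict:
    """Held-out metrics at the 0.5 probability threshold (AUC threshold-free).

    With a single-class test set the AUC is reported as NaN with
    ``auc_defined = False``; the other metrics are still returned.
    """
    y_te = np.asarray(y_te)
    proba = model.predict_proba(X_te)[:, 1]
    pred = (proba >= 0.5).astype(int)
    tp = int(((pred == 1) & (y_te == 1)).sum())
    tn = int(((pred == 0) & (y_te == 0)).sum())
    fp = int(((pred == 1) & (y_te == 0)).sum())
    fn = int(((pred == 0) & (y_te == 1)).sum())

    def _safe(num, den):
        return float(num / den) if den else 0.0

    sens = _safe(tp, tp + fn)
    spec = _safe(tn, tn + fp)
    prec = _safe(tp, tp + fp)
    metrics = {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": _safe(2 * prec * sens, prec + sens),
        "accuracy": _safe(tp + tn, len(y_te)),
    }
    if len(np.unique(y_te)) == 2:
        metrics["auc"] = float(roc_auc_score(y_te, proba))
        metrics["auc_defined"] = True
    else:
        metrics["auc"] = float("nan")
        metrics["auc_defined"] = False
    return metrics


# ---------------------------------------------------------------------------
# Attribution


def shapley_values(
    predict_fn,
    X_explain: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 8,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo interventional Shapley values, shape (n_samples, d).

    ``predict_fn`` maps an (m, d) array to m scalar outputs (here: the
    positive-class probability). For each sampled feature ordering, features
    of the explained sample are revealed into the background one at a time;
    the average marginal change attributes the prediction. Per sample, the
    attributions sum exactly to ``f(x) - mean(f(background))``.
    """
    rng = rng or np.random.default_rng(0)
    X_explain = np.asarray(X_explain, dtype=float)
    background = np.asarray(background, dtype=float)
    n, d = X_explain.shape
    B = background.shape[0]
    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        for i in range(n):
            # stack of B-row blocks: background with 0, 1, ..., d features revealed
            blocks = np.tile(background, (d + 1, 1))
            z = background.copy()
            for step, j in enumerate(order, start=1):
                z[:, j] = X_explain[i, j]
                blocks[step * B : (step + 1) * B] = z
            out = predict_fn(blocks).reshape(d + 1, B).mean(axis=1)
            phi[i, order] += np.diff(out)
    return phi / n_permutations


def _permutation_importance(model, X: pd.DataFrame, y: np.ndarray, rng) -> np.ndarray:
    """Signed AUC-drop importances (mean over 5 shuffles per feature)."""
    base = roc_auc_score(y, model.predict_proba(X)[:, 1])
    drops = np.zeros(X.shape[1])
    for j, col in enumerate(X.columns):
        for _ in range(5):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            drops[j] += base - roc_auc_score(y, model.predict_proba(Xp)[:, 1])
    return drops / 5


def attribute(
    model,
    X_explain: pd.DataFrame,
    background: pd.DataFrame,
    y_explain: np.ndarray | None = None,
    top_k: int = 10,
    method: str = "shapley",
    n_permutations: int = 8,
    max_background: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Ranked signed feature contributions for the fitted model.

    Returns the full per-feature table (``mean_abs`` descending) with a
    ``rank`` column; the caller keeps the top-k. ``method='permutation'``
    is the flagged fallback and requires ``y_explain``.
    """
    rng = np.random.default_rng(seed)
    feats = list(X_explain.columns)
    if method == "shapley":
        bg = background.to_numpy(dtype=float)
        if bg.shape[0] > max_background:
            bg = bg[rng.choice(bg.shape[0], max_background, replace=False)]
        phi = shapley_values(
            lambda a: model.predict_proba(pd.DataFrame(a, columns=feats))[:, 1],
            X_explain.to_numpy(dtype=float),
            bg,
            n_permutations=n_permutations,
            rng=rng,
        )
        table = pd.DataFrame(
            {
                "feature": feats,
                "mean_abs": np.abs(phi).mean(axis=0),
                "mean_signed": phi.mean(axis=0),
            }
        )
    elif method == "permutation":
        if y_explain is None:
            raise ValueError("permutation attribution needs labels")
        drops = _permutation_importance(model, X_explain, np.asarray(y_explain), rng)
        table = pd.DataFrame(
            {"feature": feats, "mean_abs": np.abs(drops), "mean_signed": drops}
        )
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    table = table.sort_values("mean_abs", ascending=False, kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs["method"] = method
    return table


# ---------------------------------------------------------------------------
# End-to-end harness


def run_harness(
    X: pd.DataFrame, y: np.ndarray, config: HarnessConfig | None = None
) -> dict:
    """Split, compare, evaluate, attribute; deterministic under the seed."""
    config = config or HarnessConfig()
    y = np.asarray(y)
    X_tr, X_te, y_tr, y_te = split_cohort(X, y, config)
    cv_table, best_name, best_model = train_compare(X_tr, y_tr, config)
    metrics = evaluate(best_model, X_te, y_te)
    attr = None
    if config.attribution_method != "none":
        attr = attribute(
            best_model,
            X_te,
            X_tr,
            y_explain=y_te,
            top_k=config.attribution_top_k,
            method=config.attribution_method,
            n_permutations=config.shapley_permutations,
            max_background=config.shapley_background,
            seed=config.seed,
        )
    return {
        "config": dataclasses.asdict(config),
        "n_train": int(len(X_tr)),
        "n_test": int(len(X_te)),
        "cv_auc": {m: float(cv_table.loc[m, "cv_auc"]) for m in cv_table.index},
        "best_params": {m: cv_table.loc[m, "best_params"] for m in cv_table.index},
        "selected_model": best_name,
        "test_metrics": metrics,
        "attribution_method": config.attribution_method,
        "attribution": None if attr is None else attr.head(config.attribution_top_k),
        "attribution_full": attr,
        "model": best_model,
    }
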