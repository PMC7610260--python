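"""Classical comparison classifiers: OPLS-DA (from scratch) and sklearn adapters.

OPLS-DA — orthogonal projections to latent structures, discriminant variant —
first strips from the predictors the variation orthogonal to the class
response and then fits a single predictive partial-least-squares component on
what remains.  The implementation follows the classic NIPALS-style recipe:

1. center/scale X column-wise; encode the classes as y = +/-1 and center;
2. w  ∝  Xᵀy (unit norm) — the predictive weight direction;
3. for each of ``n_orthogonal`` components on the current (deflated) X:
   t = Xw,  p = Xᵀt/(tᵀt),  w_o = p − (wᵀp)w normalized,
   t_o = Xw_o,  p_o = Xᵀt_o/(t_oᵀt_o),  X ← X − t_o p_oᵀ;
4. fit the predictive component on the deflated X: t = Xw, q = yᵀt/(tᵀt).

Because w ∝ Xᵀy and w_o ⊥ w, every orthogonal score t_o satisfies
t_oᵀy = 0 exactly, which is the defining property of the method.  With
``n_orthogonal = 0`` the fit reduces to single-component PLS1.

The LASSO / random-forest / SVM baselines delegate to scikit-learn with
hyperparameters chosen by internal 5-fold cross-validation; they are
comparison methods, not this package's contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class FitError(ValueError):
    """Raised when a baseline cannot be fitted (single class, bad shapes)."""


@dataclass
class OplsModel:
    """Fitted OPLS-DA state sufficient for out-of-sample projection."""

    predictive_weights: np.ndarray        # w, unit norm, in kept-column space
    predictive_loadings: np.ndarray       # p of the final predictive component
    orthogonal_weights: np.ndarray        # (n_orth, n_features_kept)
    orthogonal_loadings: np.ndarray       # (n_orth, n_features_kept)
    n_orthogonal: int
    y_loading: float                      # q
    y_mean: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    kept_columns: np.ndarray              # boolean mask over original columns
    class_threshold: float = 0.0
    training_scores: np.ndarray | None = None
    orthogonal_scores: np.ndarray | None = None

    def predict_scores(self, X) -> np.ndarray:
        return opls_predict(self, X)


def fit_opls_da(X, y, n_orthogonal: int = 1) -> OplsModel:
    """Fit OPLS-DA; returns a model exposing continuous case scores."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise FitError("X must be 2-D with rows aligned to y")
    classes = np.unique(y)
    if classes.size < 2:
        raise FitError("both classes must be present")
    if X.shape[0] <= n_orthogonal + 1:
        raise FitError("need n_samples > n_orthogonal + 1")

    y_pm = np.where(y == classes.max(), 1.0, -1.0)
    y_mean = y_pm.mean()
    yc = y_pm - y_mean

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    kept = sds > 0
    if not np.all(kept):
        warnings.warn(f"dropping {np.count_nonzero(~kept)} constant feature column(s)")
    if not np.any(kept):
        raise FitError("all feature columns are constant")
    Xs = (X[:, kept] - means[kept]) / sds[kept]

    w = Xs.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise FitError("Xᵀy is zero; no predictive direction")
    w /= nw

    Xd = Xs.copy()
    w_orths, p_orths, t_orths = [], [], []
    for _ in range(n_orthogonal):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        w_orths.append(w_o)
        p_orths.append(p_o)
        t_orths.append(t_o)

    t = Xd @ w
    p_pred = Xd.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    scores = y_mean + q * t

    return OplsModel(
        predictive_weights=w,
        predictive_loadings=p_pred,
        orthogonal_weights=(np.array(w_orths) if w_orths
                            else np.zeros((0, w.size))),
        orthogonal_loadings=(np.array(p_orths) if p_orths
                             else np.zeros((0, w.size))),
        n_orthogonal=len(w_orths),
        y_loading=float(q),
        y_mean=float(y_mean),
        feature_means=means,
        feature_sds=sds,
        kept_columns=kept,
        class_threshold=float(y_mean),
        training_scores=scores,
        orthogonal_scores=(np.array(t_orths) if t_orths
                           else np.zeros((0, X.shape[0]))),
    )


def opls_predict(model: OplsModel, X) -> np.ndarray:
    """Continuous case scores: strip orthogonal components, project, scale by q."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.kept_columns.size:
        raise FitError(f"expected {model.kept_columns.size} features, got {X.shape[1]}")
    kept = model.kept_columns
    Xs = (X[:, kept] - model.feature_means[kept]) / model.feature_sds[kept]
    for w_o, p_o in zip(model.orthogonal_weights, model.orthogonal_loadings):
        t_o = Xs @ w_o
        Xs = Xs - np.outer(t_o, p_o)
    scores = model.y_mean + model.y_loading * (Xs @ model.predictive_weights)
    return scores


def select_n_orthogonal(X, y, candidates=(0, 1, 2), k: int = 5, seed: int = 0) -> int:
    """Pick n_orthogonal by stratified k-fold CV AUC on the training data."""
    from .evaluation import auc, stratified_kfold

    y = np.asarray(y, dtype=int)
    folds = stratified_kfold(y, k=k, seed=seed)
    all_idx = np.arange(y.size)
    best = None
    for n_o in candidates:
        fold_aucs = []
        for test in folds:
            train = np.setdiff1d(all_idx, test)
            m = fit_opls_da(np.asarray(X)[train], y[train], n_orthogonal=n_o)
            fold_aucs.append(auc(opls_predict(m, np.asarray(X)[test]), y[test]))
        mean_auc = np.mean(fold_aucs)
        if best is None or mean_auc > best[0]:
            best = (mean_auc, n_o)
    return best[1]


@dataclass
class BaselineModel:
    """Fitted sklearn baseline exposing per-sample case scores."""

    name: str
    estimator: object
    uses_decision_function: bool = False

    def predict_scores(self, X) -> np.ndarray:
        if self.uses_decision_function:
            return np.asarray(self.estimator.decision_function(X), dtype=float)
        return np.asarray(self.estimator.predict_proba(X)[:, 1], dtype=float)


BASELINE_NAMES = ("lasso", "random_forest", "svm")


def run_baseline(name: str, X, y, hyper: dict | None = None,
                 seed: int = 0) -> tuple[BaselineModel, np.ndarray]:
    """Fit one comparison classifier; hyperparameters by internal 5-fold CV.

    ``hyper`` overrides the CV search with fixed settings (passed to the
    underlying estimator).  Returns the fitted wrapper and its scores on the
    training X.  Deterministic given ``seed``.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if name not in BASELINE_NAMES:
        raise ValueError(f"unknown baseline {name!r}; valid: {', '.join(BASELINE_NAMES)}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise FitError("both classes must be present")
    hyper = dict(hyper or {})
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    uses_df = False

    if name == "lasso":
        if hyper:
            clf = LogisticRegression(penalty="l1", solver="liblinear",
                                     random_state=seed, max_iter=2000, **hyper)
        else:
            clf = LogisticRegressionCV(penalty="l1", solver="liblinear",
                                       Cs=np.logspace(-3, 2, 8), cv=cv,
                                       scoring="roc_auc", random_state=seed,
                                       max_iter=2000)
        est = Pipeline([("scale", StandardScaler()), ("clf", clf)])
        with warnings.catch_warnings():
            # sklearn 1.9 penalty->l1_ratio transition chatter
            warnings.simplefilter("ignore", FutureWarning)
            warnings.filterwarnings("ignore", message=".*penalty.*", category=UserWarning)
            est.fit(X, y)
    elif name == "random_forest":
        base = RandomForestClassifier(random_state=seed, n_estimators=200, **hyper)
        if hyper:
            est = base
        else:
            est = GridSearchCV(base, {"max_features": ["sqrt", 0.1]},
                               cv=cv, scoring="roc_auc")
        est.fit(X, y)
    else:  # svm
        uses_df = True
        if hyper:
            clf = SVC(kernel=hyper.pop("kernel", "rbf"), random_state=seed, **hyper)
            est = Pipeline([("scale", StandardScaler()), ("clf", clf)])
        else:
            pipe = Pipeline([("scale", StandardScaler()),
                             ("clf", SVC(kernel="rbf", random_state=seed))])
            est = GridSearchCV(pipe, {"clf__C": [0.1, 1.0, 10.0]},
                               cv=cv, scoring="roc_auc")
        est.fit(X, y)

    model = BaselineModel(name, est, uses_decision_function=uses_df)
    return model, model.predict_scores(X)
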