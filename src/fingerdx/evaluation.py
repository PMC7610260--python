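"""ROC statistics for paired diagnostic-model comparison.

Implements the full evaluation harness used to compare classifiers on a
discovery/validation design: Mann-Whitney AUC, DeLong variance and confidence
intervals for a single AUC, the paired DeLong test for two correlated ROC
curves, Youden-index threshold selection, sensitivity/specificity at a fixed
threshold, stratified k-fold cross-validation, a label-permutation test for
the whole fitting procedure, and a normal-approximation two-sample power
analysis.

The DeLong machinery follows the placement-value (structural components)
formulation: for case scores ``x_i`` and control scores ``y_j``, the
placement value of a case is the fraction of controls it outscores (ties
half-weighted) and vice versa; the AUC is the mean placement value, and its
variance combines the empirical variances of the two placement vectors.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import stats


class UndefinedAUCError(ValueError):
    """Raised when AUC is requested with only one class present."""


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D vectors")
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise UndefinedAUCError("both classes must be present")
    return scores, labels


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Placement values: V10[i] = P(case_i > control) with ties at 1/2, and V01."""
    diff = cases[:, None] - controls[None, :]
    wins = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return wins.mean(axis=1), wins.mean(axis=0)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: probability a random case outscores a random control."""
    scores, labels = _check_scores_labels(scores, labels)
    v10, _ = _placements(scores[labels == 1], scores[labels == 0])
    return float(v10.mean())


def delong_variance(scores, labels) -> float:
    """DeLong variance of the AUC estimator from placement values."""
    scores, labels = _check_scores_labels(scores, labels)
    cases, controls = scores[labels == 1], scores[labels == 0]
    v10, v01 = _placements(cases, controls)
    m, n = cases.size, controls.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_ci(scores, labels, level: float = 0.95,
              scale: str = "identity") -> tuple[float, float, float]:
    """(auc, low, high) with a DeLong normal-approximation CI.

    ``scale='identity'`` builds the interval directly on the AUC and clips to
    [0, 1]; ``scale='logit'`` builds it on the log-odds of the AUC.  A
    degenerate AUC of exactly 0 or 1 yields a point interval.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = auc(scores, labels)
    var = delong_variance(scores, labels)
    if var <= 0 or a in (0.0, 1.0):
        return a, a, a
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(var)
    if scale == "logit":
        logit = np.log(a / (1 - a))
        se_logit = se / (a * (1 - a))
        lo = 1 / (1 + np.exp(-(logit - z * se_logit)))
        hi = 1 / (1 + np.exp(-(logit + z * se_logit)))
    elif scale == "identity":
        lo, hi = a - z * se, a + z * se
    else:
        raise ValueError("scale must be 'identity' or 'logit'")
    return a, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided paired DeLong test for equality of two correlated AUCs.

    Both score vectors must be computed on the same samples.  Identical score
    vectors give a difference of exactly 0 and p = 1 by convention.
    """
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, _ = _check_scores_labels(scores_b, labels)
    case_mask = labels == 1
    va10, va01 = _placements(scores_a[case_mask], scores_a[~case_mask])
    vb10, vb01 = _placements(scores_b[case_mask], scores_b[~case_mask])
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = va10.size, va01.size
    d = auc_a - auc_b
    if np.array_equal(scores_a, scores_b):
        return 1.0
    # variance of the AUC difference from the 2x2 covariance of placements
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    c = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    var_d = c[0, 0] + c[1, 1] - 2 * c[0, 1]
    if var_d <= 0:
        return 1.0 if d == 0 else 0.0
    z = d / np.sqrt(var_d)
    return float(2 * stats.norm.sf(abs(z)))


def _candidate_cuts(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent sorted unique scores, with +/-inf sentinels."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
    return np.concatenate([[-np.inf], mids, [np.inf]])


def confusion_at(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) calling a sample a case iff score > threshold."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores > threshold
    sens = float(pred[labels == 1].mean())
    spec = float((~pred[labels == 0]).mean())
    return sens, spec


def youden_threshold(scores, labels) -> float:
    """Cut maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent sorted unique scores plus
    +/-infinity sentinels; ties in J are broken toward higher specificity
    (and then toward the higher cut, which is equivalent for monotone
    specificity).
    """
    scores, labels = _check_scores_labels(scores, labels)
    best = None
    for cut in _candidate_cuts(scores):
        sens, spec = confusion_at(scores, labels, cut)
        key = (sens + spec - 1, spec, cut)
        if best is None or key > best[0]:
            best = (key, cut)
    return float(best[1])


def roc_curve_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds, sensitivity, specificity) over all candidate cuts."""
    scores, labels = _check_scores_labels(scores, labels)
    cuts = _candidate_cuts(scores)
    sens = np.empty(cuts.size)
    spec = np.empty(cuts.size)
    for i, cut in enumerate(cuts):
        sens[i], spec[i] = confusion_at(scores, labels, cut)
    return cuts, sens, spec


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """k disjoint, exhaustive test-index folds with near-equal class balance."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels, dtype=int)
    for cls in np.unique(labels):
        if np.count_nonzero(labels == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [np.sort(test) for _, test in skf.split(np.zeros_like(labels), labels)]


def cross_validated_auc(fit_and_score: Callable, X, y, k: int = 10, seed: int = 0,
                        clinical=None) -> tuple[float, list[float]]:
    """Mean fold-wise validation AUC under stratified k-fold CV.

    ``fit_and_score(X_train, y_train, X_test, clinical_train, clinical_test)``
    must return test-set case scores.  Metrics are computed per fold and
    averaged (not pooled).
    """
    y = np.asarray(y, dtype=int)
    folds = stratified_kfold(y, k=k, seed=seed)
    all_idx = np.arange(y.size)
    fold_aucs = []
    for test in folds:
        train = np.setdiff1d(all_idx, test)
        ct = clinical[train] if clinical is not None else None
        cv = clinical[test] if clinical is not None else None
        s = fit_and_score(X[train], y[train], X[test], ct, cv)
        fold_aucs.append(auc(s, y[test]))
    return float(np.mean(fold_aucs)), fold_aucs


def permutation_test(fit_and_score: Callable, X, y, B: int = 999, seed: int = 0,
                     k: int = 10) -> tuple[float, float, np.ndarray]:
    """Label-permutation significance of the whole fitting procedure.

    The statistic is the mean stratified-k-fold CV AUC.  Returns
    ``(p, observed, permuted)`` with the add-one estimator
    ``p = (1 + #{permuted >= observed}) / (B + 1)``, so the smallest
    attainable p at B = 999 is 0.001.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    observed, _ = cross_validated_auc(fit_and_score, X, y, k=k, seed=seed)
    permuted = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(y)
        permuted[b], _ = cross_validated_auc(fit_and_score, X, y_perm, k=k, seed=seed)
    p = (1 + np.count_nonzero(permuted >= observed)) / (B + 1)
    return float(p), float(observed), permuted


def min_sample_size(effect_size_d: float, alpha: float, power: float) -> int:
    """Total n (two equal groups) for a two-sided two-sample normal comparison.

    ``n_per_group = 2 * ((z_{1-alpha/2} + z_{power}) / d)^2`` rounded up;
    returns twice that.  With d = 0.70, alpha = 0.15, power = 0.9 the total is
    62.
    """
    if not 0 < alpha < 1 or not 0 < power < 1 or effect_size_d <= 0:
        raise ValueError("require 0<alpha<1, 0<power<1, d>0")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n_per_group = int(np.ceil(2 * ((z_a + z_b) / effect_size_d) ** 2))
    return 2 * n_per_group
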