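"""Severity estimation models and the bootstrap x leave-one-out protocol.

A linear model estimates the PHQ-9 score from behavioral features by least
squares; a logistic model classifies participants as having depressive
symptoms (PHQ-9 >= 5) with the 0.5 probability rule. When the feature
count is high relative to the sample, an elastic-net penalty
lambda1*||w||_1 + lambda2*||w||_2^2 (intercept unpenalized) controls
overfitting, with the lambdas tuned by cross-validation on training data
only.

Evaluation follows the study protocol: B bootstrap resamples of the
cohort, each cross-validated leave-one-entry-out; classification reports
accuracy/sensitivity/specificity and regression reports NRMSD (RMSD
normalized by the observed score range), as means and SDs across
resamples. Bootstrap duplicates can place copies of a held-out
participant in the training half; the induced optimism is inherent to the
protocol and its rate is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)


def _logspace_grid() -> np.ndarray:
    return np.logspace(-4, 2, 10)


@dataclass
class RegularizationConfig:
    """Elastic-net penalty: fixed lambdas, or grids tuned by inner CV.

    ``l1``/``l2`` set the penalty directly; when None, the corresponding
    grid is searched by ``cv_folds``-fold cross-validation on the training
    data (both grids include 0 implicitly via the unpenalized candidate
    being excluded — a zero penalty must be requested explicitly).
    """

    l1: float | None = None
    l2: float | None = None
    l1_grid: np.ndarray = field(default_factory=_logspace_grid)
    l2_grid: np.ndarray = field(default_factory=_logspace_grid)
    cv_folds: int = 5

    def fixed(self) -> bool:
        return self.l1 is not None and self.l2 is not None


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return X, names


class _LinearBase:
    """Standardized-feature linear predictor shared by both models."""

    def _linear_score(self, X) -> np.ndarray:
        X, _ = _as_matrix(X)
        Z = (X - self.mean_) / self.scale_
        return self.intercept_std + Z @ self.coef_std

    @property
    def coef(self) -> np.ndarray:
        """Coefficients on the original feature scale."""
        return self.coef_std / self.scale_

    @property
    def intercept(self) -> float:
        return float(self.intercept_std - np.sum(self.coef_std * self.mean_
                                                 / self.scale_))


@dataclass
class RegressionModel(_LinearBase):
    """Linear PHQ-9 score estimator (coefficients stored on z-scale)."""

    feature_names: list[str]
    coef_std: np.ndarray
    intercept_std: float
    mean_: np.ndarray
    scale_: np.ndarray
    l1: float = 0.0
    l2: float = 0.0

    def predict(self, X) -> np.ndarray:
        return self._linear_score(X)


@dataclass
class ClassifierModel(_LinearBase):
    """Logistic symptom classifier; positive iff P(symptoms) > threshold."""

    feature_names: list[str]
    coef_std: np.ndarray
    intercept_std: float
    mean_: np.ndarray
    scale_: np.ndarray
    l1: float = 0.0
    l2: float = 0.0
    threshold: float = 0.5

    def predict_proba(self, X) -> np.ndarray:
        from scipy.special import expit
        return expit(self._linear_score(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > self.threshold).astype(int)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _ols_fit(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([np.ones(len(Z)), Z])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient design; enable regularization "
                         "(set l1/l2 in RegularizationConfig)")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[1:], float(beta[0])


def _enet_fit(Z: np.ndarray, y: np.ndarray, l1: float,
              l2: float) -> tuple[np.ndarray, float]:
    """Minimize ||y - b0 - Z w||^2 + l1*||w||_1 + l2*||w||_2^2.

    scikit-learn's ElasticNet objective is
    (1/2n)||r||^2 + a*rho*||w||_1 + (a/2)(1-rho)*||w||_2^2, so
    a*rho = l1/(2n) and a*(1-rho) = l2/n.
    """
    n = len(y)
    alpha = l1 / (2 * n) + l2 / n
    l1_ratio = (l1 / (2 * n)) / alpha
    est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=True,
                     max_iter=200_000, tol=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Z, y)
    return est.coef_.copy(), float(est.intercept_)


def _tune(Z, y, reg: RegularizationConfig, fit_fold, loss) -> tuple[float, float]:
    """Grid-search (l1, l2) by K-fold CV on the training data only."""
    if reg.fixed():
        return float(reg.l1), float(reg.l2)
    l1s = reg.l1_grid if reg.l1 is None else [reg.l1]
    l2s = reg.l2_grid if reg.l2 is None else [reg.l2]
    kf = KFold(n_splits=min(reg.cv_folds, len(y)), shuffle=True,
               random_state=0)
    best, best_pair = np.inf, (float(l1s[0]), float(l2s[0]))
    for l1 in l1s:
        for l2 in l2s:
            losses = []
            for tr, va in kf.split(Z):
                pred = fit_fold(Z[tr], y[tr], float(l1), float(l2), Z[va])
                losses.append(loss(y[va], pred))
            m = float(np.mean(losses))
            if m < best:
                best, best_pair = m, (float(l1), float(l2))
    return best_pair


def fit_score_regression(X, y, reg: RegularizationConfig | None = None,
                         feature_names=None) -> RegressionModel:
    """Least-squares PHQ-9 score model, optionally elastic-net penalized.

    Features are standardized internally; the intercept is never
    penalized. With ``reg=None`` a plain OLS fit is used and a
    rank-deficient design raises with advice to enable regularization.
    """
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 training participants")
    Z, mean, scale = _standardize(X)
    if reg is None:
        coef, b0 = _ols_fit(Z, y)
        l1 = l2 = 0.0
    else:
        def fold(Ztr, ytr, l1, l2, Zva):
            if l1 == 0 and l2 == 0:
                w, b = _ols_fit(Ztr, ytr)
            else:
                w, b = _enet_fit(Ztr, ytr, l1, l2)
            return b + Zva @ w
        l1, l2 = _tune(Z, y, reg, fold,
                       lambda t, p: float(np.mean((t - p) ** 2)))
        coef, b0 = ((_ols_fit(Z, y)) if (l1 == 0 and l2 == 0)
                    else _enet_fit(Z, y, l1, l2))
    return RegressionModel(names, coef, b0, mean, scale, l1, l2)


def _logistic_fit(Z: np.ndarray, y: np.ndarray, l1: float,
                  l2: float) -> tuple[np.ndarray, float]:
    """Penalized maximum-likelihood logistic fit on standardized features.

    scikit-learn's objective is rho*||w||_1 + (1-rho)/2*||w||_2^2
    + C*logloss, so matching logloss + l1*||w||_1 + l2*||w||_2^2 needs
    C = 1/(l1 + 2*l2), rho = l1*C.
    """
    if l1 == 0 and l2 == 0:
        est = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-12,
                                 max_iter=20_000)
    else:
        C = 1.0 / (l1 + 2.0 * l2)
        est = LogisticRegression(solver="saga", C=C, l1_ratio=l1 * C,
                                 tol=1e-10, max_iter=200_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Z, y)
    return est.coef_.ravel().copy(), float(est.intercept_[0])


def fit_symptom_classifier(X, y, reg: RegularizationConfig | None = None,
                           feature_names=None) -> ClassifierModel:
    """Logistic classifier for depressive symptoms (positive: PHQ-9 >= 5)."""
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    Z, mean, scale = _standardize(X)
    if reg is None:
        l1 = l2 = 0.0
    else:
        def fold(Ztr, ytr, l1, l2, Zva):
            if len(np.unique(ytr)) < 2:
                return np.full(len(Zva), float(ytr[0]))
            w, b = _logistic_fit(Ztr, ytr, l1, l2)
            return 1.0 / (1.0 + np.exp(-(b + Zva @ w)))

        def logloss(t, p):
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))

        l1, l2 = _tune(Z, y, reg, fold, logloss)
    coef, b0 = _logistic_fit(Z, y, l1, l2)
    return ClassifierModel(names, coef, b0, mean, scale, l1, l2)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def nrmsd(pred, truth, value_range: float) -> float:
    """Root-mean-square deviation normalized by the observed score range."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    if len(pred) == 0:
        return float("nan")
    if value_range <= 0:
        raise ValueError("value_range must be positive")
    return float(np.sqrt(np.mean((pred - truth) ** 2)) / value_range)


def classification_metrics(pred_labels,
                           true_labels) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where a class is absent.

    Positive class = has depressive symptoms.
    """
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    if len(pred) == 0:
        raise ValueError("empty input")
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    acc = (tp + tn) / len(pred)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return acc, sens, spec


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Bootstrap x LOPO performance summary for one feature set."""

    feature_set: list[str]
    B: int
    n_participants: int
    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    nrmsd_mean: float
    nrmsd_sd: float
    score_range: float
    redraws: int
    duplicate_leak_rate: float

    def to_row(self) -> dict:
        return {
            "feature_set": "+".join(self.feature_set), "B": self.B,
            "n": self.n_participants,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity_mean": self.sensitivity_mean,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity_mean": self.specificity_mean,
            "specificity_sd": self.specificity_sd,
            "nrmsd_mean": self.nrmsd_mean, "nrmsd_sd": self.nrmsd_sd,
            "duplicate_leak_rate": self.duplicate_leak_rate,
        }


def _loo_ols_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact leave-one-out OLS predictions via the hat-matrix identity.

    For OLS the LOO residual is e_i / (1 - h_ii); per-fold feature
    standardization is an affine reparameterization and cannot change OLS
    predictions, so this matches a physical refit per fold.
    """
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    G = np.linalg.pinv(A.T @ A)
    h = np.einsum("ij,jk,ik->i", A, G, A)
    out = np.empty(len(y))
    for i in range(len(y)):
        if 1.0 - h[i] < 1e-10:  # leverage-one point: refit without it
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            b, *_ = np.linalg.lstsq(A[mask], y[mask], rcond=None)
            out[i] = A[i] @ b
        else:
            out[i] = y[i] - (y[i] - fitted[i]) / (1.0 - h[i])
    return out


def _loo_predictions(X: np.ndarray, y_score: np.ndarray, y_label: np.ndarray,
                     reg: RegularizationConfig | None,
                     folds: list[np.ndarray] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Held-out score predictions and class labels, one fold per entry.

    ``folds`` optionally groups duplicate entries (unit-level resampling):
    each fold holds out all listed rows at once.
    """
    n = len(y_score)
    if folds is None:
        folds = [np.array([i]) for i in range(n)]
    pred_score = np.empty(n)
    pred_label = np.empty(n, dtype=int)
    if reg is None and all(len(f) == 1 for f in folds):
        pred_score = _loo_ols_predictions(X, y_score)
    else:
        for held in folds:
            mask = np.ones(n, dtype=bool)
            mask[held] = False
            model = fit_score_regression(X[mask], y_score[mask], reg=reg)
            pred_score[held] = model.predict(X[held])
    for held in folds:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        ytr = y_label[mask]
        if len(np.unique(ytr)) < 2:
            pred_label[held] = int(ytr[0])  # degenerate single-class fold
            continue
        clf = fit_symptom_classifier(X[mask], ytr, reg=reg)
        pred_label[held] = clf.predict(X[held])
    return pred_score, pred_label


def bootstrap_lopo_evaluate(features: pd.DataFrame, scores: pd.Series,
                            feature_set: list[str] | None = None,
                            B: int = 1000,
                            reg: RegularizationConfig | None = None,
                            seed: int = 0, cutoff: int = 5,
                            score_range: float | None = None,
                            unit_level: bool = False,
                            auto_regularize: bool = True) -> EvaluationReport:
    """Evaluate score and symptom models by B bootstraps of LOPO CV.

    Each of B resamples draws participants with replacement (B=1 uses the
    identity resample, i.e. plain leave-one-participant-out); within a
    resample every entry is held out once, models are fit on the rest, and
    the pooled held-out predictions give that resample's NRMSD and
    accuracy/sensitivity/specificity. Means and SDs are taken across
    resamples. Resamples containing a single class are redrawn (counted).

    With ``auto_regularize``, an elastic-net penalty (CV-tuned) is applied
    when the feature set has more than two features and ``reg`` is not
    given, matching the study's usage. ``unit_level=True`` holds out all
    copies of a duplicated participant together instead of entry-by-entry.
    """
    feature_set = list(feature_set or features.columns)
    scores = scores.loc[features.index]
    X_all = features[feature_set].to_numpy(dtype=float)
    ok = np.all(np.isfinite(X_all), axis=1) & np.isfinite(
        scores.to_numpy(dtype=float))
    X_all = X_all[ok]
    y_score = scores.to_numpy(dtype=float)[ok]
    ids = features.index.to_numpy()[ok]
    y_label = (y_score >= cutoff).astype(int)
    n = len(y_score)
    if n < 4:
        raise ValueError("need at least 4 participants with complete data")
    if len(np.unique(y_label)) < 2:
        raise ValueError("cohort contains a single symptom class")
    if score_range is None:
        score_range = float(y_score.max() - y_score.min())
    if reg is None and auto_regularize and len(feature_set) > 2:
        reg = RegularizationConfig()

    rng = np.random.default_rng(seed)
    accs, senss, specs, nrmsds = [], [], [], []
    redraws = 0
    leaky = total_folds = 0
    for b in range(B):
        if B == 1:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, n)
            while len(np.unique(y_label[idx])) < 2:
                redraws += 1
                idx = rng.integers(0, n, n)
        Xb, yb, lb, idb = X_all[idx], y_score[idx], y_label[idx], ids[idx]
        if unit_level:
            folds = [np.flatnonzero(idb == u) for u in pd.unique(idb)]
        else:
            folds = [np.array([i]) for i in range(n)]
        for held in folds:
            total_folds += 1
            rest = np.delete(idb, held)
            if np.isin(idb[held], rest).any():
                leaky += 1
        ps, pl = _loo_predictions(Xb, yb, lb, reg, folds=folds)
        acc, sens, spec = classification_metrics(pl, lb)
        accs.append(acc)
        senss.append(sens)
        specs.append(spec)
        nrmsds.append(nrmsd(ps, yb, score_range))
    if redraws:
        log.info("redrew %d single-class bootstrap resamples", redraws)

    def _ms(vals):
        a = np.asarray(vals, dtype=float)
        a = a[np.isfinite(a)]
        if len(a) == 0:
            return float("nan"), float("nan")
        return float(a.mean()), float(a.std(ddof=0))

    am, asd = _ms(accs)
    sm, ssd = _ms(senss)
    pm, psd = _ms(specs)
    nm, nsd = _ms(nrmsds)
    return EvaluationReport(
        feature_set=feature_set, B=B, n_participants=n,
        accuracy_mean=am, accuracy_sd=asd,
        sensitivity_mean=sm, sensitivity_sd=ssd,
        specificity_mean=pm, specificity_sd=psd,
        nrmsd_mean=nm, nrmsd_sd=nsd, score_range=score_range,
        redraws=redraws,
        duplicate_leak_rate=leaky / total_folds if total_folds else 0.0)


def evaluate_feature_sets(features: pd.DataFrame, scores: pd.Series,
                          feature_sets: list[list[str]], **kwargs
                          ) -> pd.DataFrame:
    """One evaluation row per feature set (the shape of the study's tables)."""
    rows = [bootstrap_lopo_evaluate(features, scores, fs, **kwargs).to_row()
            for fs in feature_sets]
    return pd.DataFrame(rows).set_index("feature_set")
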