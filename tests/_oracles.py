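"""Independent brute-force/formula oracles used by the tests.

Each oracle is written from the textbook definition, deliberately on a
different computational route than the package (law-of-cosines instead of
the haversine formula, normal equations instead of coordinate descent,
IRLS instead of lbfgs, explicit sums instead of library calls).
"""

from __future__ import annotations

import math

import numpy as np

EARTH_RADIUS_KM = 6371.0


def great_circle_law_of_cosines_km(lat1, lon1, lat2, lon2) -> float:
    """Spherical law of cosines distance, R = 6371 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = (math.sin(p1) * math.sin(p2)
         + math.cos(p1) * math.cos(p2) * math.cos(dl))
    return EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, c)))


def pearson_textbook(x, y) -> tuple[float, float]:
    """Pearson r by explicit sums; two-sided p via the t transform."""
    from scipy.stats import t as tdist
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x * x).sum() - sx ** 2) \
        * math.sqrt(n * (y * y).sum() - sy ** 2)
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * tdist.sf(abs(t), n - 2)
    return r, p


def welch_textbook(a, b) -> tuple[float, float]:
    """Welch t statistic and two-sided p with Welch-Satterthwaite df."""
    from scipy.stats import t as tdist
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def ridge_normal_equations(Z, y, lam) -> tuple[np.ndarray, float]:
    """argmin ||y - b0 - Z w||^2 + lam * ||w||^2 with Z column-centered.

    For centered Z the intercept is the mean of y and the slopes solve
    (Z'Z + lam I) w = Z'(y - mean(y)).
    """
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    b0 = y.mean()
    A = Z.T @ Z + lam * np.eye(Z.shape[1])
    w = np.linalg.solve(A, Z.T @ (y - b0))
    return w, b0


def irls_logistic(Z, y, n_iter: int = 200) -> tuple[np.ndarray, float]:
    """Unpenalized logistic MLE by iteratively reweighted least squares."""
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    A = np.column_stack([np.ones(len(y)), Z])
    beta = np.zeros(A.shape[1])
    for _ in range(n_iter):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        W = np.diag(w)
        step = np.linalg.solve(A.T @ W @ A, A.T @ (y - mu))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta[1:], float(beta[0])


def nrmsd_direct(pred, truth, rng) -> float:
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    return math.sqrt(sum((p - t) ** 2 for p, t in zip(pred, truth))
                     / len(pred)) / rng


def confusion_rates(pred, true) -> tuple[float, float, float]:
    tp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 1)
    tn = sum(1 for p, t in zip(pred, true) if p == 0 and t == 0)
    fp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 0)
    fn = sum(1 for p, t in zip(pred, true) if p == 0 and t == 1)
    n = len(pred)
    return ((tp + tn) / n,
            tp / (tp + fn) if tp + fn else float("nan"),
            tn / (tn + fp) if tn + fp else float("nan"))
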