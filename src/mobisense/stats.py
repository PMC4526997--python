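"""Descriptive association analysis between features and PHQ-9 scores.

Three analyses mirror the study design: per-feature Pearson correlation
with the PHQ-9 score; a two-group comparison after splitting the cohort at
the PHQ-9 >= 5 cutoff (at least mild symptoms) using Welch two-sample
t-tests; and the feature-feature correlation matrix. No multiple-comparison
correction is applied — these are exploratory statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

PHQ9_CUTOFF = 5


@dataclass
class CorrelationResult:
    feature: str
    r: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


@dataclass
class GroupComparison:
    """Welch t-test of a feature between the below- and at/above-cutoff groups."""

    feature: str
    t: float
    p: float
    mean_lo: float
    sd_lo: float
    mean_hi: float
    sd_hi: float
    n_lo: int
    n_hi: int


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def pearson_with_p(x, y, feature: str = "") -> CorrelationResult:
    """Pearson r with two-sided p (t transform, n-2 df); pairwise-complete.

    Undefined (NaN result) with fewer than 3 complete pairs or a
    zero-variance input.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3 or np.var(x) == 0 or np.var(y) == 0:
        return CorrelationResult(feature, float("nan"), float("nan"), n)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(feature, float(r), float(p), n)


def split_by_cutoff(scores, cutoff: int = PHQ9_CUTOFF):
    """(scores < cutoff, scores >= cutoff) preserving input container type."""
    scores = pd.Series(scores)
    return scores[scores < cutoff], scores[scores >= cutoff]


def group_ttest(lo, hi, feature: str = "",
                equal_var: bool = False) -> GroupComparison:
    """Two-sided two-sample t-test (Welch by default) between groups.

    Groups with fewer than 2 non-NA values give a NaN statistic.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    lo, hi = lo[np.isfinite(lo)], hi[np.isfinite(hi)]

    def _m(a):
        return (float(np.mean(a)) if len(a) else float("nan"),
                float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"))

    m_lo, s_lo = _m(lo)
    m_hi, s_hi = _m(hi)
    if len(lo) < 2 or len(hi) < 2:
        t = p = float("nan")
    else:
        t, p = sps.ttest_ind(lo, hi, equal_var=equal_var)
    return GroupComparison(feature, float(t), float(p), m_lo, s_lo,
                           m_hi, s_hi, len(lo), len(hi))


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations among feature columns."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def feature_correlation_matrix(features: pd.DataFrame) -> CorrelationMatrix:
    """Symmetric feature-feature correlation matrix with unit diagonal."""
    cols = list(features.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = int(np.isfinite(features[cols[i]].to_numpy(float)).sum())
        for j in range(i + 1, k):
            res = pearson_with_p(features[cols[i]], features[cols[j]])
            r[i, j] = r[j, i] = res.r
            p[i, j] = p[j, i] = res.p
            n[i, j] = n[j, i] = res.n
    idx = pd.Index(cols)
    return CorrelationMatrix(pd.DataFrame(r, idx, idx),
                             pd.DataFrame(p, idx, idx),
                             pd.DataFrame(n, idx, idx))


def associate(features: pd.DataFrame, scores: pd.Series,
              cutoff: int = PHQ9_CUTOFF) -> pd.DataFrame:
    """Per-feature correlation with PHQ-9 plus the cutoff-group comparison.

    Returns a tidy frame with one row per feature: Pearson r/p/n against
    the score, and the Welch t, p and group summaries for the
    below-cutoff vs at-or-above-cutoff split.
    """
    scores = scores.loc[features.index]
    lo_ids = scores.index[scores < cutoff]
    hi_ids = scores.index[scores >= cutoff]
    rows = []
    for name in features.columns:
        col = features[name]
        corr = pearson_with_p(col, scores, feature=name)
        comp = group_ttest(col.loc[lo_ids], col.loc[hi_ids], feature=name)
        rows.append({
            "feature": name, "r": corr.r, "r_p": corr.p, "n": corr.n,
            "t": comp.t, "t_p": comp.p,
            "mean_lo": comp.mean_lo, "sd_lo": comp.sd_lo,
            "mean_hi": comp.mean_hi, "sd_hi": comp.sd_hi,
            "n_lo": comp.n_lo, "n_hi": comp.n_hi,
        })
    return pd.DataFrame(rows).set_index("feature")
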