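"""Cohort-level statistics: responder sub-group detection and metric evaluation.

Right-tail responder sub-groups are found from the per-drug score
distribution by the one-sided D'Agostino skewness test; metric quality is
evaluated against curve activity labels with AUROC and compared between
metrics with DeLong's paired test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SkewnessResult",
    "RocResult",
    "sample_skewness",
    "agostino_skewness_test",
    "detect_responder_subgroup",
    "rank_sum_test",
    "auroc",
    "delong_test",
    "subgroup_table",
]


@dataclass(frozen=True)
class SkewnessResult:
    """Sample skewness gamma, D'Agostino z and its one-sided (right-tail) p."""

    gamma: float
    z: float
    p_one_sided: float


@dataclass(frozen=True)
class RocResult:
    auroc: float
    n_pos: int
    n_neg: int
    orientation: str = "higher_is_active"


def sample_skewness(values) -> float:
    """Moment skewness g1 = m3 / m2^(3/2) (uncorrected estimator)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need >= 3 finite values")
    if np.ptp(v) == 0:
        raise ValueError("zero variance: skewness undefined")
    return float(sps.skew(v, bias=True))


def agostino_skewness_test(values, alternative: str = "positive") -> SkewnessResult:
    """D'Agostino (1970) skewness test via the normalizing transformation of g1.

    ``alternative='positive'`` gives the right-tail p-value used for
    responder detection; ``'two-sided'`` is also available.  Requires n >= 8
    for the transformation to be defined.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 8:
        raise ValueError("sample too small for D'Agostino transformation (need n >= 8)")
    if np.ptp(v) == 0:
        raise ValueError("zero variance: skewness undefined")
    gamma = sample_skewness(v)
    if gamma == 0.0:  # exactly symmetric sample: the transform maps 0 to 0
        z, p_two = 0.0, 1.0
    else:
        z, p_two = sps.skewtest(v)
    if alternative == "positive":
        p = float(sps.norm.sf(z))
    elif alternative == "two-sided":
        p = float(p_two)
    else:
        raise ValueError("alternative must be 'positive' or 'two-sided'")
    return SkewnessResult(gamma=gamma, z=float(z), p_one_sided=p)


def detect_responder_subgroup(values: pd.Series | np.ndarray,
                              alpha: float = 0.05) -> tuple[list, SkewnessResult]:
    """Minimal right-tail sub-group that explains significant positive skew.

    If the one-sided D'Agostino p is below ``alpha``, the maximum value is
    peeled off and the remainder re-tested, repeating until the skew is no
    longer significant (or too few values remain to test); the peeled samples
    are the responders.  The returned ids are always the top-k scores for
    some k, and the set is empty whenever the initial test is not significant.
    """
    if isinstance(values, pd.Series):
        series = values.dropna().astype(float)
    else:
        arr = np.asarray(values, dtype=float)
        series = pd.Series(arr[np.isfinite(arr)],
                           index=range(int(np.sum(np.isfinite(arr)))))
    initial = agostino_skewness_test(series.to_numpy())
    if initial.p_one_sided >= alpha:
        return [], initial
    order = series.sort_values(ascending=False, kind="mergesort")
    k = 0
    while True:
        k += 1
        remaining = order.iloc[k:]
        if len(remaining) < 8:
            break  # too few left to re-test; stop with the current tail
        res = agostino_skewness_test(remaining.to_numpy())
        if res.p_one_sided >= alpha:
            break
    return list(order.index[:k]), initial


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test (two-sided).

    Exact null when both groups have n <= 20 and there are no ties; normal
    approximation with midranks, tie correction and continuity correction
    otherwise.  Returns (U statistic of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def auroc(scores, labels, orientation: str = "higher_is_active") -> RocResult:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    AUROC = P(score_active > score_inactive) + P(tie)/2.  With
    ``orientation='lower_is_active'`` (e.g. IC50) scores are negated first.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    if orientation == "lower_is_active":
        s = -s
    elif orientation != "higher_is_active":
        raise ValueError("orientation must be 'higher_is_active' or 'lower_is_active'")
    ranks = sps.rankdata(s)
    value = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return RocResult(auroc=float(value), n_pos=n_pos, n_neg=n_neg, orientation=orientation)


def _placements(pos, neg):
    """DeLong structural components: per-observation placement values."""
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / pos.size for q in neg])
    return v10, v01


def delong_test(scores_1, scores_2, labels) -> tuple[float, float, float]:
    """DeLong's paired test for the difference of two correlated AUROCs.

    Both score vectors must be computed on the same labelled curves.  Returns
    (auroc_1, auroc_2, two-sided p).  A degenerate variance (e.g. identical
    score vectors) yields p = 1 with zero difference rather than a division
    by zero.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (s1.shape == s2.shape == y.shape):
        raise ValueError("scores_1, scores_2 and labels must align")
    if y.all() or not y.any():
        raise ValueError("both label classes must be present")
    m, n = int(y.sum()), int((~y).sum())
    aucs, v10s, v01s = [], [], []
    for s in (s1, s2):
        v10, v01 = _placements(s[y], s[~y])
        v10s.append(v10)
        v01s.append(v01)
        aucs.append(float(v10.mean()))
    v10s, v01s = np.array(v10s), np.array(v01s)
    s10 = np.cov(v10s)  # 2x2 covariance of placement values across metrics
    s01 = np.cov(v01s)
    cov = s10 / m + s01 / n
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ cov @ contrast)
    diff = aucs[0] - aucs[1]
    if var <= 0 or not np.isfinite(var):
        return aucs[0], aucs[1], 1.0
    z = diff / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return aucs[0], aucs[1], p


def subgroup_table(score_matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-drug responder screen over a samples x drugs score matrix.

    Emits skewness gamma, D'Agostino z and one-sided p, Benjamini-Hochberg
    FDR across drugs (raw p remains primary), the detected responder sample
    ids and the rank-sum p of responders vs the rest.  Drugs whose score
    distribution is degenerate (too few values, zero variance) are skipped.
    """
    rows = []
    for drug in score_matrix.columns:
        col = score_matrix[drug].dropna()
        try:
            responders, res = detect_responder_subgroup(col, alpha=alpha)
        except ValueError:
            continue
        if responders:
            rest = col.drop(index=responders)
            _, p_rs = rank_sum_test(col.loc[responders], rest)
        else:
            p_rs = float("nan")
        rows.append({
            "drug_id": drug, "gamma": res.gamma, "z": res.z,
            "p_skew": res.p_one_sided, "n_responders": len(responders),
            "responders": ";".join(str(r) for r in responders),
            "p_ranksum": p_rs,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_skew"] = multipletests(df["p_skew"], method="fdr_bh")[1]
    return df
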