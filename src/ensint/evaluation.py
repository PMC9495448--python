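"""Class-imbalance-aware performance measures and statistical comparisons.

Fmax — the maximum F-measure over all score thresholds, with the precision,
recall and threshold at the maximum — is the headline measure used
throughout; it is robust under class imbalance and standard in protein
function prediction (CAFA). AUPRC and AUROC are delegated to scikit-learn
(average-precision step interpolation and trapezoidal/Mann-Whitney,
respectively). Method comparisons across many tasks use the Friedman test
with Nemenyi post-hoc pairwise p-values, BH-adjusted. Feature-list overlaps
are assessed with Fisher's exact test, reporting the conditional
maximum-likelihood odds ratio alongside the sample odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Fmax
# ---------------------------------------------------------------------------

def fmax(labels: Sequence[int] | np.ndarray,
         scores: Sequence[float] | np.ndarray,
         ) -> tuple[float, float, float, float]:
    """Maximum F-measure over all score thresholds.

    Predicts positive when ``score >= t`` and sweeps t over the unique score
    values. F = 2PR/(P+R), with F = 0 when both P and R are undefined/zero.
    Returns ``(fmax, precision, recall, threshold)`` at the maximizing
    threshold; ties in F are broken toward the higher threshold.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D and the same length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("Fmax needs both classes present")

    # Sort by descending score; at threshold = s_(i) everything with score
    # >= s_(i) is predicted positive, so cumulative sums give P and R.
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    tp = np.cumsum(y[order])
    npred = np.arange(1, len(y) + 1)
    # Only thresholds at the last occurrence of each unique score are valid.
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    precision = tp[last] / npred[last]
    recall = tp[last] / n_pos
    thresholds = s_sorted[last]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(precision + recall > 0,
                     2 * precision * recall / (precision + recall), 0.0)
    # Thresholds are descending; argmax takes the first (highest) on ties.
    best = int(np.argmax(f))
    return (float(f[best]), float(precision[best]), float(recall[best]),
            float(thresholds[best]))


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve by step-wise interpolation
    (sum of precision x recall increments)."""
    y = np.asarray(labels, dtype=int)
    if y.sum() in (0, len(y)):
        raise ValueError("AUPRC needs both classes present")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (trapezoidal; equals the normalized
    Mann-Whitney U statistic, with half credit for ties)."""
    y = np.asarray(labels, dtype=int)
    if y.sum() in (0, len(y)):
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class EvaluationReport:
    """Bundle of threshold-free performance measures for one score vector."""

    fmax: float
    precision_at_fmax: float
    recall_at_fmax: float
    threshold_at_fmax: float
    auprc: float
    auroc: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def evaluate_scores(labels: Sequence[int], scores: Sequence[float],
                    ) -> EvaluationReport:
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    f, p, r, t = fmax(y, s)
    return EvaluationReport(
        fmax=f, precision_at_fmax=p, recall_at_fmax=r, threshold_at_fmax=t,
        auprc=auprc(y, s), auroc=auroc(y, s),
        n_pos=int(y.sum()), n_neg=int(len(y) - y.sum()),
    )


# ---------------------------------------------------------------------------
# Friedman / Nemenyi comparison across tasks
# ---------------------------------------------------------------------------

def friedman_nemenyi(performance: pd.DataFrame, fdr: str = "bh",
                     ) -> tuple[float, float, pd.DataFrame]:
    """Compare methods across tasks with Friedman + Nemenyi post-hoc tests.

    Parameters
    ----------
    performance : DataFrame, methods x tasks
        One performance value per (method, task); no missing cells.
    fdr : {"bh", "none"}
        Multiple-testing adjustment applied across the method pairs.

    Returns
    -------
    (friedman_statistic, friedman_p, pairwise) where ``pairwise`` is a
    symmetric DataFrame of (adjusted) Nemenyi p-values with NaN diagonal.

    Within each task, methods are ranked (1 = best, mean ranks on ties);
    the Friedman chi-square uses the tie-corrected statistic, and the
    Nemenyi pairwise p-value compares the mean-rank difference against the
    studentized range distribution.
    """
    perf = performance.astype(float)
    if perf.isna().any().any():
        raise ValueError("performance matrix has missing cells")
    k, n = perf.shape
    if k < 2 or n < 2:
        raise ValueError("need >=2 methods and >=2 tasks")

    # Rank within each task: higher performance -> rank 1.
    ranks = perf.rank(axis=0, ascending=False, method="average")
    mean_ranks = ranks.mean(axis=1)

    # Tie-corrected Friedman chi-square (Demsar / Conover form).
    ss_ranks = float(((ranks.sum(axis=1) - n * (k + 1) / 2) ** 2).sum())
    tie_term = float((ranks**2).to_numpy().sum()) - n * k * (k + 1) ** 2 / 4
    if tie_term <= 0:  # all methods tied on every task
        statistic, p_value = 0.0, 1.0
    else:
        statistic = (k - 1) * ss_ranks / tie_term
        p_value = float(stats.chi2.sf(statistic, k - 1))

    se = np.sqrt(k * (k + 1) / (6.0 * n))
    methods = list(perf.index)
    pair_p = {}
    for a, b in combinations(methods, 2):
        q = abs(mean_ranks[a] - mean_ranks[b]) / se
        pair_p[(a, b)] = float(stats.studentized_range.sf(q * np.sqrt(2), k, np.inf))
    pairs = list(pair_p)
    pvals = np.array([pair_p[p] for p in pairs])
    if fdr == "bh" and len(pvals):
        pvals = multipletests(pvals, method="fdr_bh")[1]
    elif fdr not in ("bh", "none"):
        raise ValueError(f"unknown fdr method {fdr!r}")
    out = pd.DataFrame(np.nan, index=methods, columns=methods)
    for (a, b), p in zip(pairs, pvals):
        out.loc[a, b] = out.loc[b, a] = min(float(p), 1.0)
    return float(statistic), p_value, out


# ---------------------------------------------------------------------------
# Fisher overlap test
# ---------------------------------------------------------------------------

def overlap_fisher(list_a: Sequence[str], list_b: Sequence[str],
                   universe_size: int) -> dict[str, float]:
    """Fisher's exact test for the overlap between two feature lists.

    Builds the 2x2 table (in both / a only / b only / neither) over a
    universe of ``universe_size`` features and returns the two-sided exact
    p-value plus two odds-ratio estimates: the conditional MLE of the
    noncentral hypergeometric likelihood (``odds_ratio``) and the sample
    (cross-product) ratio (``sample_odds_ratio``).
    """
    a, b = set(map(str, list_a)), set(map(str, list_b))
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = universe_size - len(a | b)
    if n22 < 0:
        raise ValueError("universe smaller than the union of the lists")
    table = np.array([[n11, n12], [n21, n22]])
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    cmle = stats.contingency.odds_ratio(table, kind="conditional").statistic
    sample = stats.contingency.odds_ratio(table, kind="sample").statistic
    return {
        "p_value": p,
        "odds_ratio": float(cmle),
        "sample_odds_ratio": float(sample),
        "n_overlap": float(n11),
    }
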