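"""Per-subject metrics, the ΔAccu cohort contrast, and its statistics.

All accuracies and F-scores are carried as percentages (0–100).  The cohort
analysis mirrors the standard BCI-inefficiency protocol: subjects are ranked
by an online(-proxy) accuracy, median-split into low/high performers, and the
per-subject CNN-minus-CSP+LDA test-accuracy difference (ΔAccu) is compared
between groups with an independent t-test after Shapiro–Wilk normality
checks; a paired t-test compares the two decoders across the pooled cohort.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .records import CohortComparison, EvalResult, SubjectRecord

#: Improvement histogram bins (percent-point ranges, inclusive of endpoints
#: after rounding to the nearest integer percent).
IMPROVEMENT_BINS: Tuple[Tuple[int, int], ...] = (
    (1, 5), (6, 10), (11, 15), (16, 20), (21, 25), (26, 30))
BIN_LABELS: Tuple[str, ...] = tuple(f"{lo}-{hi}%" for lo, hi in IMPROVEMENT_BINS)
OVERFLOW_LABEL = "outside"


def train_test_split(n_trials: int, labels: Sequence[int], fraction: float = 0.8,
                     seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified, disjoint, exhaustive 80/20 split; deterministic per seed."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    labels = np.asarray(labels)
    if len(labels) != n_trials:
        raise ValueError("labels length must equal n_trials")
    rng = np.random.default_rng(seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = int(round(fraction * len(idx)))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def accuracy(predictions: Sequence[int], labels: Sequence[int]) -> float:
    """Percent of correct predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) == 0:
        raise ValueError("empty input")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    return float(np.mean(predictions == labels) * 100.0)


def f_score_per_class(predictions: Sequence[int], labels: Sequence[int]) -> Tuple[float, float]:
    """Per-class F1 (%, harmonic mean of precision and recall); 0 when P+R = 0."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) == 0:
        raise ValueError("empty input")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    out = []
    for cls in (0, 1):
        tp = np.sum((predictions == cls) & (labels == cls))
        fp = np.sum((predictions == cls) & (labels != cls))
        fn = np.sum((predictions != cls) & (labels == cls))
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        out.append(100.0 * f)
    return out[0], out[1]


def delta_accuracy(eval_dl: EvalResult, eval_ml: EvalResult) -> float:
    """ΔAccu = CNN test accuracy − CSP+LDA test accuracy, percent points.

    Both results must come from the same subject split (same split seed) for
    the difference to be meaningful.
    """
    if eval_dl.split_seed != eval_ml.split_seed:
        raise ValueError("eval results come from different splits")
    return eval_dl.test_accuracy - eval_ml.test_accuracy


def median_split(records: List[SubjectRecord]) -> List[SubjectRecord]:
    """Assign low/high performer groups by online accuracy.

    Stable sort by (online_accuracy, subject_id); the lower half becomes the
    "low" group.  With even n the groups are exactly equal-sized regardless
    of ties at the median.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records for a median split")
    if any(r.online_accuracy is None for r in records):
        raise ValueError("all records need an online_accuracy")
    order = sorted(records, key=lambda r: (r.online_accuracy, r.subject_id))
    n_low = len(order) // 2
    for i, rec in enumerate(order):
        rec.group = "low" if i < n_low else "high"
    return records


def shapiro_wilk(sample: Sequence[float]) -> Tuple[float, float]:
    """Shapiro–Wilk normality test (W, p) for 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _t_ci(mean_diff: float, se: float, df: int) -> Tuple[float, float]:
    tcrit = stats.t.ppf(0.975, df)
    return mean_diff - tcrit * se, mean_diff + tcrit * se


def paired_ttest(a: Sequence[float], b: Sequence[float]
                 ) -> Tuple[float, int, float, Tuple[float, float]]:
    """Two-sided paired t-test: (t, df, p, 95% CI of the mean difference)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired test needs equal-length samples, n >= 2")
    d = a - b
    n = len(d)
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        warnings.warn("zero variance of paired differences; t is infinite")
        t = math.copysign(math.inf, md) if md != 0 else 0.0
        p = 0.0 if md != 0 else 1.0
        return t, df, p, (md, md)
    se = sd / math.sqrt(n)
    t = md / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), _t_ci(md, se, df)


def independent_ttest(a: Sequence[float], b: Sequence[float]
                      ) -> Tuple[float, int, float, Tuple[float, float]]:
    """Two-sided pooled-variance Student t-test: (t, df, p, 95% CI of mean diff)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("independent test needs n >= 2 per group")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    md = a.mean() - b.mean()
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        warnings.warn("zero pooled variance; t is infinite")
        t = math.copysign(math.inf, md) if md != 0 else 0.0
        p = 0.0 if md != 0 else 1.0
        return t, df, p, (md, md)
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = md / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), _t_ci(md, se, df)


def bin_improvements(deltas: Sequence[float]) -> Dict[str, int]:
    """Histogram of accuracy improvements over six 5-point bins (1–30%).

    Each value is rounded to the nearest integer percent (half-to-even) and
    assigned to the bin containing it; values landing outside every bin go
    to an ``outside`` bucket with a warning.
    """
    counts: Dict[str, int] = {lab: 0 for lab in BIN_LABELS}
    counts[OVERFLOW_LABEL] = 0
    for v in deltas:
        r = int(np.rint(v))
        for (lo, hi), lab in zip(IMPROVEMENT_BINS, BIN_LABELS):
            if lo <= r <= hi:
                counts[lab] += 1
                break
        else:
            warnings.warn(f"improvement {v:.2f}% falls outside the 1-30% bins")
            counts[OVERFLOW_LABEL] += 1
    return counts


def compare_cohort(records: List[SubjectRecord]) -> CohortComparison:
    """The full group analysis over completed subject records.

    Requires each record to carry eval_ml, eval_dl and online_accuracy.
    Performs the median split (if not already assigned), computes ΔAccu per
    subject, per-group moments and normality, the between-group independent
    t-test, the pooled paired t-test of CNN vs CSP+LDA test accuracy, and
    the improvement histogram.
    """
    if any(r.eval_ml is None or r.eval_dl is None for r in records):
        raise ValueError("all records need both model evaluations")
    for r in records:
        r.delta_accu = delta_accuracy(r.eval_dl, r.eval_ml)
    if any(r.group is None for r in records):
        median_split(records)
    low = [r for r in records if r.group == "low"]
    high = [r for r in records if r.group == "high"]
    if len(low) < 3 or len(high) < 3:
        raise ValueError(
            "need at least 3 records per group (Shapiro-Wilk minimum)")
    d_low = np.array([r.delta_accu for r in low])
    d_high = np.array([r.delta_accu for r in high])
    t_ind, df_ind, p_ind, ci_ind = independent_ttest(d_low, d_high)
    acc_dl = [r.eval_dl.test_accuracy for r in records]
    acc_ml = [r.eval_ml.test_accuracy for r in records]
    t_pair, df_pair, p_pair, ci_pair = paired_ttest(acc_dl, acc_ml)
    return CohortComparison(
        n_low=len(low), n_high=len(high),
        mean_delta_low=float(d_low.mean()), sd_delta_low=float(d_low.std(ddof=1)),
        mean_delta_high=float(d_high.mean()), sd_delta_high=float(d_high.std(ddof=1)),
        shapiro_low=shapiro_wilk(d_low), shapiro_high=shapiro_wilk(d_high),
        independent_t=(t_ind, df_ind, p_ind), independent_ci95=ci_ind,
        paired_t=(t_pair, df_pair, p_pair), paired_ci95=ci_pair,
        histogram=bin_improvements([r.delta_accu for r in records]),
    )
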