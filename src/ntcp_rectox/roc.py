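"""ROC curves, AUC, and AUC confidence intervals for binary outcomes.

AUC is computed as the Mann-Whitney pairwise statistic
P(score_event > score_nonevent) + 0.5 * P(tie), which equals the
trapezoidal area under the empirical ROC curve; both routes are exposed
and agree exactly (with tie handling) by construction of the curve on
unique thresholds.  Confidence intervals use a stratified nonparametric
bootstrap (percentile) by default; the DeLong asymptotic interval is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["ROCResult", "SingleClassError", "auc", "auc_ci", "roc_curve"]


class SingleClassError(ValueError):
    """Outcomes contain only events or only non-events."""


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray          # 1 - specificity
    tpr: np.ndarray          # sensitivity
    auc: float
    auc_ci95: tuple | None
    method: str


def _validate(scores, outcomes):
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be matching 1-D arrays")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.sum() == 0 or y.sum() == y.size:
        raise SingleClassError("outcomes must contain both classes")
    return s, y


def auc(scores, outcomes) -> float:
    """Mann-Whitney AUC: fraction of (event, non-event) pairs correctly
    ordered, counting ties as half."""
    s, y = _validate(scores, outcomes)
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = rankdata(s)  # mid-ranks handle ties as half-credit
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores, outcomes) -> ROCResult:
    """Empirical ROC on unique descending thresholds, from (0,0) to (1,1).

    The trapezoidal area equals the pairwise AUC to machine precision.
    """
    s, y = _validate(scores, outcomes)
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([distinct, [y.size - 1]])
    tps = np.cumsum(y_sorted)[idx]
    fps = (idx + 1) - tps
    n1 = int(y.sum())
    n0 = y.size - n1
    tpr = np.concatenate([[0.0], tps / n1])
    fpr = np.concatenate([[0.0], fps / n0])
    thresholds = np.concatenate([[np.inf], s_sorted[idx]])
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds, fpr, tpr, area, None, "trapezoid")


def _auc_from_ranks(s, y):
    n1 = y.sum()
    return (rankdata(s)[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * (y.size - n1))


def auc_ci(
    scores,
    outcomes,
    n_boot: int = 2000,
    seed: int | None = None,
    method: str = "bootstrap",
) -> tuple:
    """95% CI for the AUC.

    ``bootstrap``: stratified nonparametric percentile interval (events and
    non-events resampled separately), deterministic given ``seed``.
    ``delong``: asymptotic normal interval from the DeLong variance.
    Intervals are clipped to [0, 1].
    """
    s, y = _validate(scores, outcomes)
    point = auc(s, y)
    if method == "delong":
        ev, ne = s[y == 1], s[y == 0]
        n1, n0 = ev.size, ne.size
        # placement values: V10[i] = P(ne < ev_i) + 0.5 P(=), and symmetric
        v10 = np.array([(np.sum(ne < e) + 0.5 * np.sum(ne == e)) / n0 for e in ev])
        v01 = np.array([(np.sum(ev > x) + 0.5 * np.sum(ev == x)) / n1 for x in ne])
        var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
            np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
        )
        half = norm.ppf(0.975) * np.sqrt(var)
        lo, hi = point - half, point + half
    elif method == "bootstrap":
        if n_boot < 200:
            raise ValueError("n_boot must be >= 200")
        rng = np.random.default_rng(seed)
        ev, ne = s[y == 1], s[y == 0]
        stats = np.empty(n_boot)
        yy = np.concatenate([np.ones(ev.size, int), np.zeros(ne.size, int)])
        for b in range(n_boot):
            sb = np.concatenate(
                [rng.choice(ev, ev.size, replace=True), rng.choice(ne, ne.size, replace=True)]
            )
            stats[b] = _auc_from_ranks(sb, yy)
        lo, hi = np.percentile(stats, [2.5, 97.5])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo = min(float(np.clip(lo, 0.0, 1.0)), point)
    hi = max(float(np.clip(hi, 0.0, 1.0)), point)
    return lo, hi
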