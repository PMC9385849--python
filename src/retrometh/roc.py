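"""Single-locus ROC evaluation.

Each candidate CpG's raw beta value is used as the classifier score (no
model fitting).  AUC is the tie-corrected Mann-Whitney U statistic scaled
by n_pos * n_neg; confidence intervals come from the DeLong variance
estimate (default, deterministic) or a seeded percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ROCResult", "auc_mann_whitney", "roc_points", "auc_ci", "roc_table"]


def auc_mann_whitney(scores_pos, scores_neg) -> float:
    """AUC = U / (n_pos * n_neg) with 0.5 credit per tie.

    No orientation flip is applied; the caller chooses score polarity.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes need at least one score")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve points (fpr, tpr), thresholded at each distinct score.

    ``labels`` are truthy for the positive class.  The curve starts at
    (0, 0), ends at (1, 1) and is non-decreasing in both coordinates; its
    trapezoidal area equals :func:`auc_mann_whitney`.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes need at least one sample")
    order = np.argsort(-scores, kind="mergesort")
    scores_sorted, y_sorted = scores[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # keep only the last index of each run of equal scores
    distinct = np.nonzero(np.diff(scores_sorted, append=np.nan))[0]
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    return np.column_stack([fpr, tpr])


def _delong_variance(pos: np.ndarray, neg: np.ndarray):
    """DeLong AUC and its variance via placement values."""
    m, n = pos.size, neg.size
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(
    scores_pos,
    scores_neg,
    method: str = "delong",
    level: float = 0.95,
    seed: int = 0,
    n_boot: int = 2000,
):
    """Confidence interval for the AUC, truncated to [0, 1].

    Returns ``(ci_low, ci_high, degenerate)`` where ``degenerate`` marks a
    zero DeLong variance (e.g. perfect separation), reported as the point
    interval [auc, auc].
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 scores per class")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if method == "delong":
        auc, var = _delong_variance(pos, neg)
        if var <= 0:
            return auc, auc, True
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        return max(0.0, auc - half), min(1.0, auc + half), False
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for i in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            aucs[i] = auc_mann_whitney(bp, bn)
        lo, hi = np.quantile(aucs, [(1 - level) / 2.0, 0.5 + level / 2.0])
        degenerate = lo == hi
        return float(lo), float(hi), bool(degenerate)
    raise ValueError("method must be 'delong' or 'bootstrap'")


@dataclass
class ROCResult:
    probe_id: str
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    method: str
    degenerate: bool
    curve: np.ndarray = field(repr=False)


def roc_table(
    beta,
    probe_ids,
    case_label: str,
    control_labels,
    method: str = "delong",
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-probe ROC evaluation of a variant cohort against pooled controls.

    ``beta`` is a :class:`retrometh.diffmeth.BetaMatrix`; the positive
    class is ``case_label`` and the negative class pools all
    ``control_labels``.  Scores are raw beta values.
    """
    pos_samples = beta.samples_in(case_label)
    neg_samples = [s for lab in control_labels for s in beta.samples_in(lab)]
    if len(pos_samples) < 2 or len(neg_samples) < 2:
        raise ValueError("need at least 2 samples per class")
    rows = []
    for pid in probe_ids:
        pid = str(pid)
        if pid not in beta.values.index:
            raise KeyError(f"probe {pid!r} not in beta matrix")
        pos = beta.values.loc[pid, pos_samples].to_numpy(dtype=float)
        neg = beta.values.loc[pid, neg_samples].to_numpy(dtype=float)
        auc = auc_mann_whitney(pos, neg)
        lo, hi, deg = auc_ci(pos, neg, method=method, level=level, seed=seed)
        rows.append(
            {
                "probe_id": pid,
                "auc": auc,
                "ci_low": lo,
                "ci_high": hi,
                "n_pos": len(pos_samples),
                "n_neg": len(neg_samples),
                "method": method,
                "degenerate": deg,
            }
        )
    return pd.DataFrame(rows)
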