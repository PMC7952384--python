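"""Evaluation metrics and statistics for the screening pipeline.

Dice overlap, sensitivity/specificity with exact Clopper-Pearson
confidence intervals, ROC AUC with a logit-transformed confidence interval
(Hanley-McNeil variance), confidence-region-stratified performance tables,
the Wilcoxon rank-sum comparison of ISNT scores, and the Pearson
correlation used to compare the pipeline's MCDR with expert VCDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

__all__ = [
    "dice",
    "clopper_pearson",
    "sens_spec_ci",
    "roc_auc",
    "auc_ci_logit",
    "region_table",
    "wilcoxon_rank_sum",
    "pearson_correlation",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient: intersection area over the average of the two areas.

    Two empty masks agree perfectly on absence and score 1 by convention.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one shape")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (beta-quantile) binomial confidence interval."""
    if trials < 1:
        raise ValueError("need at least one trial")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lo, hi


def sens_spec_ci(tp: int, fn: int, tn: int, fp: int, level: float = 0.95) -> dict:
    """Sensitivity and specificity with exact Clopper-Pearson intervals."""
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("both a positive and a negative class are required")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = clopper_pearson(tp, tp + fn, level)
    spec_ci = clopper_pearson(tn, tn + fp, level)
    return {
        "sensitivity": sens,
        "sensitivity_ci": sens_ci,
        "specificity": spec,
        "specificity_ci": spec_ci,
    }


def roc_auc(p, labels) -> float:
    """AUC of the ROC curve; equals the Mann-Whitney probability
    P(score_case > score_control) + 0.5 * P(equal)."""
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels.astype(int), np.asarray(p, float)))


def auc_ci_logit(auc: float, n_pos: int, n_neg: int, level: float = 0.95) -> tuple[float, float]:
    """Logit-transformed nonparametric AUC confidence interval.

    The AUC variance is the Hanley-McNeil estimate; the normal interval is
    formed on logit(AUC) via the delta method and back-transformed, so the
    bounds always stay inside (0, 1).
    """
    if not 0.0 < auc < 1.0:
        raise ValueError("degenerate AUC of exactly 0 or 1; use exact methods instead")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes must be non-empty")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se_logit = np.sqrt(max(var, 0.0)) / (auc * (1 - auc))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = expit(logit(auc) - z * se_logit), expit(logit(auc) + z * se_logit)
    return float(lo), float(hi)


def _counts(pred_glaucoma: np.ndarray, truth: np.ndarray) -> dict:
    return {
        "tp": int(np.sum(pred_glaucoma & truth)),
        "fn": int(np.sum(~pred_glaucoma & truth)),
        "tn": int(np.sum(~pred_glaucoma & ~truth)),
        "fp": int(np.sum(pred_glaucoma & ~truth)),
    }


def _row(name: str, counts: dict, level: float) -> dict:
    row = {"region": name, **counts}
    pos = counts["tp"] + counts["fn"]
    neg = counts["tn"] + counts["fp"]
    if pos > 0:
        row["sensitivity"] = counts["tp"] / pos
        row["sensitivity_lo"], row["sensitivity_hi"] = clopper_pearson(counts["tp"], pos, level)
    else:
        row["sensitivity"] = row["sensitivity_lo"] = row["sensitivity_hi"] = np.nan
    if neg > 0:
        row["specificity"] = counts["tn"] / neg
        row["specificity_lo"], row["specificity_hi"] = clopper_pearson(counts["tn"], neg, level)
    else:
        row["specificity"] = row["specificity_lo"] = row["specificity_hi"] = np.nan
    return row


def region_table(diagnoses, labels, level: float = 0.95) -> pd.DataFrame:
    """Confidence-region-stratified performance table.

    Rows: overall, reliable (union of reliable_glaucoma and
    reliable_normal), suspicious.  The per-cell counts of the reliable and
    suspicious rows partition the overall row.
    """
    if len(diagnoses) == 0:
        raise ValueError("no diagnoses to tabulate")
    truth = np.asarray(labels, bool)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present overall")
    pred = np.array([d.final_label == "glaucoma" for d in diagnoses])
    reliable = np.array([d.region in ("reliable_glaucoma", "reliable_normal") for d in diagnoses])
    rows = [
        _row("overall", _counts(pred, truth), level),
        _row("reliable", _counts(pred[reliable], truth[reliable]), level),
        _row("suspicious", _counts(pred[~reliable], truth[~reliable]), level),
    ]
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with tie correction.

    Returns the Mann-Whitney U statistic of the first sample and the
    two-sided p-value (exact for small tie-free samples).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(result.statistic), float(result.pvalue)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation between two measurement vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation is undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
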