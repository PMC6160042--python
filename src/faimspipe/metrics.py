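"""ROC/AUC evaluation with stratified bootstrap confidence intervals.

AUC is the Mann–Whitney probability that a randomly chosen case scores
above a randomly chosen control (ties count one half), identical to the
trapezoidal area under the ROC curve.  Confidence intervals are
percentile intervals over 2000 stratified bootstrap replicates (cases
and controls resampled independently).  The operating threshold
maximises (SE − 1 + SP)² + (SP − 1 + SE)², which algebraically equals
2·(SE + SP − 1)² — i.e. the squared Youden index — and sensitivity/
specificity get exact Clopper–Pearson binomial intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .selection import ranksum_p, _labels_to_case_mask

__all__ = [
    "ROCSummary",
    "auc",
    "bootstrap_ci",
    "balance_threshold",
    "binomial_ci",
    "roc_points",
    "roc_summary",
    "demographic_auc",
    "compare_predictions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROCSummary:
    """AUC with bootstrap CI plus the balanced operating point."""

    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_boot: int = 2000
    n_case: int = 0
    n_control: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "n_boot": self.n_boot,
            "n_case": self.n_case,
            "n_control": self.n_control,
        }


def _split_scores(labels: Sequence, scores: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    mask = _labels_to_case_mask(labels)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != mask.shape:
        raise ValueError("labels and scores differ in length")
    return scores[mask], scores[~mask]


def auc(labels: Sequence, scores: Sequence[float]) -> float:
    """Mann–Whitney AUC: P(case score > control score) + ½·P(tie)."""
    case, control = _split_scores(labels, scores)
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def _auc_from_groups(case: np.ndarray, control: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([case, control]))
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def bootstrap_ci(
    labels: Sequence,
    scores: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% percentile CI of the AUC over stratified bootstrap replicates.

    Cases and controls are resampled with replacement independently, so
    every replicate contains both classes.
    """
    case, control = _split_scores(labels, scores)
    rng = np.random.default_rng(seed)
    n1, n2 = case.size, control.size
    idx1 = rng.integers(0, n1, size=(n_boot, n1))
    idx2 = rng.integers(0, n2, size=(n_boot, n2))
    boot_case = case[idx1]
    boot_ctrl = control[idx2]
    pooled = np.concatenate([boot_case, boot_ctrl], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    aucs = u / (n1 * n2)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def balance_threshold(labels: Sequence, scores: Sequence[float]) -> tuple[float, float, float]:
    """Operating point maximising (SE−1+SP)² + (SP−1+SE)².

    Candidate thresholds are midpoints of adjacent distinct sorted
    scores plus sentinels below the minimum and above the maximum; a
    sample is called a case when its score ≥ threshold.  The criterion
    equals 2·(SE+SP−1)², so it selects a Youden-index extremum; ties are
    broken by higher specificity, then lower threshold.

    Returns ``(threshold, sensitivity, specificity)``.
    """
    case, control = _split_scores(labels, scores)
    distinct = np.unique(np.concatenate([case, control]))
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    se = (case[None, :] >= candidates[:, None]).mean(axis=1)
    sp = (control[None, :] < candidates[:, None]).mean(axis=1)
    crit = (se - 1 + sp) ** 2 + (sp - 1 + se) ** 2
    # lexicographic tie-break: criterion, then specificity, then -threshold
    order = np.lexsort((candidates, -sp, -crit))
    best = order[0]
    return float(candidates[best]), float(se[best]), float(sp[best])


def binomial_ci(successes: int, total: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= successes <= total:
        raise ValueError("successes must be in [0, total]")
    ci = stats.binomtest(successes, total).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return float(ci.low), float(ci.high)


def roc_points(labels: Sequence, scores: Sequence[float]):
    """All operating points as a DataFrame of (threshold, SE, SP)."""
    import pandas as pd

    case, control = _split_scores(labels, scores)
    distinct = np.unique(np.concatenate([case, control]))
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    se = (case[None, :] >= candidates[:, None]).mean(axis=1)
    sp = (control[None, :] < candidates[:, None]).mean(axis=1)
    return pd.DataFrame({"threshold": candidates, "sensitivity": se, "specificity": sp})


def roc_summary(
    labels: Sequence,
    scores: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCSummary:
    """Full evaluation of one prediction set."""
    case, control = _split_scores(labels, scores)
    point = _auc_from_groups(case, control)
    ci = bootstrap_ci(labels, scores, n_boot=n_boot, seed=seed)
    thr, se, sp = balance_threshold(labels, scores)
    se_ci = binomial_ci(int(round(se * case.size)), case.size)
    sp_ci = binomial_ci(int(round(sp * control.size)), control.size)
    return ROCSummary(
        auc=point,
        auc_ci=ci,
        threshold=thr,
        sensitivity=se,
        sensitivity_ci=se_ci,
        specificity=sp,
        specificity_ci=sp_ci,
        n_boot=n_boot,
        n_case=case.size,
        n_control=control.size,
    )


def demographic_auc(
    covariate: Sequence[float],
    labels: Sequence,
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCSummary:
    """Treat a single demographic covariate as a biomarker score.

    Sex should be encoded 0/1.  The AUC is orientation-corrected — if
    the covariate scores controls higher, the sign is flipped (logged)
    so the reported value is max(a, 1−a).  A constant covariate yields
    AUC 0.5 with a warning.
    """
    covariate = np.asarray(covariate, dtype=float)
    if np.unique(covariate).size == 1:
        logger.warning("constant covariate: AUC is 0.5 by convention")
        mask = _labels_to_case_mask(labels)
        return ROCSummary(
            auc=0.5,
            auc_ci=(0.5, 0.5),
            threshold=float(covariate[0]),
            sensitivity=1.0,
            sensitivity_ci=binomial_ci(int(mask.sum()), int(mask.sum())),
            specificity=0.0,
            specificity_ci=binomial_ci(0, int((~mask).sum())),
            n_boot=n_boot,
            n_case=int(mask.sum()),
            n_control=int((~mask).sum()),
        )
    if auc(labels, covariate) < 0.5:
        logger.info("covariate orientation flipped (controls scored higher)")
        covariate = -covariate
    return roc_summary(labels, covariate, n_boot=n_boot, seed=seed)


def compare_predictions(
    probabilities_a: Sequence[float], probabilities_b: Sequence[float]
) -> float:
    """Two-sided rank-sum p-value comparing two probability sets.

    Used to ask whether two pipeline variants (e.g. with and without
    demographic features) produce significantly different prediction
    probability distributions.
    """
    a = np.asarray(probabilities_a, dtype=float)
    b = np.asarray(probabilities_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both probability sets must be non-empty")
    return ranksum_p(a, b)
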