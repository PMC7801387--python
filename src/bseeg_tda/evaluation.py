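"""Case labeling, ROC/AUC with DeLong inference, and cohort-table statistics.

Delirium case status comes from clinical instruments (CAM-ICU, DRS, DOSS, or
chart documentation).  Scores are compared to that label with the ROC curve:
the AUC is the Mann–Whitney estimator (ties counted 1/2), its 95% CI uses the
DeLong structural-component variance with a normal approximation, and two
correlated AUCs (BSEEG vs TDA on the same subjects) are compared with the
paired DeLong test.  The clinical operating point fixes sensitivity at 0.80
and reports the specificity achieved there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "Assessment",
    "RocResult",
    "OperatingPoint",
    "DelongResult",
    "DegenerateCohortError",
    "DegenerateTableError",
    "label_delirium",
    "auc",
    "delong_paired_test",
    "specificity_at_sensitivity",
    "chi_square_2x2",
    "two_sample_t",
    "wilson_interval",
]


class DegenerateCohortError(ValueError):
    """ROC analysis needs at least one subject in each class."""


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero margin has no chi-square statistic."""


@dataclass(frozen=True)
class Assessment:
    """Clinical assessment of one subject at enrollment."""

    cam_icu_positive: bool = False
    drs: float = 0.0
    doss: float = 0.0
    chart_delirium: bool = False

    def __post_init__(self) -> None:
        if self.drs < 0 or self.doss < 0:
            raise ValueError("DRS and DOSS scores are nonnegative")


#: Instrument cut-offs defining a delirium case.
DRS_CUTOFF = 19.0
DOSS_CUTOFF = 3.0


def label_delirium(a: Assessment) -> bool:
    """Case definition: CAM-ICU positive, DRS ≥ 19, DOSS ≥ 3, or chart evidence."""
    return bool(
        a.cam_icu_positive
        or a.drs >= DRS_CUTOFF
        or a.doss >= DOSS_CUTOFF
        or a.chart_delirium
    )


@dataclass(frozen=True)
class RocResult:
    """AUC with DeLong 95% CI and the full threshold sweep.

    ``thresholds`` rows are (threshold, sensitivity, specificity); a subject
    is called positive when score ≥ threshold, so sensitivity falls and
    specificity rises as the threshold increases.
    """

    auc: float
    ci_low: float
    ci_high: float
    variance: float
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc + 1e-12 and self.auc <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the AUC")


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    degenerate: bool = False


def _check_cohort(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D sequences")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite (drop missing values first)")
    if labels.all() or not labels.any():
        raise DegenerateCohortError("need at least one positive and one negative subject")
    return scores, labels


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components.

    v10[i] = P(score of positive i exceeds a random negative) with ties 1/2,
    v01[j] likewise per negative; the AUC is the mean of either vector.
    """
    pos = scores[labels]
    neg = scores[~labels]
    greater = (pos[:, None] > neg[None, :]).astype(float)
    ties = (pos[:, None] == neg[None, :]).astype(float)
    psi = greater + 0.5 * ties
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def auc(scores: Sequence[float], labels: Sequence[bool], confidence: float = 0.95) -> RocResult:
    """Mann–Whitney AUC with DeLong variance and a normal-approximation CI.

    Higher score must mean more delirium-like.  The CI is clipped to [0, 1].
    """
    scores, labels = _check_cohort(np.asarray(scores), np.asarray(labels))
    v10, v01, auc_hat = _placements(scores, labels)
    n1, n0 = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if n1 > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n0 > 1 else 0.0
    variance = s10 / n1 + s01 / n0
    zq = stats.norm.ppf(0.5 + confidence / 2)
    half = zq * np.sqrt(max(variance, 0.0))
    ci_low = float(np.clip(auc_hat - half, 0.0, 1.0))
    ci_high = float(np.clip(auc_hat + half, 0.0, 1.0))

    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    sweep = np.column_stack([thr, tpr, 1.0 - fpr])
    return RocResult(auc=auc_hat, ci_low=min(ci_low, auc_hat), ci_high=max(ci_high, auc_hat),
                     variance=variance, thresholds=sweep)


def delong_paired_test(
    score_a: Sequence[float],
    score_b: Sequence[float],
    labels: Sequence[bool],
) -> DelongResult:
    """Paired DeLong test for two correlated AUCs on the same subjects.

    z = (AUC_a − AUC_b) / sqrt(var_a + var_b − 2 cov); two-sided p from the
    normal distribution.  When the variance of the difference is zero (e.g.
    identical score vectors) the comparison is degenerate and p = 1.
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    if score_a.shape != score_b.shape:
        raise ValueError("paired scores must have identical length")
    scores_a, lab = _check_cohort(score_a, np.asarray(labels))
    scores_b, _ = _check_cohort(score_b, np.asarray(labels))

    va10, va01, auc_a = _placements(scores_a, lab)
    vb10, vb01, auc_b = _placements(scores_b, lab)
    n1, n0 = len(va10), len(va01)

    def cov(x: np.ndarray, y: np.ndarray) -> float:
        if len(x) < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    var_a = (cov(va10, va10) / n1 if n1 > 1 else 0.0) + (cov(va01, va01) / n0 if n0 > 1 else 0.0)
    var_b = (cov(vb10, vb10) / n1 if n1 > 1 else 0.0) + (cov(vb01, vb01) / n0 if n0 > 1 else 0.0)
    cov_ab = (cov(va10, vb10) / n1 if n1 > 1 else 0.0) + (cov(va01, vb01) / n0 if n0 > 1 else 0.0)

    var_diff = var_a + var_b - 2 * cov_ab
    if var_diff <= 1e-15:
        return DelongResult(auc_a=auc_a, auc_b=auc_b, z=0.0, p=1.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return DelongResult(auc_a=auc_a, auc_b=auc_b, z=float(z), p=float(p))


def specificity_at_sensitivity(roc: RocResult, target_sensitivity: float = 0.80) -> OperatingPoint:
    """Best specificity among thresholds whose sensitivity reaches the target.

    No interpolation: the returned point is an actual threshold of the sweep,
    with its achieved (≥ target) sensitivity.  If no threshold attains the
    target, the all-positive threshold (sensitivity 1) is returned.
    """
    sweep = roc.thresholds
    if sweep.size == 0:
        raise ValueError("empty ROC sweep")
    ok = sweep[:, 1] >= target_sensitivity
    if not ok.any():
        ok = sweep[:, 1] >= sweep[:, 1].max()
    candidates = sweep[ok]
    best = candidates[np.argmax(candidates[:, 2])]
    return OperatingPoint(threshold=float(best[0]), sensitivity=float(best[1]),
                          specificity=float(best[2]))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of [[a, b], [c, d]] without continuity correction."""
    table = np.asarray([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError("zero row or column margin")
    stat, _, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat)


def two_sample_t(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> float:
    """Pooled-variance unpaired t-statistic from group summaries (a − b)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n ≥ 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    t, _ = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True)
    return float(t)


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Offered for specificity/sensitivity point estimates; this is the
    package's own interval choice, not a reproduction of any published one.
    """
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError("need 0 ≤ successes ≤ n with n > 0")
    z = stats.norm.ppf(0.5 + confidence / 2)
    p = successes / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))
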