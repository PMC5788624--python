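"""Marker-level statistics: Welch's t, pooled fold change, ROC/AUC with
Hanley-McNeil confidence intervals, Youden cutoffs, Wilson score intervals,
marker-sum panels, and Fisher's exact test for 2x2 tables.

These are the tests and summaries applied to the absolute-copy expression
data: Welch's two-tailed t-test for differential expression, fold changes of
sample-size-weighted pooled group means, ROC curves whose AUC equals the
pairwise concordance probability, single cutoffs chosen by the Youden index,
binomial confidence intervals by the Wilson score method, and Fisher's exact
test for dichotomized in situ hybridization calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateDataError, DomainError, InsufficientDataError, MarkerMissingError


@dataclass(frozen=True)
class GroupSummary:
    """Sample count and arithmetic mean copies for one histology group."""

    label: str
    n: int
    mean: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if not math.isfinite(self.mean):
            raise DomainError(f"group {self.label!r}: mean must be finite")


@dataclass(frozen=True)
class ROCResult:
    """AUC with a Hanley-McNeil CI, the ROC points, and the chosen cutoff.

    The confidence interval is Wald-type (AUC +/- z * SE) and may extend
    beyond [0, 1]; it is reported unclipped, as ROC software conventionally
    prints it.
    """

    auc: float
    ci_low: float
    ci_high: float
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    cutoff: float
    sensitivity: float
    specificity: float


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("Welch's t needs >= 2 values per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pooled_mean(summaries: Iterable[GroupSummary]) -> float:
    """Sample-size-weighted mean across groups."""
    summaries = list(summaries)
    total_n = sum(s.n for s in summaries)
    if total_n == 0:
        raise DomainError("no samples in pooled groups")
    return sum(s.n * s.mean for s in summaries) / total_n


def group_fold_change(
    summaries: Sequence[GroupSummary],
    numerator: Sequence[str],
    denominator: Sequence[str],
) -> float:
    """Fold change of pooled means: pooled(numerator) / pooled(denominator).

    Pooling is sample-size weighted, so e.g. the distal-vs-proximal fold for
    a marker equals (n_onco*mean_onco + n_ch*mean_ch)/(n_onco+n_ch) divided by
    the corresponding pooled proximal mean. With single groups on both sides
    this reduces to a plain ratio of means.
    """
    by_label = {s.label: s for s in summaries}
    for lbl in list(numerator) + list(denominator):
        if lbl not in by_label:
            raise DomainError(f"group {lbl!r} not found in summaries")
    num = pooled_mean(by_label[l] for l in numerator)
    den = pooled_mean(by_label[l] for l in denominator)
    if den <= 0:
        raise DomainError(f"denominator pooled mean must be > 0, got {den}")
    return num / den


def _concordance_auc(positives: np.ndarray, negatives: np.ndarray) -> float:
    """Mann-Whitney concordance: P(pos > neg) + 0.5 * P(pos == neg)."""
    pooled = np.concatenate([positives, negatives])
    ranks = sps.rankdata(pooled)
    n_pos, n_neg = len(positives), len(negatives)
    rank_sum = ranks[:n_pos].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of the AUC by the Hanley-McNeil formula."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc_auc(
    positives: Sequence[float],
    negatives: Sequence[float],
    confidence: float = 0.95,
) -> ROCResult:
    """ROC analysis of a marker: concordance AUC, Hanley-McNeil CI, Youden cutoff.

    Orientation is caller-declared: ``positives`` is the class expected to
    score high. The AUC is not reflected about 0.5, so an anti-discriminating
    marker yields AUC < 0.5.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise InsufficientDataError("ROC needs >= 1 value in each class")
    auc = _concordance_auc(pos, neg)
    se = hanley_mcneil_se(auc, len(pos), len(neg))
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    scores = np.concatenate([pos, neg])
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    cutoff, sens, spec = youden_cutoff(pos, neg)
    return ROCResult(
        auc=float(auc),
        ci_low=float(auc - z * se),
        ci_high=float(auc + z * se),
        fpr=tuple(float(v) for v in fpr),
        tpr=tuple(float(v) for v in tpr),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
    )


def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct observed values."""
    uniq = np.unique(values)
    if len(uniq) < 2:
        return uniq.copy()
    return (uniq[:-1] + uniq[1:]) / 2.0


def youden_cutoff(
    positives: Sequence[float], negatives: Sequence[float]
) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent observed values (so no datum
    sits exactly on the cutoff); a sample is called positive when its value
    is strictly above the cutoff. Ties in J are broken toward higher
    specificity, i.e. the higher cutoff.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    values = np.concatenate([pos, neg])
    cands = _candidate_cutoffs(values)
    if len(cands) == 0:
        raise InsufficientDataError("no candidate cutoffs")
    sens = (pos[None, :] > cands[:, None]).mean(axis=1)
    spec = (neg[None, :] <= cands[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    tied = np.flatnonzero(j >= j.max() - 1e-12)
    i = int(tied[-1])  # highest cutoff among ties -> highest specificity
    return float(cands[i]), float(sens[i]), float(spec[i])


def wilson_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials < 1:
        raise DomainError(f"trials must be >= 1, got {trials}")
    if not 0 <= successes <= trials:
        raise DomainError(f"successes {successes} outside [0, {trials}]")
    low, high = proportion_confint(successes, trials, alpha=1 - confidence, method="wilson")
    return float(low), float(high)


def combined_panel_score(
    sample: Mapping[str, float], markers: Sequence[str]
) -> float:
    """Sum of absolute copy values over a marker subset.

    The marker-combination score used to ask whether summed expression of
    two markers discriminates better than either alone.
    """
    total = 0.0
    for m in markers:
        if m not in sample:
            raise MarkerMissingError(m, "combined_panel_score")
        total += float(sample[m])
    return total


def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table: returns (odds ratio, two-sided p).

    The two-sided p follows the probability-mass rule (sum over all tables
    with the observed margins whose conditional probability does not exceed
    the observed table's). The odds ratio is the sample cross-product ad/bc,
    reported as ``inf`` when bc = 0 with ad > 0.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise DomainError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise DomainError("table entries must be non-negative integers")
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise DegenerateDataError("a margin of the 2x2 table is zero")
    odds, p = sps.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(odds), float(p)


def marker_comparison(
    high_group: Sequence[float],
    low_group: Sequence[float],
    summaries: Sequence[GroupSummary] | None = None,
    numerator: Sequence[str] | None = None,
    denominator: Sequence[str] | None = None,
) -> dict:
    """One row of the marker-statistics report for a single comparison.

    ``high_group`` holds the per-sample values of the class expected to
    express high (the ROC positive class). Returns fold change (from the
    supplied summaries or from the empirical means), Welch's t/df/p, AUC with
    CI, Youden cutoff with sensitivity/specificity, Wilson CIs on both, and
    the accuracy at the cutoff.
    """
    hi = np.asarray(high_group, dtype=float)
    lo = np.asarray(low_group, dtype=float)
    if summaries is not None and numerator is not None and denominator is not None:
        fold = group_fold_change(summaries, numerator, denominator)
    else:
        fold = float(hi.mean() / lo.mean())
    t, df, p = welch_t_test(hi, lo)
    roc = roc_auc(hi, lo)
    n_hi, n_lo = len(hi), len(lo)
    tp = int(np.sum(hi > roc.cutoff))
    tn = int(np.sum(lo <= roc.cutoff))
    sens_ci = wilson_ci(tp, n_hi)
    spec_ci = wilson_ci(tn, n_lo)
    return {
        "fold": fold,
        "t": t,
        "df": df,
        "p": p,
        "auc": roc.auc,
        "auc_ci_low": roc.ci_low,
        "auc_ci_high": roc.ci_high,
        "cutoff": roc.cutoff,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
        "sens_ci_low": sens_ci[0],
        "sens_ci_high": sens_ci[1],
        "spec_ci_low": spec_ci[0],
        "spec_ci_high": spec_ci[1],
        "accuracy": (tp + tn) / (n_hi + n_lo),
        "n_high": n_hi,
        "n_low": n_lo,
    }
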