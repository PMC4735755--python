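"""Within/between-class distance summaries and the study's test statistics.

* Per-sample average Euclidean distance to same-class samples ("within")
  and to different-class samples ("between") in the projected face space;
  their separation indexes class clustering.
* One-sided two-sample Kolmogorov-Smirnov test of the alternative
  "between stochastically larger than within",
  D = max_x [ ECDF_within(x) - ECDF_between(x) ], asymptotic p.
* Pooled-variance (Student) two-sample t-test for comparing
  percent-correct samples across conditions, df = n1 + n2 - 2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from .subspace import ProjectedSet

__all__ = [
    "DistanceSummary",
    "StatResult",
    "class_distance_summary",
    "ks_between_gt_within",
    "compare_conditions_ttest",
]


@dataclass(frozen=True)
class DistanceSummary:
    """Per-sample within/between average distances plus the KS test of
    'between' > 'within'.  Samples in singleton classes contribute to
    'between' only."""

    within_avg: np.ndarray = field(repr=False)
    between_avg: np.ndarray = field(repr=False)
    ks_D: float
    ks_p: float


@dataclass(frozen=True)
class StatResult:
    """Pooled two-sample t-test result (df = n1 + n2 - 2)."""

    t_value: float
    df: int
    p_value: float


def class_distance_summary(pset: ProjectedSet) -> DistanceSummary:
    """Average each sample's Euclidean distances to all other samples,
    split by shared vs different evaluation label."""
    labels = np.asarray(pset.eval_labels)
    n = pset.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("all samples share one class; need >= 2 classes")
    dist = squareform(pdist(pset.coordinates))
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    diff = labels[:, None] != labels[None, :]

    n_same = same.sum(axis=1)
    n_diff = diff.sum(axis=1)
    with np.errstate(invalid="ignore"):
        within_all = (dist * same).sum(axis=1) / n_same
    between_avg = (dist * diff).sum(axis=1) / n_diff
    within_avg = within_all[n_same > 0]  # singleton classes excluded
    d, p = ks_between_gt_within(within_avg, between_avg)
    return DistanceSummary(
        within_avg=within_avg, between_avg=between_avg, ks_D=d, ks_p=p
    )


def ks_between_gt_within(
    within_avg: np.ndarray, between_avg: np.ndarray
) -> tuple[float, float]:
    """One-sided two-sample KS statistic for 'between' stochastically
    larger than 'within', with the one-sided asymptotic p-value (the
    exp(-2 n_eff D^2) large-sample form with Hodges' finite-sample
    correction, n_eff = n1 n2 / (n1 + n2))."""
    within_avg = np.asarray(within_avg, dtype=float)
    between_avg = np.asarray(between_avg, dtype=float)
    if within_avg.size == 0 or between_avg.size == 0:
        raise ValueError("both distance samples must be non-empty")
    res = scipy.stats.ks_2samp(
        within_avg, between_avg, alternative="greater", method="asymp"
    )
    return float(res.statistic), float(res.pvalue)


def compare_conditions_ttest(perf_a, perf_b) -> StatResult:
    """Pooled-variance two-sample t-test between two lists of
    percent-correct values; positive t when mean(perf_a) > mean(perf_b).

    Degenerate inputs: zero pooled variance with equal means gives
    t = 0, p = 1; zero pooled variance with unequal means is an error.
    """
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return StatResult(t_value=0.0, df=df, p_value=1.0)
        raise ValueError("zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return StatResult(t_value=float(t), df=int(df), p_value=float(p))
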