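"""Neurological severity scores and group statistics.

The NSS is a 0–18 composite (motor 0–6, sensory 0–2, beam balance 0–6,
reflex/abnormal movement 0–4; higher = worse), scored per rat by several
examiners over repeated trials and averaged.  Group results are summarized as
mean ± SEM and compared by two-sample t-tests (Welch by default); headline
between-group effects are reported as percent differences relative to the
anesthetic group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "NSS_CATEGORY_MAXIMA",
    "NSS_MAX_TOTAL",
    "NSSRecord",
    "GroupComparison",
    "nss_total",
    "group_summary",
    "ttest_groups",
    "percent_difference",
    "compare_groups",
    "timepoint_comparison",
]

NSS_CATEGORY_MAXIMA = {"motor": 6, "sensory": 2, "beam": 6, "reflex": 4}
NSS_MAX_TOTAL = sum(NSS_CATEGORY_MAXIMA.values())


@dataclass
class NSSRecord:
    """One examiner's scoring of one rat on one trial."""

    rat_id: str
    examiner_id: str
    motor: int
    sensory: int
    beam: int
    reflex: int
    trial_index: int = 0

    def validate(self) -> None:
        for name, maximum in NSS_CATEGORY_MAXIMA.items():
            v = getattr(self, name)
            if not 0 <= v <= maximum:
                raise ValueError(f"{name} score {v} outside [0, {maximum}]")

    @property
    def total(self) -> int:
        self.validate()
        return self.motor + self.sensory + self.beam + self.reflex


@dataclass
class GroupComparison:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_stat: float
    p_value: float
    percent_diff: float
    significant: bool


def nss_total(records: Sequence[NSSRecord]) -> float:
    """Composite score for one rat: per-record total, averaged over
    examiners and trials."""
    if len(records) == 0:
        raise ValueError("at least one record required")
    return float(np.mean([r.total for r in records]))


def group_summary(values: Iterable[float]) -> tuple[float, float]:
    """Mean and SEM (sample sd with n−1 denominator over √n)."""
    v = np.asarray(list(values), dtype=np.float64)
    if v.size < 2:
        raise ValueError("group summary needs n >= 2")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def ttest_groups(
    a: Iterable[float],
    b: Iterable[float],
    equal_var: bool = False,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test; Welch by default, pooled on request.

    Degenerate case: both groups with zero variance and equal means is a
    perfect null and reported as t = 0, p = 1.
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0, False
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), bool(p < alpha)


def percent_difference(mean_conscious: float, mean_anesthetic: float) -> float:
    """Relative group difference, % of the anesthetic-group mean, 1 decimal."""
    if mean_anesthetic <= 0:
        raise ValueError("anesthetic-group mean must be positive")
    return round(100.0 * (mean_conscious - mean_anesthetic) / mean_anesthetic, 1)


def compare_groups(
    a: Iterable[float],
    b: Iterable[float],
    equal_var: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Full mean ± SEM / t-test / percent-difference comparison (a vs b)."""
    a = list(a)
    b = list(b)
    mean_a, sem_a = group_summary(a)
    mean_b, sem_b = group_summary(b)
    t, p, sig = ttest_groups(a, b, equal_var=equal_var, alpha=alpha)
    return GroupComparison(
        mean_a=mean_a,
        sem_a=sem_a,
        mean_b=mean_b,
        sem_b=sem_b,
        t_stat=t,
        p_value=p,
        percent_diff=percent_difference(mean_a, mean_b) if mean_b > 0 else float("nan"),
        significant=sig,
    )


def timepoint_comparison(
    series_a: Sequence,
    series_b: Sequence,
    equal_var: bool = False,
    bonferroni: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-bin t-tests between two groups of area time series.

    ``series_a`` / ``series_b`` are sequences of :class:`AreaSeries` (one per
    animal) with identical time axes.  Returns (times, p-values); no
    multiple-testing correction by default, a Bonferroni factor on request.
    """
    times = np.asarray(series_a[0].times_min, dtype=np.float64)
    for s in list(series_a) + list(series_b):
        if not np.allclose(np.asarray(s.times_min, dtype=np.float64), times):
            raise ValueError("time axes are misaligned across animals")
    mat_a = np.array([s.areas_mm2 for s in series_a], dtype=np.float64)
    mat_b = np.array([s.areas_mm2 for s in series_b], dtype=np.float64)
    pvals = np.empty(times.size)
    for j in range(times.size):
        _, p, _ = ttest_groups(mat_a[:, j], mat_b[:, j], equal_var=equal_var)
        pvals[j] = p
    if bonferroni:
        pvals = np.minimum(pvals * times.size, 1.0)
    return times, pvals
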