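"""Univariate cohort statistics: Pearson correlations against viral load,
ANOVA / Kruskal–Wallis group comparisons with Bonferroni pairwise adjustment,
box-plot summaries with explicit whisker fences, and the representative-subject
selector used to pick cells for confocal imaging.

Box-plot "limits" follow the convention of drawing whiskers at *observed data
values*: the lower limit is the smallest sample value at or above
Q1 − 1.5·IQR, the upper limit the largest sample value at or below
Q3 + 1.5·IQR.  Quartiles use linear interpolation by default (type 7), with a
type-6 option for parity checks against spreadsheet software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    x_name: str
    y_name: str
    n_excluded: int = 0


@dataclass
class BoxStats:
    q1: float
    median: float
    mean: float
    q3: float
    lower_limit: float
    upper_limit: float
    n: int


@dataclass
class GroupTestResult:
    method: str
    statistic: float
    p_value: float
    pairwise_p: pd.DataFrame
    pairwise_significant: pd.DataFrame
    n_pairs: int


def correlate(
    x,
    y,
    log_x: bool = False,
    log_y: bool = False,
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value.

    Non-finite pairs are dropped (count reported); a log10 transform can be
    requested per variable, in which case nonpositive values are excluded too.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    if log_x:
        ok &= x > 0
    if log_y:
        ok &= y > 0
    n_excl = int((~ok).sum())
    if n_excl:
        log.info("correlate(%s, %s): excluded %d pairs", x_name, y_name, n_excl)
    xs, ys = x[ok], y[ok]
    if len(xs) < 3:
        raise ValueError("need at least 3 finite pairs")
    if log_x:
        xs = np.log10(xs)
    if log_y:
        ys = np.log10(ys)
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(float(r), len(xs), float(p), x_name, y_name, n_excl)


def box_stats(values, quartile_method: str = "linear") -> BoxStats:
    """Box-plot summary whose whisker limits are observed sample values.

    ``quartile_method`` is passed to :func:`numpy.quantile` (``"linear"`` =
    type 7 default; ``"weibull"`` = type 6 for spreadsheet parity).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 4:
        raise ValueError("need at least 4 finite values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=quartile_method)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside_lo = v[v >= lo_fence]
    inside_hi = v[v <= hi_fence]
    return BoxStats(
        q1=float(q1),
        median=float(med),
        mean=float(v.mean()),
        q3=float(q3),
        lower_limit=float(inside_lo.min()),
        upper_limit=float(inside_hi.max()),
        n=len(v),
    )


def compare_groups(values_by_group: dict, method: str = "kruskal") -> GroupTestResult:
    """Omnibus ANOVA or Kruskal–Wallis plus Bonferroni-adjusted pairwise tests.

    Pairwise tests reuse the omnibus method on each pair of groups; raw
    p-values are multiplied by the number of pairs and capped at 1, so a pair
    is flagged significant iff its raw p < 0.05 / n_pairs.
    """
    if method not in ("anova", "kruskal"):
        raise ValueError("method must be 'anova' or 'kruskal'")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v[np.isfinite(v)] for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if min(len(v) for v in groups.values()) < 2:
        raise ValueError("every group needs at least two values")
    samples = list(groups.values())
    if method == "anova":
        stat, p = stats.f_oneway(*samples)
        pair_fn = lambda a, b: stats.f_oneway(a, b)
    else:
        stat, p = stats.kruskal(*samples)
        pair_fn = lambda a, b: stats.kruskal(a, b)
    labels = list(groups)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    pair_p = pd.DataFrame(np.eye(len(labels)) * np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            _, p_raw = pair_fn(groups[a], groups[b])
            adj = min(1.0, float(p_raw) * n_pairs)
            pair_p.loc[a, b] = pair_p.loc[b, a] = adj
    return GroupTestResult(
        method="ANOVA" if method == "anova" else "Kruskal-Wallis",
        statistic=float(stat),
        p_value=float(p),
        pairwise_p=pair_p,
        pairwise_significant=pair_p < 0.05,
        n_pairs=n_pairs,
    )


def select_representative_subjects(values_by_subject: pd.Series) -> dict[str, str]:
    """Subjects with the minimal, median-rank and maximal parameter value.

    ``values_by_subject`` maps subject id -> value (e.g. basal MFI of high-ROS
    lymphocytes).  Ties resolve to the lexicographically lower subject id.
    Returns ``{"min": id, "med": id, "max": id}``.
    """
    s = pd.Series(values_by_subject).dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 subjects per group")
    order = s.reset_index()
    order.columns = ["subject_id", "value"]
    order = order.sort_values(["value", "subject_id"], kind="mergesort").reset_index(drop=True)
    med_pos = (len(order) - 1) // 2
    top = order["value"].iloc[-1]
    max_id = order.loc[order["value"] == top, "subject_id"].min()
    return {
        "min": str(order.loc[0, "subject_id"]),
        "med": str(order.loc[med_pos, "subject_id"]),
        "max": str(max_id),
    }
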