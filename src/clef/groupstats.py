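"""Two-group comparisons of per-subject metrics.

The primary contrast is a pooled-variance (Student's) two-tailed unpaired
t-test; Welch's correction is available via a flag.  Histogram bins are
compared per bin across subjects with Bonferroni adjustment, where the
multiplier m counts only the testable bins (bins with all-zero counts in
both groups are flagged untestable and excluded from m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "ttest_unpaired", "binwise_compare"]


@dataclass
class GroupComparison:
    metric: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float
    p_adjusted: float | None = None
    testable: bool = True

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "mean1": self.mean1, "sd1": self.sd1, "n1": self.n1,
            "mean2": self.mean2, "sd2": self.sd2, "n2": self.n2,
            "t": self.t, "df": self.df, "p": self.p,
            "p_adjusted": self.p_adjusted, "testable": self.testable,
        }


def ttest_unpaired(
    x_group,
    y_group,
    metric: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Two-tailed unpaired t-test (pooled variance by default).

    Zero variance in both groups with equal means yields t = 0, p = 1 by
    convention.
    """
    x = np.asarray(x_group, dtype=float)
    y = np.asarray(y_group, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("groups must contain finite values only")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):  # degenerate: no variance anywhere
        t = 0.0
        p = 1.0
        df = float(x.size + y.size - 2)
    return GroupComparison(
        metric=metric,
        mean1=float(x.mean()), sd1=float(x.std(ddof=1)), n1=int(x.size),
        mean2=float(y.mean()), sd2=float(y.std(ddof=1)), n2=int(y.size),
        t=t, df=df, p=p,
    )


def binwise_compare(
    counts_group1: np.ndarray,
    counts_group2: np.ndarray,
    bin_edges: np.ndarray,
    metric_prefix: str = "bin",
    welch: bool = False,
) -> list[GroupComparison]:
    """Per-bin t-tests on per-subject histogram counts, Bonferroni adjusted.

    ``counts_group*`` are (n_subjects, n_bins) arrays sharing ``bin_edges``.
    """
    c1 = np.atleast_2d(np.asarray(counts_group1, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts_group2, dtype=float))
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = edges.size - 1
    if c1.shape[1] != n_bins or c2.shape[1] != n_bins:
        raise ValueError("count matrices do not match the bin edges")
    results: list[GroupComparison] = []
    for j in range(n_bins):
        x, y = c1[:, j], c2[:, j]
        name = f"{metric_prefix}_{edges[j]:g}_{edges[j + 1]:g}"
        if not x.any() and not y.any():
            results.append(
                GroupComparison(
                    metric=name,
                    mean1=0.0, sd1=0.0, n1=x.size,
                    mean2=0.0, sd2=0.0, n2=y.size,
                    t=float("nan"), df=float(x.size + y.size - 2),
                    p=float("nan"), testable=False,
                )
            )
        else:
            results.append(ttest_unpaired(x, y, metric=name, welch=welch))
    m = sum(r.testable for r in results)
    for r in results:
        if r.testable:
            r.p_adjusted = min(1.0, m * r.p)
    return results
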