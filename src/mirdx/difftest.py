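"""Per-miRNA two-group Wilcoxon rank-sum tests and boxplot-style group
summaries.

The rank-sum p-value is exact (full enumeration of rank assignments) for
small tie-free samples, and a tie- and continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, MatrixError, SampleTable

__all__ = ["WilcoxonResult", "wilcoxon_rank_sum", "per_mirna_tests", "group_summary"]

ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank sum of the first group (midranks for ties)
    pvalue: float
    exact: bool

    def __iter__(self):
        return iter((self.statistic, self.pvalue))


def _exact_tails(ranks: np.ndarray, n1: int, w_obs: float) -> tuple[float, float]:
    """Null tail probabilities of the rank-sum by enumerating all C(n, n1)
    assignments of group membership to the observed ranks."""
    n = len(ranks)
    total = 0
    ge = 0
    le = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        w = float(ranks[list(idx)].sum())
        total += 1
        if w >= w_obs - eps:
            ge += 1
        if w <= w_obs + eps:
            le += 1
    return ge / total, le / total


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    exact_threshold: int = 12,
) -> WilcoxonResult:
    """Two-sample Wilcoxon rank-sum test.

    The statistic is the rank sum of ``x`` in the pooled sample (midranks
    for ties).  With combined n ≤ ``exact_threshold`` and no ties the null
    distribution is enumerated exactly; otherwise a normal approximation
    with tie correction and a 0.5 continuity correction is used.  The
    two-sided p is min(1, 2·min(tails)).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise MatrixError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    if n < 3:
        raise MatrixError("need a combined sample of at least 3")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < n

    if n <= exact_threshold and not has_ties:
        p_ge, p_le = _exact_tails(ranks, n1, w)
        exact = True
    else:
        mean = n1 * (n + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            # all values identical: the statistic is degenerate at its mean
            p_ge = p_le = 1.0
        else:
            sd = np.sqrt(var)
            p_ge = float(stats.norm.sf((w - mean - 0.5) / sd))
            p_le = float(stats.norm.cdf((w - mean + 0.5) / sd))
        exact = False

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return WilcoxonResult(statistic=w, pvalue=p, exact=exact)


def per_mirna_tests(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    mirna_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    adjust: str | None = None,
    exact_threshold: int = 12,
) -> pd.DataFrame:
    """Two-sided rank-sum test of tumor vs control for each miRNA.

    Raw p-values are reported; ``adjust="bh"`` adds a Benjamini–Hochberg
    column (off by default).  Rows preserve request order.
    """
    tumor = [s for s in matrix.sample_ids if samples.label_of(s) == "tumor"]
    control = [s for s in matrix.sample_ids if samples.label_of(s) == "control"]
    if not tumor or not control:
        raise MatrixError("both tumor and control groups must be non-empty")
    if mirna_ids is None:
        mirna_ids = list(matrix.mirna_ids)
    ti = [matrix.sample_index(s) for s in tumor]
    ci = [matrix.sample_index(s) for s in control]
    rows = []
    for m in mirna_ids:
        row = matrix.values[matrix.mirna_index(m), :]
        res = wilcoxon_rank_sum(row[ti], row[ci], "two_sided", exact_threshold)
        rows.append(
            {
                "mirna_id": m,
                "n_tumor": len(ti),
                "n_control": len(ci),
                "statistic": res.statistic,
                "p_two_sided": res.pvalue,
                "significant_0.05": res.pvalue < alpha,
            }
        )
    df = pd.DataFrame(rows)
    if adjust == "bh":
        p = df["p_two_sided"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(ranked)
        q[order] = np.minimum(ranked, 1.0)
        df["p_bh"] = q
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def group_summary(matrix: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Boxplot statistics per miRNA × group: median, quartiles, whisker
    bounds (most extreme values within 1.5·IQR of the quartiles), n."""
    groups = {
        "tumor": [s for s in matrix.sample_ids if samples.label_of(s) == "tumor"],
        "control": [s for s in matrix.sample_ids if samples.label_of(s) == "control"],
    }
    rows = []
    for m in matrix.mirna_ids:
        full = matrix.values[matrix.mirna_index(m), :]
        for group, ids in groups.items():
            if not ids:
                continue
            vals = full[[matrix.sample_index(s) for s in ids]]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
            rows.append(
                {
                    "mirna_id": m,
                    "group": group,
                    "n": int(vals.size),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "whisker_low": float(inside.min()),
                    "whisker_high": float(inside.max()),
                }
            )
    return pd.DataFrame(rows)
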