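"""Cross-platform and replicate agreement via Pearson correlation of
log expression: single-sample, differential (pairwise sample subtraction),
and replicate-by-replicate correlation matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix, MatrixError
from .normalize import LogConfig, log_transform, positive_common_subset

logger = logging.getLogger(__name__)

__all__ = [
    "pearson",
    "platform_correlation",
    "differential_correlation",
    "mean_pairwise_differential_correlation",
    "MeanDifferentialResult",
    "replicate_correlation_matrix",
]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson r after pairwise-dropping missing entries.

    Requires at least 3 complete pairs and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise MatrixError(f"need at least 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MatrixError("constant vector: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def _log_columns(
    ngs: ExpressionMatrix,
    array: ExpressionMatrix,
    samples: Sequence[str],
    cfg: LogConfig,
    strict: bool,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Positive-common-subset then log both matrices restricted to `samples`.

    Returns (ngs log columns, array log columns, common miRNA ids)."""
    a = ngs.subset_samples([s for s in samples])
    b = array.subset_samples([s for s in samples])
    a, b = positive_common_subset(a, b, strict=strict)
    la = log_transform(a, cfg)
    lb = log_transform(b, cfg)
    return la.values, lb.values, la.mirna_ids


def platform_correlation(
    ngs: ExpressionMatrix,
    array: ExpressionMatrix,
    sample: str,
    cfg: LogConfig = LogConfig(),
    strict: bool = True,
) -> float:
    """Pearson r between log NGS counts and log (probe-averaged) array
    signal for one sample, over the positive common miRNA subset."""
    va, vb, ids = _log_columns(ngs, array, [sample], cfg, strict)
    if len(ids) < 3:
        raise MatrixError(f"sample {sample!r}: fewer than 3 common positive miRNAs")
    return pearson(va[:, 0], vb[:, 0])


def differential_correlation(
    ngs: ExpressionMatrix,
    array: ExpressionMatrix,
    pair: tuple[str, str],
    cfg: LogConfig = LogConfig(),
    strict: bool = True,
) -> float:
    """Pearson r between the two platforms' per-miRNA log differences
    (sample_i − sample_j) on the common subset positive in all four columns."""
    i, j = pair
    if i == j:
        raise MatrixError("differential correlation needs two distinct samples")
    va, vb, _ = _log_columns(ngs, array, [i, j], cfg, strict)
    return pearson(va[:, 0] - va[:, 1], vb[:, 0] - vb[:, 1])


@dataclass
class MeanDifferentialResult:
    """Mean differential correlation with pair bookkeeping."""

    value: float
    n_pairs: int
    n_skipped: int
    pair_values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __float__(self) -> float:
        return self.value


def mean_pairwise_differential_correlation(
    ngs: ExpressionMatrix,
    array: ExpressionMatrix,
    samples: Sequence[str],
    cfg: LogConfig = LogConfig(),
    strict: bool = True,
) -> MeanDifferentialResult:
    """Arithmetic mean of differential_correlation over all unordered
    distinct sample pairs; pairs failing preconditions are skipped and
    counted."""
    samples = list(samples)
    if len(samples) < 2:
        raise MatrixError("need at least 2 samples")
    values: dict[tuple[str, str], float] = {}
    skipped = 0
    for i, j in combinations(sorted(samples), 2):
        try:
            values[(i, j)] = differential_correlation(ngs, array, (i, j), cfg, strict)
        except MatrixError as exc:
            skipped += 1
            logger.warning("skipping pair (%s, %s): %s", i, j, exc)
    if not values:
        raise MatrixError("no sample pair yielded a correlation")
    return MeanDifferentialResult(
        value=float(np.mean(list(values.values()))),
        n_pairs=len(values),
        n_skipped=skipped,
        pair_values=values,
    )


def replicate_correlation_matrix(
    replicates: Sequence[ExpressionMatrix],
    cfg: LogConfig = LogConfig(),
) -> np.ndarray:
    """Pairwise Pearson r of log expression across technical replicates.

    Each replicate contributes its full (miRNA × sample) log matrix,
    flattened; entries non-positive in either member of a pair are dropped
    pairwise.  Returns a symmetric k × k matrix with unit diagonal.
    """
    if len(replicates) < 2:
        raise MatrixError("need at least 2 replicates")
    base = replicates[0]
    for r in replicates[1:]:
        if r.mirna_ids != base.mirna_ids or r.sample_ids != base.sample_ids:
            raise MatrixError("replicates must share the same miRNA and sample universe")
    logs = [log_transform(r, cfg).values.ravel() for r in replicates]
    k = len(logs)
    out = np.eye(k)
    for a, b in combinations(range(k), 2):
        out[a, b] = out[b, a] = pearson(logs[a], logs[b])
    return out
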