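"""Normalization: log transform, per-sample z-scoring, probe averaging,
and the positive common-subset restriction used before cross-platform
log correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix, MatrixError, ProbeMap

logger = logging.getLogger(__name__)

__all__ = [
    "LogConfig",
    "log_transform",
    "zscore_by_sample",
    "average_probes_to_mirna",
    "positive_common_subset",
]


@dataclass(frozen=True)
class LogConfig:
    """Log-transform convention.

    ``base`` defaults to 10; with ``pseudocount`` 0 (the default),
    non-positive raw values become missing (NaN) rather than being shifted.
    """

    base: float = 10.0
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.base <= 1:
            raise ValueError("log base must exceed 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def log_transform(matrix: ExpressionMatrix, cfg: LogConfig = LogConfig()) -> ExpressionMatrix:
    """log_base(value + pseudocount); non-positive arguments become NaN."""
    if matrix.scale != "raw":
        raise MatrixError(f"log_transform expects a raw matrix, got scale={matrix.scale!r}")
    shifted = matrix.values + cfg.pseudocount
    out = np.full_like(shifted, np.nan, dtype=float)
    ok = shifted > 0
    out[ok] = np.log(shifted[ok]) / np.log(cfg.base)
    return matrix.with_values(out, scale="log")


def zscore_by_sample(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each sample column to mean 0, sample variance 1 (n−1).

    Missing entries are ignored in the moments and stay missing.
    """
    if matrix.scale == "zscore":
        # idempotence shortcut is NOT taken: re-standardizing is a no-op
        # numerically, so just fall through and recompute.
        pass
    values = matrix.values
    if matrix.n_mirna < 2:
        raise MatrixError("z-scoring needs at least 2 miRNAs per sample")
    out = np.empty_like(values, dtype=float)
    for j, sample in enumerate(matrix.sample_ids):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            raise MatrixError(f"sample {sample!r}: fewer than 2 observed values")
        sd = obs.std(ddof=1)
        if sd == 0:
            raise MatrixError(f"sample {sample!r}: constant column, cannot z-score")
        out[:, j] = (col - obs.mean()) / sd
    return matrix.with_values(out, scale="zscore")


def average_probes_to_mirna(
    probe_matrix: ExpressionMatrix, pmap: ProbeMap
) -> ExpressionMatrix:
    """Collapse probe rows to mature-miRNA rows by arithmetic mean.

    Probes absent from the map are dropped; the number dropped is logged.
    miRNA output order follows first appearance of each mapped probe.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    dropped = 0
    for i, probe in enumerate(probe_matrix.mirna_ids):
        if probe not in pmap:
            dropped += 1
            continue
        mirna = pmap[probe]
        if mirna not in groups:
            order.append(mirna)
            groups[mirna] = []
        groups[mirna].append(i)
    if dropped:
        logger.warning("average_probes_to_mirna: dropped %d unmapped probes", dropped)
    if not order:
        logger.warning("average_probes_to_mirna: no probes mapped; empty result")
    values = (
        np.vstack([probe_matrix.values[groups[m], :].mean(axis=0) for m in order])
        if order
        else np.empty((0, probe_matrix.n_samples))
    )
    return ExpressionMatrix(
        values=values,
        mirna_ids=order,
        sample_ids=list(probe_matrix.sample_ids),
        platform=probe_matrix.platform,
        scale=probe_matrix.scale,
    )


def positive_common_subset(
    ngs: ExpressionMatrix,
    array: ExpressionMatrix,
    strict: bool = True,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to miRNAs usable for log correlation.

    With ``strict=True`` (default) a miRNA is kept when every value in both
    matrices is strictly positive; ``strict=False`` keeps the literal
    non-negative rule (use together with a log pseudocount).  Output rows are
    sorted by miRNA id so the result is stable under input row permutation.
    """
    common = set(ngs.mirna_ids) & set(array.mirna_ids)
    if not common:
        raise MatrixError("no miRNA ids in common between the two matrices")

    def usable(matrix: ExpressionMatrix, mirna: str) -> bool:
        row = matrix.values[matrix.mirna_index(mirna), :]
        if np.isnan(row).any():
            return False
        return bool((row > 0).all() if strict else (row >= 0).all())

    keep = sorted(m for m in common if usable(ngs, m) and usable(array, m))
    if not keep:
        raise MatrixError("no miRNAs satisfy the positivity rule on both platforms")
    return ngs.subset_mirnas(keep), array.subset_mirnas(keep)
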