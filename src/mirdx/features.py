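"""PCA-based unsupervised feature extraction and PCA-based linear
discriminant diagnosis with leave-one-out cross-validation.

The procedure:

1. Embed each miRNA of a per-sample standardized matrix into two dimensions
   by PCA (miRNAs as observations, samples as variables) and select the M
   miRNAs farthest from the origin — an entirely label-free step.
2. Embed each sample into M′ dimensions by PCA of the selected M-row
   submatrix (samples as observations).
3. Classify with Fisher's linear discriminant on the M′-dimensional sample
   scores, validated leave-one-out: the sample embedding and the
   discriminant are refit on each fold's training samples and the held-out
   sample is projected into them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix, MatrixError, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "FEConfig",
    "FeatureSelection",
    "MirnaEmbedding",
    "SampleEmbedding",
    "LDAModel",
    "DiscriminationResult",
    "pca_embed_mirnas",
    "select_outlier_mirnas",
    "pca_embed_samples",
    "lda_fit",
    "lda_score",
    "loocv_classify",
    "classification_metrics",
    "fisher_exact_one_sided",
    "auc_from_scores",
]

POSITIVE = "tumor"
NEGATIVE = "control"


@dataclass(frozen=True)
class FEConfig:
    """Feature-extraction / discrimination configuration.

    ``m_select`` is the number of outlier miRNAs kept (the study used 11);
    the miRNA embedding is fixed at 2 PCs; ``m_prime`` sample-PC scores feed
    the discriminant.
    """

    m_select: int = 11
    m_prime: int = 2
    n_embed_pc: int = 2
    selection_rule: str = "top_M_distance"
    distance_threshold: float | None = None
    priors: str = "equal"  # or "proportional"

    def __post_init__(self) -> None:
        if self.m_select < 1:
            raise ValueError("m_select must be >= 1")
        if self.m_prime < 1:
            raise ValueError("m_prime must be >= 1")
        if self.n_embed_pc != 2:
            raise ValueError("the miRNA embedding is fixed at 2 PCs")
        if self.selection_rule not in ("top_M_distance", "distance_threshold"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")
        if self.priors not in ("equal", "proportional"):
            raise ValueError("priors must be 'equal' or 'proportional'")


@dataclass
class MirnaEmbedding:
    mirna_ids: list[str]
    coords: np.ndarray  # (n_mirna, 2) PC scores
    explained_variance: np.ndarray


@dataclass
class FeatureSelection:
    """Selected outlier miRNAs, sorted by descending distance from origin."""

    mirna_ids: list[str]
    coords: np.ndarray  # (M, 2)
    distances: np.ndarray  # (M,)


def _pca_scores(x: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-observation PCA. Returns (scores, components, mean, singular values).

    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive (determinism up to this convention).
    """
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    comps = vt[:n_components]
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            u[:, k] = -u[:, k]
    scores = xc @ comps.T
    return scores, comps, mean, s[:n_components]


def pca_embed_mirnas(matrix: ExpressionMatrix) -> MirnaEmbedding:
    """Embed each miRNA into 2-D: scores on the first two principal axes of
    the miRNA × sample matrix, miRNAs treated as observations.

    Expects a per-sample z-scored matrix; each sample dimension is
    (re)centered over miRNAs before the decomposition.
    """
    if matrix.scale != "zscore":
        raise MatrixError("pca_embed_mirnas expects a z-scored matrix")
    if matrix.n_mirna < 3 or matrix.n_samples < 2:
        raise MatrixError("need at least 3 miRNAs and 2 samples")
    if np.isnan(matrix.values).any():
        raise MatrixError("missing values not supported in the embedding")
    scores, _, _, sv = _pca_scores(matrix.values, 2)
    if sv[0] <= 1e-12:
        raise MatrixError("matrix has no variance: embedding undefined")
    # rank-1 input (proportional sample columns) is allowed: PC2 scores
    # are numerically zero and all distance lives on the first axis
    if sv[1] <= 1e-10 * sv[0]:
        scores[:, 1] = 0.0
    n = matrix.n_mirna
    return MirnaEmbedding(
        mirna_ids=list(matrix.mirna_ids),
        coords=scores,
        explained_variance=sv**2 / (n - 1),
    )


def select_outlier_mirnas(embedding: MirnaEmbedding, cfg: FEConfig) -> FeatureSelection:
    """Keep the M miRNAs with the largest Euclidean distance from the
    origin of the 2-D embedding; distance ties break lexicographically."""
    d = np.linalg.norm(embedding.coords, axis=1)
    if cfg.selection_rule == "top_M_distance":
        if cfg.m_select > len(embedding.mirna_ids):
            raise MatrixError(
                f"M={cfg.m_select} exceeds the {len(embedding.mirna_ids)} available miRNAs"
            )
        order = sorted(range(len(d)), key=lambda i: (-d[i], embedding.mirna_ids[i]))
        keep = order[: cfg.m_select]
    else:
        if cfg.distance_threshold is None:
            raise ValueError("distance_threshold rule requires a threshold")
        keep = [i for i in range(len(d)) if d[i] >= cfg.distance_threshold]
        keep.sort(key=lambda i: (-d[i], embedding.mirna_ids[i]))
        if not keep:
            raise MatrixError("no miRNA reaches the distance threshold")
    return FeatureSelection(
        mirna_ids=[embedding.mirna_ids[i] for i in keep],
        coords=embedding.coords[keep],
        distances=d[keep],
    )


@dataclass
class SampleEmbedding:
    """Fitted sample-space PCA: projects samples onto M′ principal axes."""

    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, m_prime)
    components: np.ndarray  # (m_prime, M)
    mean: np.ndarray  # (M,)

    def transform(self, columns: np.ndarray) -> np.ndarray:
        """Project new samples (columns of the M-row submatrix, shape
        (M,) or (n, M)) onto the fitted axes."""
        x = np.atleast_2d(columns)
        return (x - self.mean) @ self.components.T


def pca_embed_samples(
    matrix: ExpressionMatrix, selection: FeatureSelection, m_prime: int
) -> SampleEmbedding:
    """Embed samples into m_prime dimensions via PCA of the selected-miRNA
    submatrix, samples as observations."""
    sub = matrix.subset_mirnas(selection.mirna_ids)
    x = sub.values.T  # samples × M
    max_rank = min(len(selection.mirna_ids), sub.n_samples - 1)
    if m_prime > max_rank:
        raise MatrixError(f"m_prime={m_prime} exceeds available rank {max_rank}")
    scores, comps, mean, sv = _pca_scores(x, m_prime)
    return SampleEmbedding(
        sample_ids=list(sub.sample_ids), scores=scores, components=comps, mean=mean
    )


# -- Fisher linear discriminant ---------------------------------------------


@dataclass
class LDAModel:
    """Fisher discriminant: score = w·x; predict positive when the score
    exceeds ``threshold``."""

    weights: np.ndarray
    threshold: float
    positive: str = POSITIVE
    negative: str = NEGATIVE
    degenerate_majority: str | None = None


def lda_fit(scores: np.ndarray, labels: list[str], priors: str = "equal", ridge: float = 1e-6) -> LDAModel:
    """Fit Fisher's linear discriminant on M′-dimensional sample scores.

    Direction w = pooled-within-covariance⁻¹ (mean_pos − mean_neg); the
    threshold sits at the midpoint of the projected class means (equal
    priors) or is shifted by −log(π₊/π₋) under proportional priors.
    Singular pooled covariance is ridge-regularized (λ = ridge·trace/dim).
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[0] != len(labels):
        raise ValueError("scores and labels disagree in length")
    labels = list(labels)
    classes = sorted(set(labels))
    if set(classes) != {POSITIVE, NEGATIVE}:
        raise MatrixError(f"need both classes {POSITIVE!r} and {NEGATIVE!r}, got {classes}")
    pos = x[[l == POSITIVE for l in labels]]
    neg = x[[l == NEGATIVE for l in labels]]
    if len(pos) < 1 or len(neg) < 1:
        raise MatrixError("each class needs at least 1 sample")
    if len(pos) + len(neg) < 3:
        raise MatrixError("need at least 3 samples in total")
    m1, m0 = pos.mean(axis=0), neg.mean(axis=0)
    n1, n0 = len(pos), len(neg)
    # max(n-2, 1) keeps the pooled scatter defined when one class
    # contributes a single sample (leave-one-out folds of tiny designs)
    sw = ((pos - m1).T @ (pos - m1) + (neg - m0).T @ (neg - m0)) / max(n1 + n0 - 2, 1)
    dim = sw.shape[0]
    lam = ridge * np.trace(sw) / dim if np.trace(sw) > 0 else ridge
    try:
        cond = np.linalg.cond(sw)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        logger.warning("singular pooled covariance; applying ridge %.3g", lam)
        sw = sw + lam * np.eye(dim)
    w = np.linalg.solve(sw, m1 - m0)
    if np.allclose(w, 0):
        majority = POSITIVE if n1 >= n0 else NEGATIVE
        logger.warning("degenerate discriminant (identical class means); majority fallback to %r", majority)
        return LDAModel(weights=np.zeros(dim), threshold=0.0, degenerate_majority=majority)
    threshold = float(w @ (m1 + m0) / 2.0)
    if priors == "proportional":
        threshold -= math.log(n1 / n0)
    return LDAModel(weights=w, threshold=threshold)


def lda_score(model: LDAModel, score_vector: np.ndarray) -> float:
    """Continuous discriminant score w·x (higher → positive class)."""
    return float(np.asarray(score_vector, dtype=float) @ model.weights)


def lda_predict(model: LDAModel, score_vector: np.ndarray) -> str:
    if model.degenerate_majority is not None:
        return model.degenerate_majority
    return POSITIVE if lda_score(model, score_vector) > model.threshold else NEGATIVE


# -- metrics -----------------------------------------------------------------


@dataclass
class DiscriminationResult:
    """Held-out predictions, confusion table and diagnostic metrics.

    The confusion table is prediction × truth ordered
    [positive, negative] on both axes: [[TP, FP], [FN, TN]].
    """

    sample_ids: list[str]
    truths: list[str]
    predictions: list[str]
    scores: np.ndarray
    confusion: np.ndarray
    selection: FeatureSelection | None = None
    accuracy: float = float("nan")  # percent
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    auc: float = float("nan")
    fisher_p: float = float("nan")
    extras: dict = field(default_factory=dict)


def fisher_exact_one_sided(table, alternative: str = "greater") -> float:
    """One-sided Fisher exact p for a 2×2 table by full enumeration.

    With ``a`` the (0,0) cell and all margins fixed, ``"greater"`` (the
    default, testing positive association between row 0 and column 0)
    returns P(A ≥ a) under the hypergeometric null — so a table with the
    (0,0) cell at its minimum given the margins has p = 1.  ``"less"``
    returns P(A ≤ a).  Exact integer arithmetic via binomial coefficients.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("expected a 2×2 table")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)

    def pmf_num(k: int) -> int:
        return math.comb(r1, k) * math.comb(n - r1, c1 - k)

    if alternative == "greater":
        num = sum(pmf_num(k) for k in range(a, hi + 1))
    else:
        num = sum(pmf_num(k) for k in range(lo, a + 1))
    return num / denom


def auc_from_scores(scores, truths: list[str]) -> float:
    """Rank-statistic AUC: probability a random positive outranks a random
    negative, ties counted one half (midranks)."""
    scores = np.asarray(scores, dtype=float)
    is_pos = np.array([t == POSITIVE for t in truths])
    n1, n0 = int(is_pos.sum()), int((~is_pos).sum())
    if n1 == 0 or n0 == 0:
        raise MatrixError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[is_pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def classification_metrics(
    confusion,
    scores=None,
    truths: list[str] | None = None,
    result: DiscriminationResult | None = None,
) -> DiscriminationResult:
    """Compute accuracy (percent), sensitivity, specificity, AUC and the
    one-sided Fisher exact p from a prediction × truth confusion table
    ordered [[TP, FP], [FN, TN]].

    AUC requires per-sample ``scores`` and ``truths``; without them it is
    left NaN.
    """
    t = np.asarray(confusion, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2×2 confusion table")
    n = t.sum()
    if n == 0:
        raise ValueError("empty confusion table")
    tp, fp, fn, tn = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    if tp + fn == 0 or fp + tn == 0:
        raise MatrixError("a truth class is empty")
    if result is None:
        result = DiscriminationResult(
            sample_ids=[], truths=list(truths or []), predictions=[],
            scores=np.asarray(scores if scores is not None else []),
            confusion=t.astype(int),
        )
    result.accuracy = float((tp + tn) / n * 100.0)
    result.sensitivity = float(tp / (tp + fn))
    result.specificity = float(tn / (tn + fp))
    result.fisher_p = fisher_exact_one_sided(t.astype(int))
    if scores is not None and truths is not None and len(truths):
        result.auc = auc_from_scores(scores, truths)
    return result


# -- leave-one-out pipeline --------------------------------------------------


def loocv_classify(
    matrix: ExpressionMatrix, samples: SampleTable, cfg: FEConfig = FEConfig()
) -> DiscriminationResult:
    """Full PCA-feature-extraction + LDA pipeline, validated leave-one-out.

    The outlier-miRNA selection is computed once on all samples — it never
    sees the labels, so no label information leaks into the folds.  The
    sample embedding and the discriminant are refit on each fold's n−1
    training samples; the held-out sample is projected and scored.
    """
    if matrix.n_samples < 4:
        raise MatrixError("need at least 4 samples for leave-one-out")
    labels = samples.labels_for(matrix.sample_ids)
    for lab, name in ((POSITIVE, "positive"), (NEGATIVE, "negative")):
        if labels.count(lab) < 2:
            raise MatrixError(f"{name} class has fewer than 2 samples")

    embedding = pca_embed_mirnas(matrix)
    selection = select_outlier_mirnas(embedding, cfg)
    sub = matrix.subset_mirnas(selection.mirna_ids)
    x = sub.values.T  # samples × M

    preds: list[str] = []
    held_scores: list[float] = []
    n = sub.n_samples
    for i in range(n):
        train = [j for j in range(n) if j != i]
        train_labels = [labels[j] for j in train]
        if POSITIVE not in train_labels or NEGATIVE not in train_labels:
            raise MatrixError("a fold lost an entire class")
        train_matrix = sub.subset_samples([sub.sample_ids[j] for j in train])
        emb = pca_embed_samples(train_matrix, selection, cfg.m_prime)
        model = lda_fit(emb.scores, train_labels, priors=cfg.priors)
        held = emb.transform(x[i])[0]
        held_scores.append(lda_score(model, held))
        preds.append(lda_predict(model, held))

    confusion = np.zeros((2, 2), dtype=int)
    for p, t in zip(preds, labels):
        confusion[0 if p == POSITIVE else 1, 0 if t == POSITIVE else 1] += 1
    result = DiscriminationResult(
        sample_ids=list(sub.sample_ids),
        truths=labels,
        predictions=preds,
        scores=np.asarray(held_scores),
        confusion=confusion,
        selection=selection,
    )
    return classification_metrics(confusion, held_scores, labels, result=result)
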