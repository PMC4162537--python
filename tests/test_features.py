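import math
from fractions import Fraction

import numpy as np
import pytest

from mirdx.features import (
    FEConfig,
    MirnaEmbedding,
    auc_from_scores,
    classification_metrics,
    fisher_exact_one_sided,
    lda_fit,
    lda_predict,
    lda_score,
    loocv_classify,
    pca_embed_mirnas,
    pca_embed_samples,
    select_outlier_mirnas,
)
from mirdx.matrix import ExpressionMatrix, MatrixError, SampleRecord, SampleTable
from mirdx.normalize import zscore_by_sample


def _zmatrix(values, ids=None, samples=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"m{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, ids, samples, "ngs", "zscore")


# ---------------------------------------------------------------------------
# miRNA embedding


class TestMirnaEmbedding:
    def test_rank_one_gives_zero_pc2(self, rng):
        col = rng.normal(size=8)
        col = (col - col.mean()) / col.std(ddof=1)
        vals = np.column_stack([col, col, col])  # proportional sample columns
        emb = pca_embed_mirnas(_zmatrix(vals))
        np.testing.assert_allclose(emb.coords[:, 1], 0.0, atol=1e-10)

    def test_dominant_mirna_attains_max_distance(self, rng):
        # oracle: eigendecomposition of the centered covariance gives the
        # same score geometry; the row with 10x centered magnitude must win
        base = rng.normal(size=(20, 5)) * 0.1
        base[7] = 10.0 * rng.normal(size=5)
        x = base - base.mean(axis=0)
        vals = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)  # z-score columns
        m = _zmatrix(vals)
        emb = pca_embed_mirnas(m)
        d = np.linalg.norm(emb.coords, axis=1)
        assert np.argmax(d) == 7

        # independent oracle: PC scores from eigh of the covariance matrix
        xc = vals - vals.mean(axis=0)
        cov = xc.T @ xc
        w, v = np.linalg.eigh(cov)
        top2 = v[:, np.argsort(w)[::-1][:2]]
        oracle = xc @ top2
        np.testing.assert_allclose(
            np.sort(np.abs(emb.coords), axis=0),
            np.sort(np.abs(oracle), axis=0),
            atol=1e-8,
        )

    def test_row_permutation_equivariance(self, rng):
        vals = rng.normal(size=(12, 6))
        vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
        m = _zmatrix(vals)
        emb = pca_embed_mirnas(m)
        perm = list(rng.permutation(m.mirna_ids))
        emb_p = pca_embed_mirnas(m.subset_mirnas(perm))
        lookup = {mid: row for mid, row in zip(emb.mirna_ids, emb.coords)}
        for mid, row in zip(emb_p.mirna_ids, emb_p.coords):
            np.testing.assert_allclose(np.abs(row), np.abs(lookup[mid]), atol=1e-8)

    def test_requires_zscore_scale(self, small_counts):
        with pytest.raises(MatrixError, match="z-scored"):
            pca_embed_mirnas(small_counts)

    def test_too_small(self):
        with pytest.raises(MatrixError):
            pca_embed_mirnas(_zmatrix(np.ones((2, 3))))


class TestOutlierSelection:
    def _embedding(self):
        return MirnaEmbedding(
            mirna_ids=["A", "B", "C"],
            coords=np.array([[3.0, 4.0], [1.0, 0.0], [0.0, 2.0]]),
            explained_variance=np.array([1.0, 1.0]),
        )

    def test_euclidean_ranking(self):
        sel = select_outlier_mirnas(self._embedding(), FEConfig(m_select=2))
        assert sel.mirna_ids == ["A", "C"]
        np.testing.assert_allclose(sel.distances, [5.0, 2.0])

    def test_select_all(self):
        sel = select_outlier_mirnas(self._embedding(), FEConfig(m_select=3))
        assert set(sel.mirna_ids) == {"A", "B", "C"}
        assert list(sel.distances) == sorted(sel.distances, reverse=True)

    def test_tie_breaks_lexicographically(self):
        emb = MirnaEmbedding(
            mirna_ids=["zz", "aa", "top"],
            coords=np.array([[0.0, 2.0], [2.0, 0.0], [5.0, 0.0]]),
            explained_variance=np.array([1.0, 1.0]),
        )
        sel = select_outlier_mirnas(emb, FEConfig(m_select=2))
        assert sel.mirna_ids == ["top", "aa"]

    def test_m_too_large(self):
        with pytest.raises(MatrixError):
            select_outlier_mirnas(self._embedding(), FEConfig(m_select=4))

    def test_sign_invariance_of_selection(self):
        emb = self._embedding()
        flipped = MirnaEmbedding(
            mirna_ids=emb.mirna_ids,
            coords=emb.coords * np.array([-1.0, 1.0]),
            explained_variance=emb.explained_variance,
        )
        a = select_outlier_mirnas(emb, FEConfig(m_select=2))
        b = select_outlier_mirnas(flipped, FEConfig(m_select=2))
        assert a.mirna_ids == b.mirna_ids
        np.testing.assert_allclose(a.distances, b.distances)


class TestSampleEmbedding:
    def _selection(self, ids):
        return type("S", (), {"mirna_ids": ids})()

    def test_duplicated_samples_identical_scores(self, rng):
        vals = rng.normal(size=(5, 4))
        vals[:, 3] = vals[:, 0]  # duplicate sample column
        m = _zmatrix(vals)
        from mirdx.features import FeatureSelection

        sel = FeatureSelection(m.mirna_ids, np.zeros((5, 2)), np.zeros(5))
        emb = pca_embed_samples(m, sel, 2)
        np.testing.assert_allclose(emb.scores[0], emb.scores[3], atol=1e-10)

    def test_full_rank_isometry(self, rng):
        vals = rng.normal(size=(6, 5))
        m = _zmatrix(vals)
        from mirdx.features import FeatureSelection

        sel = FeatureSelection(m.mirna_ids, np.zeros((6, 2)), np.zeros(6))
        rank = m.n_samples - 1
        emb = pca_embed_samples(m, sel, rank)
        x = vals.T
        for i in range(5):
            for j in range(i + 1, 5):
                d_data = np.linalg.norm(x[i] - x[j])
                d_score = np.linalg.norm(emb.scores[i] - emb.scores[j])
                assert d_score == pytest.approx(d_data, abs=1e-8)

    def test_m_prime_exceeds_rank(self, rng):
        m = _zmatrix(rng.normal(size=(6, 3)))
        from mirdx.features import FeatureSelection

        sel = FeatureSelection(m.mirna_ids, np.zeros((6, 2)), np.zeros(6))
        with pytest.raises(MatrixError, match="rank"):
            pca_embed_samples(m, sel, 3)

    def test_separated_clusters_separate_on_pc1(self, rng):
        # planted shift of 6 (>= 3 SD of unit noise) between two groups
        a = rng.normal(0, 1, size=(8, 10))
        b = rng.normal(0, 1, size=(8, 6)) + 6.0
        m = _zmatrix(np.hstack([a, b]))
        from mirdx.features import FeatureSelection

        sel = FeatureSelection(m.mirna_ids, np.zeros((8, 2)), np.zeros(8))
        emb = pca_embed_samples(m, sel, 2)
        g1, g2 = emb.scores[:10, 0], emb.scores[10:, 0]
        assert max(g1.min(), g2.min()) > min(g1.max(), g2.max()) or max(
            g2.min(), g1.min()
        ) > min(g2.max(), g1.max())
        lo = min(g1.max(), g2.max())
        hi = max(g1.min(), g2.min())
        assert hi > lo  # no overlap on PC1


# ---------------------------------------------------------------------------
# LDA


class TestLDA:
    def test_symmetric_1d(self, rng):
        x = np.concatenate([rng.normal(-1, 0.5, 40), rng.normal(1, 0.5, 40)])[:, None]
        labels = ["control"] * 40 + ["tumor"] * 40
        model = lda_fit(x, labels)
        # threshold at the midpoint of projected means ~ 0
        mid = model.threshold / np.linalg.norm(model.weights)
        assert abs(mid) < 0.3
        assert lda_predict(model, np.array([2.0])) == "tumor"
        assert lda_predict(model, np.array([-2.0])) == "control"

    def test_identical_means_majority_fallback(self, caplog):
        x = np.array([[0.0], [0.0], [0.0], [0.0], [0.0]])
        labels = ["tumor", "tumor", "tumor", "control", "control"]
        with caplog.at_level("WARNING"):
            model = lda_fit(x, labels)
        assert model.degenerate_majority == "tumor"
        assert lda_predict(model, np.array([5.0])) == "tumor"
        assert "degenerate" in caplog.text

    @staticmethod
    def _angle_to_x_axis(n_per_class, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n_per_class, 2))
        b = rng.normal(0, 1, size=(n_per_class, 2)) + np.array([3.0, 0.0])
        model = lda_fit(
            np.vstack([a, b]), ["control"] * n_per_class + ["tumor"] * n_per_class
        )
        w = model.weights / np.linalg.norm(model.weights)
        return np.degrees(np.arccos(abs(w[0])))

    def test_direction_matches_closed_form(self):
        # isotropic 2-D Gaussians, means (0,0) and (3,0): the population
        # Fisher direction is exactly the x-axis; at n=200 the estimate's
        # mean angular error stays below 5 degrees over 20 seeds
        angles = [self._angle_to_x_axis(100, seed) for seed in range(20)]
        assert np.mean(angles) < 5.0

    def test_direction_consistency_large_n(self):
        angles = [self._angle_to_x_axis(5000, seed) for seed in range(5)]
        assert max(angles) < 2.0

    def test_single_class_error(self):
        with pytest.raises(MatrixError):
            lda_fit(np.zeros((4, 1)), ["tumor"] * 4)

    def test_single_member_class_allowed(self):
        x = np.array([[0.0], [0.1], [3.0]])
        model = lda_fit(x, ["control", "control", "tumor"])
        assert lda_predict(model, np.array([3.0])) == "tumor"


# ---------------------------------------------------------------------------
# metrics + Fisher


def _fisher_oracle(table) -> float:
    """Brute force: enumerate every 2x2 table with the observed margins,
    probability from the factorial formula (exact rational arithmetic)."""
    t = np.asarray(table, dtype=int)
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    r1, r2, c1, c2, n = a + b, c + d, a + c, b + d, a + b + c + d
    f = math.factorial

    def prob(aa):
        bb, cc, dd = r1 - aa, c1 - aa, r2 - (c1 - aa)
        if min(bb, cc, dd) < 0:
            return Fraction(0)
        return Fraction(f(r1) * f(r2) * f(c1) * f(c2), f(n) * f(aa) * f(bb) * f(cc) * f(dd))

    return float(sum(prob(aa) for aa in range(a, n + 1)))


class TestFisherExact:
    def test_printed_confusion_table(self):
        p = fisher_exact_one_sided([[12, 0], [2, 6]])
        assert p == pytest.approx(91 / 125970, rel=1e-12)
        assert p == pytest.approx(7.2239e-4, abs=1e-7)

    def test_whole_support_p_one(self):
        # (0,0) cell at its minimum given margins -> lower tail covers all
        assert fisher_exact_one_sided([[0, 5], [5, 0]]) == pytest.approx(1.0)

    def test_single_most_extreme_table(self):
        p = fisher_exact_one_sided([[14, 0], [0, 6]])
        assert p == pytest.approx(1 / math.comb(20, 14), rel=1e-12)

    def test_negative_entries(self):
        with pytest.raises(ValueError):
            fisher_exact_one_sided([[1, -1], [0, 2]])

    def test_exhaustive_against_brute_force_oracle(self):
        # every 2x2 table with positive margins and n <= 30
        checked = 0
        for n in range(2, 31):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        assert fisher_exact_one_sided(t) == pytest.approx(
                            _fisher_oracle(t), rel=1e-10
                        ), t
                        checked += 1
        assert checked > 10_000


class TestMetrics:
    def test_table2_accuracy(self):
        res = classification_metrics([[12, 0], [2, 6]])
        assert res.accuracy == pytest.approx(90.0)

    def test_table2_fisher(self):
        res = classification_metrics([[12, 0], [2, 6]])
        assert res.fisher_p == pytest.approx(91 / 125970, rel=1e-12)

    def test_perfect_classifier(self):
        scores = np.array([1.0] * 14 + [-1.0] * 6)
        truths = ["tumor"] * 14 + ["control"] * 6
        res = classification_metrics([[14, 0], [0, 6]], scores, truths)
        assert res.accuracy == pytest.approx(100.0)
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(1.0)

    def test_auc_negation_symmetry(self, rng):
        scores = rng.normal(size=20)
        truths = ["tumor"] * 12 + ["control"] * 8
        a = auc_from_scores(scores, truths)
        b = auc_from_scores(-scores, truths)
        assert a + b == pytest.approx(1.0)

    def test_auc_ties_half(self):
        assert auc_from_scores([1.0, 1.0], ["tumor", "control"]) == pytest.approx(0.5)

    def test_confusion_sums(self):
        res = classification_metrics([[12, 0], [2, 6]])
        assert res.confusion.sum() == 20
        assert res.accuracy == pytest.approx(res.confusion.trace() / 20 * 100)

    def test_empty_truth_class_error(self):
        with pytest.raises(MatrixError):
            classification_metrics([[5, 0], [3, 0]])


# ---------------------------------------------------------------------------
# LOOCV pipeline


def _make_table(sample_ids, labels):
    return SampleTable([SampleRecord(s, l) for s, l in zip(sample_ids, labels)])


class TestLOOCV:
    def test_minimal_2v2(self, rng):
        vals = rng.normal(size=(6, 4))
        vals[:3, :2] += 4.0  # separate the first two samples
        vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
        m = _zmatrix(vals)
        table = _make_table(m.sample_ids, ["tumor", "tumor", "control", "control"])
        res = loocv_classify(m, table, FEConfig(m_select=4, m_prime=2))
        assert res.confusion.sum() == 4
        assert len(res.predictions) == 4

    def test_separated_synthetic_high_accuracy(self):
        from mirdx.cli import prepare_classification_matrix
        from mirdx.simulate import GeneratorConfig, simulate_dataset

        hits = 0
        for seed in range(5):
            ds = simulate_dataset(GeneratorConfig(seed=seed))
            z = prepare_classification_matrix(ds.counts)
            res = loocv_classify(z, ds.samples, FEConfig())
            if res.accuracy >= 90.0:
                hits += 1
        assert hits >= 4

    def test_selection_is_label_free(self, rng):
        from mirdx.simulate import GeneratorConfig, simulate_dataset
        from mirdx.cli import prepare_classification_matrix

        ds = simulate_dataset(GeneratorConfig(seed=0, n_mirna=80))
        z = prepare_classification_matrix(ds.counts)
        t1 = ds.samples
        perm = list(rng.permutation(t1.labels_for(z.sample_ids)))
        t2 = _make_table(z.sample_ids, perm)
        r1 = loocv_classify(z, t1, FEConfig(m_select=5))
        r2 = loocv_classify(z, t2, FEConfig(m_select=5))
        assert r1.selection.mirna_ids == r2.selection.mirna_ids

    def test_too_few_samples(self, rng):
        m = _zmatrix(rng.normal(size=(5, 3)))
        table = _make_table(m.sample_ids, ["tumor", "tumor", "control"])
        with pytest.raises(MatrixError):
            loocv_classify(m, table, FEConfig(m_select=3))

    def test_deterministic(self):
        from mirdx.cli import prepare_classification_matrix
        from mirdx.simulate import GeneratorConfig, simulate_dataset

        ds = simulate_dataset(GeneratorConfig(seed=1, n_mirna=100))
        z = prepare_classification_matrix(ds.counts)
        r1 = loocv_classify(z, ds.samples, FEConfig())
        r2 = loocv_classify(z, ds.samples, FEConfig())
        assert r1.predictions == r2.predictions
        np.testing.assert_array_equal(r1.scores, r2.scores)
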