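import numpy as np
import pytest
from sklearn.base import clone

from udscreen.scoring import (
    UglyDucklingScorer,
    cosine_distance,
    median_embedding,
    top_k,
    ud_scores,
)


class TestMedianEmbedding:
    def test_single_row(self):
        np.testing.assert_array_equal(median_embedding([[3.0, 1.0]]), [3.0, 1.0])

    def test_coordinate_wise(self):
        E = [[0, 0], [1, 1], [2, 2]]
        np.testing.assert_array_equal(median_embedding(E), [1, 1])

    def test_even_count_midpoint(self):
        np.testing.assert_array_equal(median_embedding([[0, 2], [2, 0]]), [1, 1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_embedding(np.empty((0, 4)))


class TestCosineDistance:
    def test_identical(self):
        assert cosine_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_opposite(self):
        assert cosine_distance([1, 1], [-1, -1]) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0, 0], [1, 0])


# rows chosen so the coordinate-wise median is (1,0,0) and the cosine
# distances from it are 0, 0.2 and 0.4: cos = 1/sqrt(1+y^2) -> y = 0.75
# gives cos 0.8, z = 4/3 gives cos 0.6.
HAND_MATRIX = np.array(
    [
        [1.0, 0.0, 0.0],
        [1.0, 0.75, 0.0],
        [1.0, 0.0, 4.0 / 3.0],
    ]
)


class TestUDScores:
    def test_identical_rows_all_zero(self):
        table = ud_scores(np.ones((4, 3)))
        assert (table["raw_distance"] == 0).all()
        assert (table["score"] == 0).all()

    def test_hand_worked_scores(self):
        table = ud_scores(HAND_MATRIX)
        np.testing.assert_allclose(sorted(table["raw_distance"]), [0.0, 0.2, 0.4], atol=1e-12)
        np.testing.assert_allclose(sorted(table["score"]), [0.0, 0.5, 1.0], atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(20, 8)) + 2.0
        t1, t2 = ud_scores(E), ud_scores(E * 3.0)
        np.testing.assert_allclose(t1["score"], t2["score"], atol=1e-12)
        assert list(t1["rank"]) == list(t2["rank"])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        E = rng.normal(size=(15, 6)) + 1.5
        ids = [f"L{i}" for i in range(15)]
        perm = rng.permutation(15)
        t1 = ud_scores(E, ids).set_index("lesion_id")
        t2 = ud_scores(E[perm], [ids[i] for i in perm]).set_index("lesion_id")
        np.testing.assert_allclose(
            t1["score"].sort_index(), t2["score"].sort_index(), atol=1e-12
        )

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(2)
        table = ud_scores(rng.normal(size=(30, 5)) + 2.0)
        assert sorted(table["rank"]) == list(range(1, 31))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            ud_scores(np.ones((1, 4)))


class TestTopK:
    def test_truncation_when_fewer_lesions(self):
        table = ud_scores(HAND_MATRIX, lesion_ids=["a", "b", "c"])
        assert len(top_k(table, 10)) == 3

    def test_matches_descending_sort(self):
        rng = np.random.default_rng(3)
        E = rng.normal(size=(25, 7)) + 2.0
        table = ud_scores(E)
        expected = list(
            table.sort_values(["score", "lesion_id"], ascending=[False, True])[
                "lesion_id"
            ][:10]
        )
        assert top_k(table, 10) == expected

    def test_k1_is_argmax(self):
        table = ud_scores(HAND_MATRIX, lesion_ids=["a", "b", "c"])
        (best,) = top_k(table, 1)
        assert best == table.loc[table["score"].idxmax(), "lesion_id"]


class TestPlantedOutlierRecovery:
    def make_embeddings(self, rng, n_inliers=200, n_outliers=5, dim=32):
        base = np.ones(dim)
        inliers = base + rng.normal(0, 0.05, size=(n_inliers, dim))
        # orthogonal-ish displacement at >= 5x inlier dispersion
        outliers = []
        for _ in range(n_outliers):
            direction = rng.normal(size=dim)
            direction -= direction @ base / (base @ base) * base
            direction /= np.linalg.norm(direction)
            outliers.append(base + 6 * 0.05 * np.sqrt(dim) * direction)
        return np.vstack([inliers, np.array(outliers)])

    def test_outliers_land_in_top_10(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            E = self.make_embeddings(rng)
            table = ud_scores(E)
            top = set(top_k(table, 10))
            if all(200 + i in top for i in range(5)):
                hits += 1
        assert hits >= 19


class TestScorerEstimator:
    def test_fit_attributes_and_sklearn_protocol(self):
        rng = np.random.default_rng(4)
        E = rng.normal(size=(40, 6)) + 2.0
        scorer = UglyDucklingScorer(top_k=5)
        assert clone(scorer).get_params() == scorer.get_params()
        scorer.fit(E)
        assert len(scorer.top_k_ids_) == 5
        assert scorer.score_table_.shape[0] == 40
        assert len(scorer.ranking_) == 40
        d = scorer.score_samples(E[:3])
        np.testing.assert_allclose(
            d, scorer.score_table_["raw_distance"][:3], atol=1e-12
        )

    def test_medoid_reference_is_a_row(self):
        rng = np.random.default_rng(5)
        E = rng.normal(size=(12, 4)) + 3.0
        scorer = UglyDucklingScorer(reference="medoid").fit(E)
        assert any(np.allclose(scorer.reference_embedding_, row) for row in E)
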