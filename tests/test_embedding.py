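import numpy as np
import pytest

from udscreen.embedding import (
    DESK_SCALE,
    FULL_SCALE,
    EmbedderConfig,
    HandcraftedFeatureEmbedder,
    SelfDistillationEmbedder,
    build_views,
    ranking_converged,
    stopping_epoch,
)


def lesion_patch(rng, size=32, color=(0.4, 0.28, 0.22), skin=(0.85, 0.7, 0.6), r_frac=0.3):
    """Round synthetic lesion patch on a skin background."""
    patch = np.empty((size, size, 3))
    patch[:] = skin
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - size / 2) ** 2 + (xx - size / 2) ** 2 <= (r_frac * size) ** 2
    patch[mask] = color
    patch += rng.normal(0, 0.01, patch.shape)
    return np.clip(patch, 0, 1)


def patient_patches(rng, n_common=20, n_outliers=2, size=32):
    patches = [lesion_patch(rng, size) for _ in range(n_common)]
    patches += [
        lesion_patch(rng, size, color=(0.75, 0.15, 0.35), r_frac=0.42)
        for _ in range(n_outliers)
    ]
    return patches


FAST = dict(
    view_size=12, hidden_dim=32, embedding_dim=16, projection_dim=16,
    min_epochs=3, max_epochs=5, check_interval_epochs=1, random_state=7,
)


class TestRankingConverged:
    @pytest.mark.parametrize(
        "prev, cur, expected",
        [
            (["a", "b", "c"], ["a", "b", "c"], True),
            (["a", "b", "c"], ["a", "c", "b"], False),  # order-sensitive
            (["a", "b"], ["a", "b", "c"], False),
            ([], [], True),
        ],
    )
    def test_cases(self, prev, cur, expected):
        assert ranking_converged(prev, cur) is expected


class TestStoppingRule:
    def test_degenerate_one_epoch_schedule(self):
        epoch, reason = stopping_epoch(lambda e: ["a"], 1, 1, 1)
        assert (epoch, reason) == (1, "max_epochs")

    def test_converges_at_first_repeat(self):
        # rankings differ at 200 and 210, repeat at 220
        seq = {200: ["a", "b"], 210: ["b", "a"], 220: ["b", "a"]}
        epoch, reason = stopping_epoch(lambda e: seq[e], 200, 300, 10)
        assert (epoch, reason) == (220, "converged")

    def test_never_stops_before_min_epochs(self):
        calls = []

        def ranking(e):
            calls.append(e)
            return ["a"]

        epoch, reason = stopping_epoch(ranking, 50, 80, 10)
        assert min(calls) == 50
        assert (epoch, reason) == (60, "converged")

    def test_unstable_ranking_hits_cap(self):
        epoch, reason = stopping_epoch(lambda e: [f"x{e}"], 10, 40, 5)
        assert (epoch, reason) == (40, "max_epochs")


class TestBuildViews:
    def test_no_augmentation_gives_copies(self):
        config = EmbedderConfig(
            view_size=24, brightness_jitter_strength=0.0, color_jitter_multiplier=0.0,
            global_scale=(1.0, 1.0), local_scale=(1.0, 1.0),
        )
        patch = np.random.default_rng(0).uniform(size=(24, 24, 3))
        views = build_views(patch, config, np.random.default_rng(1))
        assert len(views) == config.n_global_views + config.n_local_views
        for v in views:
            np.testing.assert_array_equal(v, patch)

    def test_deterministic_under_seed(self):
        config = EmbedderConfig(view_size=16)
        patch = np.random.default_rng(2).uniform(size=(32, 32, 3))
        v1 = build_views(patch, config, np.random.default_rng(99))
        v2 = build_views(patch, config, np.random.default_rng(99))
        for a, b in zip(v1, v2):
            np.testing.assert_array_equal(a, b)

    def test_stronger_color_jitter_spreads_channel_means(self):
        patch = np.full((16, 16, 3), 0.5)
        means = {}
        for mult in (1.0, 10.0):
            config = EmbedderConfig(
                view_size=16, brightness_jitter_strength=0.0,
                color_jitter_multiplier=mult,
                global_scale=(1.0, 1.0), local_scale=(1.0, 1.0),
            )
            rng = np.random.default_rng(3)
            vals = []
            for _ in range(300):
                for v in build_views(patch, config, rng):
                    vals.append(v.mean(axis=(0, 1)))
            means[mult] = np.std(np.array(vals), axis=0)
        assert (means[10.0] > means[1.0]).all()


class TestSelfDistillationEmbedder:
    def test_too_few_patches_rejected(self, rng):
        patches = patient_patches(rng, n_common=5, n_outliers=0)
        with pytest.raises(ValueError, match="at least"):
            SelfDistillationEmbedder(**FAST).fit(patches)

    def test_training_is_reproducible(self, rng):
        patches = patient_patches(rng, n_common=12, n_outliers=1)
        e1 = SelfDistillationEmbedder(**FAST).fit(patches)
        e2 = SelfDistillationEmbedder(**FAST).fit(patches)
        assert e1.training_log_.loss_per_epoch == e2.training_log_.loss_per_epoch
        assert e1.training_log_.ranking_checks == e2.training_log_.ranking_checks
        np.testing.assert_array_equal(e1.transform(patches), e2.transform(patches))

    def test_inference_is_deterministic_and_duplicate_consistent(self, rng):
        patches = patient_patches(rng, n_common=12, n_outliers=1)
        emb = SelfDistillationEmbedder(**FAST).fit(patches)
        E1 = emb.transform(patches)
        E2 = emb.transform(patches)
        np.testing.assert_array_equal(E1, E2)
        dup = emb.transform([patches[0], patches[0]])
        np.testing.assert_array_equal(dup[0], dup[1])

    def test_stop_epoch_within_schedule(self, rng):
        patches = patient_patches(rng, n_common=14, n_outliers=1)
        emb = SelfDistillationEmbedder(**FAST).fit(patches)
        assert 3 <= emb.stop_epoch_ <= 5
        if emb.stop_reason_ == "converged":
            checks = [e for e, _ in emb.training_log_.ranking_checks]
            assert emb.stop_epoch_ in checks

    def test_outliers_separate_from_median(self, rng):
        """Color/shape outliers must sit farther from the median embedding."""
        from udscreen.scoring import cosine_distance, median_embedding

        patches = patient_patches(rng, n_common=30, n_outliers=5)
        emb = SelfDistillationEmbedder(
            view_size=12, hidden_dim=64, embedding_dim=32, projection_dim=32,
            min_epochs=8, max_epochs=12, check_interval_epochs=2, random_state=0,
        ).fit(patches)
        E = emb.transform(patches)
        med = median_embedding(E)
        d = np.array([cosine_distance(row, med) for row in E])
        assert d[30:].mean() > d[:30].mean()

    def test_profiles_match_contracts(self):
        assert FULL_SCALE.min_epochs == 200 and FULL_SCALE.max_epochs == 300
        assert FULL_SCALE.patch_size == 224
        assert DESK_SCALE.patch_size == 64 and DESK_SCALE.max_epochs == 30
        est = DESK_SCALE.estimator()
        assert est.min_epochs == 20 and est.check_interval_epochs == 2


class TestHandcraftedFeatureEmbedder:
    def test_deterministic_and_sklearn_compatible(self, rng):
        from sklearn.base import clone

        patches = patient_patches(rng, n_common=10, n_outliers=2)
        emb = HandcraftedFeatureEmbedder()
        clone(emb)  # must be clonable
        E1 = emb.fit(patches).transform(patches)
        E2 = HandcraftedFeatureEmbedder().fit(patches).transform(patches)
        np.testing.assert_array_equal(E1, E2)
        assert E1.shape[0] == 12

    def test_outliers_separate(self, rng):
        from udscreen.scoring import top_k, ud_scores

        patches = patient_patches(rng, n_common=40, n_outliers=4)
        E = HandcraftedFeatureEmbedder().fit(patches).transform(patches)
        top = set(top_k(ud_scores(E), 4))
        assert top == {40, 41, 42, 43}
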