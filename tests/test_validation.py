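import numpy as np
import pytest

from udscreen.geometry import BoundingBox
from udscreen.validation import (
    EvaluationConfig,
    SelectionRecord,
    group_summaries,
    majority_selection,
    match_boxes_by_iou,
    match_selections_to_lesions,
    sensitivity,
    top_u_ai_sensitivity,
    truncate_selection,
)


def record(picks, group="derm>10y", part="p1", patient="img1", conf=4, ai=False):
    return SelectionRecord(part, group, patient, list(picks), conf, ai)


class TestSelectionRecord:
    def test_duplicate_picks_rejected(self):
        with pytest.raises(ValueError):
            record(["a", "a"])

    def test_confidence_range_enforced(self):
        with pytest.raises(ValueError):
            record(["a"], conf=6)


class TestMatching:
    def detected(self):
        return [
            BoundingBox(0, 0, 10, 10, lesion_id="A"),
            BoundingBox(50, 50, 60, 60, lesion_id="B"),
        ]

    def test_identity_mapping(self):
        drawn = [BoundingBox(0, 0, 10, 10), BoundingBox(50, 50, 60, 60)]
        assert match_selections_to_lesions(drawn, self.detected(), 0.3) == ["A", "B"]

    def test_no_overlap_dropped(self):
        assert match_selections_to_lesions(
            [BoundingBox(200, 200, 210, 210)], self.detected(), 0.3
        ) == []

    def test_highest_iou_wins(self):
        detected = [
            BoundingBox(0, 0, 10, 10, lesion_id="big"),
            BoundingBox(0, 0, 30, 10, lesion_id="small_overlap"),
        ]
        drawn = [BoundingBox(0, 0, 11, 10)]
        assert match_selections_to_lesions(drawn, detected, 0.1) == ["big"]

    def test_box_mapping_is_one_to_one(self):
        source = [
            BoundingBox(0, 0, 10, 10, lesion_id="t1"),
            BoundingBox(1, 0, 11, 10, lesion_id="t2"),
        ]
        mapping = match_boxes_by_iou(source, self.detected(), 0.3)
        assert mapping == {"t1": "A"} or mapping == {"t2": "A"}


class TestTruncation:
    def test_rank_20_cap(self):
        rec = record([f"l{i}" for i in range(25)])
        assert truncate_selection(rec, 20).ordered_lesion_ids == [
            f"l{i}" for i in range(20)
        ]

    def test_short_selection_unchanged(self):
        rec = record(["a", "b", "c"])
        assert truncate_selection(rec, 20).ordered_lesion_ids == ["a", "b", "c"]

    def test_excluded_pick_removed_and_later_shift_up(self):
        rec = record(["a", "b", "c", "d"])
        out = truncate_selection(rec, 3, excluded_lesions={"c"})
        assert out.ordered_lesion_ids == ["a", "b", "d"]


class TestSensitivity:
    @pytest.mark.parametrize(
        "selected, reference, expected",
        [
            ({"a", "b", "c"}, {"a", "b"}, 1.0),
            ({"x"}, {"a", "b"}, 0.0),
            ({"a", "b", "c"}, {"a", "b", "c", "d"}, 0.75),
        ],
    )
    def test_values(self, selected, reference, expected):
        assert sensitivity(selected, reference) == pytest.approx(expected)

    def test_empty_reference_undefined(self):
        assert sensitivity({"a"}, set()) is None


class TestMajoritySelection:
    def test_unanimous(self):
        recs = [record(["a", "b"], part=f"e{i}") for i in range(3)]
        assert majority_selection(recs) == {"a", "b"}

    def test_single_vote_excluded(self):
        recs = [
            record(["a", "b"], part="e1"),
            record(["a"], part="e2"),
            record(["a"], part="e3"),
        ]
        assert majority_selection(recs) == {"a"}

    def test_pairwise_overlap_counts(self):
        recs = [
            record(["A", "B"], part="e1"),
            record(["B", "C"], part="e2"),
            record(["C", "A"], part="e3"),
        ]
        assert majority_selection(recs) == {"A", "B", "C"}

    def test_wrong_group_rejected(self):
        with pytest.raises(ValueError):
            majority_selection([record(["a"], group="student")])

    def test_assisted_records_rejected(self):
        with pytest.raises(ValueError):
            majority_selection([record(["a"], ai=True)])


class TestTopUSensitivity:
    def test_exact_match(self):
        rec = record(["a", "b", "c"])
        assert top_u_ai_sensitivity(["a", "b", "c"], rec, 3) == 1.0

    def test_undetected_picks_count_as_fn(self):
        # 4 picks: 2 in AI top-10, 1 ranked below, 1 never detected
        ai = ["p1", "p2"] + [f"f{i}" for i in range(8)] + ["p3"]
        rec = record(["p1", "p2", "p3", "ghost"])
        assert top_u_ai_sensitivity(ai, rec, 10) == pytest.approx(0.5)

    def test_exhaustive_prefix(self):
        ai = ["a", "b", "c", "d"]
        rec = record(["d", "a"])
        assert top_u_ai_sensitivity(ai, rec, 99) == 1.0

    def test_monotone_in_u(self):
        rng = np.random.default_rng(0)
        ai = [f"l{i}" for i in range(30)]
        picks = list(rng.choice(ai, size=8, replace=False))
        rec = record(picks)
        vals = [top_u_ai_sensitivity(ai, rec, u) for u in range(1, 31)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestGroupSummaries:
    def toy_cohort(self):
        """3 experts x 2 images, everyone picks everything the AI ranks high."""
        lesions = [f"l{i}" for i in range(12)]
        records = []
        for img in ("img1", "img2"):
            for e in range(3):
                records.append(
                    record(lesions[:6], part=f"e{e}", patient=img, conf=5)
                )
        rankings = {"img1": lesions, "img2": lesions}
        return records, rankings

    def test_perfect_agreement_gives_unit_sensitivity(self):
        records, rankings = self.toy_cohort()
        report = group_summaries(records, rankings, EvaluationConfig(top_u_max=12))
        cell = report["groups"]["derm>10y|no_ai"]
        assert cell["majority_sensitivity_mean"] == 1.0
        assert cell["top_k_ai_sensitivity_mean"] == 1.0
        assert report["ai"]["top_k_sensitivity_vs_majority_mean"] == 1.0

    def test_single_record_iqr_zero(self):
        rec = [record(["a", "b"])]
        report = group_summaries(rec, {"img1": ["a", "b", "c"]})
        cell = report["groups"]["derm>10y|no_ai"]
        assert cell["top_k_ai_sensitivity_iqr"] == 0.0
        # one expert cannot form a 2-of-3 majority: reference undefined
        assert np.isnan(cell["majority_sensitivity_mean"])

    def test_empty_majority_skipped_not_zero(self):
        # no two experts agree on anything -> reference empty -> mean is nan
        records = [
            record(["a"], part="e1"),
            record(["b"], part="e2"),
            record(["c"], part="e3"),
        ]
        report = group_summaries(records, {"img1": ["a", "b", "c"]})
        assert np.isnan(
            report["groups"]["derm>10y|no_ai"]["majority_sensitivity_mean"]
        )

    def test_confidence_deltas_paired(self):
        records = [
            record(["a"], part="p", conf=3, ai=False),
            record(["a", "b"], part="p", conf=5, ai=True),
        ]
        report = group_summaries(records, {"img1": ["a", "b"]})
        delta = report["groups"]["derm>10y|delta"]
        assert delta["confidence_change_mean"] == 2.0
        assert delta["selected_count_change_mean"] == 1.0

    def test_simulated_cohort_recovers_pick_rates(self):
        """Summary means track the generating behavior probabilities."""
        from udscreen.synthetic import (
            GroupBehavior,
            PhantomConfig,
            generate_phantom,
            generate_selections,
        )

        behaviors = {
            "derm>10y": GroupBehavior(0.95, 0.02),
            "student": GroupBehavior(0.60, 0.10),
        }
        cohort = ((3, "derm>10y"), (3, "student"))
        all_records, rankings = [], {}
        n_images = 30
        for s in range(n_images):
            config = PhantomConfig(
                image_height=256, image_width=256, n_common=15, n_outliers=5,
                min_lesion_gap=20.0, n_shadow_regions=0, seed=s,
            )
            _, truth = generate_phantom(config)
            pid = f"img{s}"
            all_records += generate_selections(
                truth, behaviors, cohort, patient_id=pid, seed=1000 + s
            )
            # AI ranking: outliers first (a perfect scorer), then common
            ids = [b.lesion_id for b in truth.boxes]
            out = [i for i, o in zip(ids, truth.is_outlier) if o]
            rest = [i for i in ids if i not in out]
            rankings[pid] = out + rest
        report = group_summaries(
            all_records, rankings, EvaluationConfig(ai_top_k=5, top_u_max=5)
        )
        # students pick ~60% of the 5 outliers the AI ranks top-5, plus some
        # common lesions the AI ranks below: top-5 AI sensitivity per record is
        # roughly p_out*5 / (p_out*5 + p_common*15)
        stu = report["groups"]["student|no_ai"]["top_k_ai_sensitivity_mean"]
        expected = 0.60 * 5 / (0.60 * 5 + 0.10 * 15)
        assert abs(stu - expected) < 0.10
        exp = report["groups"]["derm>10y|no_ai"]["top_k_ai_sensitivity_mean"]
        assert exp > stu
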