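import numpy as np
import pytest

from cmrqc.errors import AlignmentError
from cmrqc.geom_metrics import SliceComparison
from cmrqc.multilevel import (
    ReaderPair,
    classify_slice_positions,
    compare_stacks,
    decision_metrics,
    dice_average,
    stratified_metrics,
)
from cmrqc.synthetic import ErrorModel, PhantomParams, apply_error_model, generate_phantom

from .conftest import single_structure_stack


def record(decision, dice, slice_index=0, hd=None, vol=0.0):
    return SliceComparison(
        slice_index=slice_index,
        phase="ED",
        entity="lv_endo",
        decision=decision,
        dice_pct=dice,
        hausdorff_mm=hd,
        area_a_mm2=0.0,
        area_b_mm2=0.0,
        volume_diff_ml=vol,
        abs_volume_diff_ml=abs(vol),
    )


class TestClassifySlicePositions:
    def test_expert_1_to_8_reader_2_to_9(self):
        expert = single_structure_stack(range(1, 9))
        reader = single_structure_stack(range(2, 10), reader_id="ai")
        labels = classify_slice_positions(expert, reader, "lv_endo", "ED")
        assert {s for s, p in labels.items() if p == "basal"} == {8, 9}
        assert {s for s, p in labels.items() if p == "apical"} == {1}
        assert {s for s, p in labels.items() if p == "midventricular"} == set(range(2, 8))
        assert labels[0] == "unassigned"

    def test_expert_3_to_8_reader_1_to_9(self):
        expert = single_structure_stack(range(3, 9))
        reader = single_structure_stack(range(1, 10), reader_id="ai")
        labels = classify_slice_positions(expert, reader, "lv_endo", "ED")
        assert {s for s, p in labels.items() if p == "basal"} == {8, 9}
        assert {s for s, p in labels.items() if p == "apical"} == {1, 2, 3}
        assert {s for s, p in labels.items() if p == "midventricular"} == set(range(4, 8))

    def test_empty_expert_gives_all_unassigned(self):
        expert = single_structure_stack([])
        reader = single_structure_stack(range(2, 5), reader_id="ai")
        labels = classify_slice_positions(expert, reader, "lv_endo", "ED")
        assert set(labels.values()) == {"unassigned"}

    def test_anchors_follow_expert_not_reader(self):
        """Swapping readers moves the anchors with the (new) expert."""
        a = single_structure_stack(range(1, 9))
        b = single_structure_stack(range(2, 10), reader_id="ai")
        labels_ab = classify_slice_positions(a, b, "lv_endo", "ED")
        labels_ba = classify_slice_positions(b, a, "lv_endo", "ED")
        assert labels_ab[8] == "basal" and labels_ab[9] == "basal"
        assert labels_ba[9] == "basal" and labels_ba[2] == "apical"

    def test_misaligned_grids_raise(self):
        a = single_structure_stack(range(1, 5), n_slices=6)
        b = single_structure_stack(range(1, 5), n_slices=8)
        with pytest.raises(AlignmentError):
            classify_slice_positions(a, b, "lv_endo", "ED")


class TestDecisionMetrics:
    def test_hand_counted_confusion(self):
        expert = single_structure_stack(range(1, 9))
        reader = single_structure_stack(range(2, 10), reader_id="ai")
        buckets = decision_metrics(expert, reader, "lv_endo", "ED")
        overall = buckets["overall"]
        assert (overall.tp, overall.fp, overall.fn) == (7, 1, 1)
        assert overall.precision_pct == pytest.approx(87.5)
        assert overall.recall_pct == pytest.approx(87.5)
        assert buckets["basal"].fp == 1 and buckets["apical"].fn == 1

    def test_identical_readers_are_perfect(self):
        expert = single_structure_stack(range(1, 9))
        buckets = decision_metrics(expert, expert, "lv_endo", "ED")
        assert buckets["overall"].precision_pct == 100.0
        assert buckets["overall"].recall_pct == 100.0

    def test_empty_denominator_is_undefined_marker(self):
        expert = single_structure_stack(range(2, 5))
        reader = single_structure_stack([], reader_id="ai")
        buckets = decision_metrics(expert, reader, "lv_endo", "ED")
        assert buckets["overall"].precision_pct is None  # tp + fp == 0
        assert buckets["overall"].recall_pct == 0.0

    def test_partition_property(self):
        expert = single_structure_stack(range(1, 9))
        reader = single_structure_stack(range(3, 10), reader_id="ai")
        buckets = decision_metrics(expert, reader, "lv_endo", "ED")
        summed = sum(
            buckets[p].tp + buckets[p].fp + buckets[p].fn
            for p in ("basal", "midventricular", "apical", "unassigned")
        )
        union = set(range(1, 9)) | set(range(3, 10))
        assert summed == len(union)


class TestDiceAverage:
    def test_convention_example(self):
        records = [record("neither", 100.0), record("both", 100.0, hd=0.0),
                   record("only_a", 0.0)]
        mean_all, sd_all = dice_average(records, "all_slices")
        mean_both, _ = dice_average(records, "both_only")
        assert mean_all == pytest.approx(200 / 3, abs=0.05)
        assert sd_all is None  # no sd reported for the all-slices convention
        assert mean_both == pytest.approx(100.0)

    def test_conventions_agree_without_decision_errors(self):
        records = [record("both", v, hd=0.0) for v in (90.0, 95.0, 85.0)]
        assert dice_average(records, "all_slices")[0] == pytest.approx(
            dice_average(records, "both_only")[0]
        )

    def test_single_one_only_record(self):
        records = [record("only_b", 0.0)]
        assert dice_average(records, "all_slices") == (0.0, None)
        assert dice_average(records, "both_only") == (None, None)

    def test_all_slices_never_exceeds_both_only_with_errors(self, rng):
        for _ in range(20):
            records = [
                record("both", rng.uniform(50, 100), hd=1.0)
                for _ in range(rng.integers(1, 10))
            ]
            records += [record("only_a", 0.0)] * int(rng.integers(1, 4))
            assert (
                dice_average(records, "all_slices")[0]
                <= dice_average(records, "both_only")[0]
            )


class TestStratifiedMetrics:
    def test_identical_readers_all_perfect(self):
        stack, _ = generate_phantom(PhantomParams(n_slices=5), case_id="s")
        table = stratified_metrics(ReaderPair(stack, stack))
        populated = table[table.n_slices > 0]
        filled = populated.dropna(subset=["dice_both_mean_pct"])
        assert np.allclose(filled["dice_both_mean_pct"], 100.0)
        assert np.allclose(filled["hd_mean_mm"].dropna(), 0.0)
        assert (populated["precision_pct"].dropna() == 100.0).all()
        assert (populated["recall_pct"].dropna() == 100.0).all()

    def test_row_contract(self):
        stack, _ = generate_phantom(PhantomParams(n_slices=5), case_id="s")
        table = stratified_metrics(ReaderPair(stack, stack))
        entities = {e for e, _ in table.index}
        assert entities == {"lv_endo", "lvm", "rv_endo", "overall"}
        for entity in ("lv_endo", "lvm", "rv_endo", "overall"):
            assert {p for e, p in table.index if e == entity} >= {
                "basal", "midventricular", "apical"
            }

    def test_basal_only_errors_stay_basal(self):
        stack, _ = generate_phantom(PhantomParams(n_slices=8), case_id="s")
        model = ErrorModel("basal_decision", {"p_drop_anchor": 1.0})
        reader, _ = apply_error_model(stack, model, seed=11)
        table = stratified_metrics(ReaderPair(stack, reader))
        overall = table.loc["overall"]
        assert overall.loc["basal", "recall_pct"] < 100.0
        assert overall.loc["midventricular", "recall_pct"] == 100.0
        assert overall.loc["apical", "recall_pct"] == 100.0

    def test_error_free_cohort_zero_distances(self):
        stack, _ = generate_phantom(PhantomParams(n_slices=6), case_id="s")
        records = compare_stacks(ReaderPair(stack, stack))
        assert all(r.hausdorff_mm == 0.0 for r in records if r.decision == "both")
        assert all(r.abs_volume_diff_ml == 0.0 for r in records)
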