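import io

import numpy as np
import pytest

from cmrqc.clinical_params import clinical_summary, structure_volume
from cmrqc.errors import ValidationError
from cmrqc.io_contours import write_contour_stack
from cmrqc.multilevel import ReaderPair, classify_slice_positions, compare_stacks
from cmrqc.synthetic import (
    ErrorModel,
    PhantomParams,
    apply_error_model,
    apply_error_models,
    generate_phantom,
    make_cohort,
)


def serialized(stack, tmp_path, name):
    path = tmp_path / name
    write_contour_stack(stack, path)
    return path.read_bytes()


class TestGeneratePhantom:
    def test_flat_stack_matches_closed_form(self):
        params = PhantomParams(n_slices=8, lv_endo_radii_mm=(20.0,) * 8)
        stack, truth = generate_phantom(params, case_id="flat")
        analytic = 8 * np.pi * 400 * 7 / 1000  # 70.37 ml
        assert truth.lvedv_ml == pytest.approx(analytic, rel=1e-9)
        assert structure_volume(stack, "lv_endo", "ED") == pytest.approx(
            analytic, rel=0.001
        )

    def test_same_seed_is_byte_identical(self, tmp_path):
        a, _ = generate_phantom(PhantomParams(), seed=7, case_id="d")
        b, _ = generate_phantom(PhantomParams(), seed=7, case_id="d")
        assert serialized(a, tmp_path, "a.json") == serialized(b, tmp_path, "b.json")

    def test_contraction_controls_ef(self):
        eps = 0.2
        params = PhantomParams(lv_contraction=1 - eps)
        _, truth = generate_phantom(params, case_id="ef")
        assert truth.lvef_pct == pytest.approx(100 * (1 - (1 - eps) ** 2), abs=0.1)

    def test_truth_volumes_are_disc_sums_of_truth_areas(self):
        _, truth = generate_phantom(PhantomParams(n_slices=6), case_id="t")
        areas = truth.slice_areas_mm2[("ED", "lv_endo")]
        assert truth.lvedv_ml == pytest.approx(sum(areas.values()) * 7 / 1000, rel=1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValidationError):
            PhantomParams(lv_contraction=1.5)
        with pytest.raises(ValidationError):
            PhantomParams(boundary_vertices=32)

    def test_measured_params_match_truth(self):
        stack, truth = generate_phantom(PhantomParams(), case_id="m")
        summary = clinical_summary(stack)
        for field in ("lvedv_ml", "lvesv_ml", "lvm_g", "rvedv_ml"):
            assert getattr(summary, field) == pytest.approx(
                getattr(truth, field), rel=0.01
            )


class TestErrorModels:
    def test_radial_bias_expected_volume_offset(self):
        params = PhantomParams(n_slices=8, lv_endo_radii_mm=(20.0,) * 8)
        stack, _ = generate_phantom(params, case_id="rb")
        model = ErrorModel("radial_bias", {"delta_mm": -0.5}, structures=("lv_endo",))
        reader, events = apply_error_model(stack, model, seed=0)
        offset = structure_volume(reader, "lv_endo", "ED") - structure_volume(
            stack, "lv_endo", "ED"
        )
        analytic = 8 * np.pi * (19.5**2 - 400) * 7 / 1000  # -3.47 ml
        assert offset == pytest.approx(analytic, rel=0.01)
        bookkept = sum(
            e.volume_offset_ml
            for e in events
            if e.structure == "lv_endo" and e.phase == "ED"
        )
        assert bookkept == pytest.approx(offset, rel=1e-9)

    def test_translation_dice_and_hausdorff(self):
        params = PhantomParams(
            n_slices=1, lv_endo_radii_mm=(20.0,), pixel_spacing_mm=(1.0, 1.0),
            margin_slices=0,
        )
        stack, _ = generate_phantom(params, case_id="tr")
        model = ErrorModel(
            "translation", {"d_mm": 5.0, "direction_deg": 30.0},
            structures=("lv_endo",),
        )
        reader, _ = apply_error_model(stack, model, seed=0)
        records = [
            r
            for r in compare_stacks(ReaderPair(stack, reader))
            if r.entity == "lv_endo" and r.decision == "both" and r.phase == "ED"
        ]
        assert records[0].dice_pct == pytest.approx(84.1, abs=0.2)
        assert records[0].hausdorff_mm == pytest.approx(5.0, abs=0.1)

    def test_basal_drop_forces_recall_loss(self):
        stack, _ = generate_phantom(PhantomParams(n_slices=6), case_id="bd")
        model = ErrorModel("basal_decision", {"p_drop_anchor": 1.0})
        reader, events = apply_error_model(stack, model, seed=1)
        anchor = max(stack.segmented_indices("lv_endo", "ED"))
        assert anchor not in reader.segmented_indices("lv_endo", "ED")
        assert any(e.kind == "basal_decision" for e in events)

    def test_error_locality_respects_positions(self):
        stack, _ = generate_phantom(PhantomParams(n_slices=8), case_id="loc")
        model = ErrorModel(
            "radial_bias", {"delta_mm": 1.0}, structures=("lv_endo",),
            positions=("basal",),
        )
        reader, events = apply_error_model(stack, model, seed=0)
        labels = classify_slice_positions(stack, reader, "lv_endo", "ED")
        for e in events:
            if e.phase == "ED":
                assert labels[e.slice_index] == "basal"
        # untouched slices are bit-identical
        for ann in stack.slices:
            other = reader.annotation(ann.slice_index, ann.phase)
            touched = {(e.slice_index, e.phase) for e in events}
            if (ann.slice_index, ann.phase) not in touched and "lv_endo" in ann.contours:
                np.testing.assert_array_equal(
                    ann.contours["lv_endo"].rings[0],
                    other.contours["lv_endo"].rings[0],
                )

    def test_fragmentation_shrinks_area(self):
        stack, _ = generate_phantom(PhantomParams(n_slices=4), case_id="fr")
        model = ErrorModel(
            "fragmentation", {"p": 1.0, "area_fraction": 0.1}, structures=("rv_endo",)
        )
        reader, _ = apply_error_model(stack, model, seed=2)
        assert structure_volume(reader, "rv_endo", "ED") == pytest.approx(
            0.1 * structure_volume(stack, "rv_endo", "ED"), rel=0.01
        )

    def test_vertex_jitter_keeps_valid_contours(self):
        stack, _ = generate_phantom(PhantomParams(n_slices=4), case_id="vj")
        model = ErrorModel("vertex_jitter", {"sd_mm": 0.2}, structures=("rv_endo",))
        reader, events = apply_error_model(stack, model, seed=3)
        assert events  # some slices perturbed
        clinical_summary(reader)  # still a valid stack end-to-end

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            ErrorModel("smoothing", {})

    def test_determinism(self, tmp_path):
        stack, _ = generate_phantom(PhantomParams(n_slices=5), case_id="det")
        model = ErrorModel("vertex_jitter", {"sd_mm": 0.3})
        a, _ = apply_error_model(stack, model, seed=9)
        b, _ = apply_error_model(stack, model, seed=9)
        assert serialized(a, tmp_path, "a.json") == serialized(b, tmp_path, "b.json")


class TestMakeCohort:
    def test_identity_cohort_is_perfect(self):
        cohort = make_cohort(3, seed=5)
        for expert, reader in zip(cohort.expert_stacks, cohort.reader_stacks):
            records = compare_stacks(ReaderPair(expert, reader))
            assert all(
                r.dice_pct == pytest.approx(100.0) for r in records
            )

    def test_negative_radial_bias_gives_negative_cohort_bias(self):
        models = [ErrorModel("radial_bias", {"delta_mm": -0.4}, structures=("lv_endo",))]
        cohort = make_cohort(6, models=models, seed=5)
        diffs = [
            structure_volume(r, "lv_endo", "ED") - structure_volume(e, "lv_endo", "ED")
            for e, r in zip(cohort.expert_stacks, cohort.reader_stacks)
        ]
        assert np.mean(diffs) < 0

    def test_same_seed_same_manifest(self):
        a = make_cohort(4, seed=3)
        b = make_cohort(4, seed=3)
        assert a.manifest == b.manifest
        assert [t.to_dict() for t in a.truths] == [t.to_dict() for t in b.truths]

    def test_pipeline_recovers_injected_bias_within_two_percent(self):
        """Cohort-mean injected EDV offset recovered through the full pipeline."""
        models = [ErrorModel("radial_bias", {"delta_mm": -0.5}, structures=("lv_endo",))]
        cohort = make_cohort(20, models=models, seed=17)
        measured, expected = [], []
        for expert, reader, truth in zip(
            cohort.expert_stacks, cohort.reader_stacks, cohort.truths
        ):
            measured.append(
                structure_volume(reader, "lv_endo", "ED")
                - structure_volume(expert, "lv_endo", "ED")
            )
            expected.append(truth.injected_volume_offset_ml["lv_endo/ED"])
        assert np.mean(measured) == pytest.approx(np.mean(expected), rel=0.02)
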