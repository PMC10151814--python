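"""Quantitative clinical function parameters from contour stacks.

Volumes use disc summation (Simpson's method): the sum over segmented slices
of the cross-sectional region area times the slice spacing (thickness + gap).
No partial-disc interpolation is applied at the base or apex — parameters are
computed exactly from the slices the reader segmented.

Reported parameters: end-diastolic and end-systolic volume and ejection
fraction for both ventricles, and left-ventricular myocardial mass (at ED,
myocardial volume × tissue density, default 1.05 g/ml).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import pandas as pd

from .contour_model import ContourStack, build_region
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Standard myocardial tissue density in g/ml.
MYOCARDIAL_DENSITY_G_PER_ML = 1.05

#: Column order used by every per-case parameter table in the package.
PARAM_COLUMNS = (
    "lvedv_ml",
    "lvesv_ml",
    "lvef_pct",
    "rvedv_ml",
    "rvesv_ml",
    "rvef_pct",
    "lvm_g",
)


@dataclass(frozen=True)
class ClinicalParams:
    """Per-case function parameters (volumes in ml, EF in percent, mass in g)."""

    lvedv_ml: float
    lvesv_ml: float
    lvef_pct: float
    rvedv_ml: float
    rvesv_ml: float
    rvef_pct: float
    lvm_g: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def structure_volume(stack: ContourStack, entity: str, phase: str) -> float:
    """Disc-summation volume in ml of one entity in one phase.

    Slices where the reader did not segment the entity contribute zero. For
    the myocardium, a slice with an epicardial but no endocardial contour
    contributes the full epicardial area (the cavity is taken to vanish
    apically); such slices are logged as reportable events.
    """
    stack.require_phase(phase)
    spacing_mm = stack.slice_spacing_mm
    total_mm3 = 0.0
    for idx in stack.slice_indices(phase):
        ann = stack.annotation(idx, phase)
        region = build_region(ann, entity, stack.pixel_spacing_mm)
        if region is not None:
            total_mm3 += region.area_mm2 * spacing_mm
        elif entity == "lvm" and ann.has("lv_epi") and not ann.has("lv_endo"):
            from .contour_model import polygon_area

            area = polygon_area(ann.contours["lv_epi"], stack.pixel_spacing_mm)
            total_mm3 += area * spacing_mm
            logger.info(
                "case %s: slice %d phase %s has lv_epi without lv_endo; "
                "full epicardial area counted toward LVM",
                stack.case_id,
                idx,
                phase,
            )
    return total_mm3 / 1000.0


def ejection_fraction(edv_ml: float, esv_ml: float) -> float:
    """Ejection fraction in percent: 100·(EDV − ESV)/EDV."""
    if edv_ml <= 0:
        raise ValidationError(
            f"ejection fraction undefined for EDV = {edv_ml} ml (must be > 0)"
        )
    return 100.0 * (edv_ml - esv_ml) / edv_ml


def myocardial_mass(
    stack: ContourStack, density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML
) -> float:
    """LV myocardial mass in grams at end-diastole."""
    if density_g_per_ml < 0:
        raise ValidationError("density must be >= 0")
    return structure_volume(stack, "lvm", "ED") * density_g_per_ml


def clinical_summary(
    stack: ContourStack, density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML
) -> ClinicalParams:
    """All seven clinical parameters for one case. Requires ED and ES."""
    stack.require_phase("ED")
    stack.require_phase("ES")
    lvedv = structure_volume(stack, "lv_endo", "ED")
    lvesv = structure_volume(stack, "lv_endo", "ES")
    rvedv = structure_volume(stack, "rv_endo", "ED")
    rvesv = structure_volume(stack, "rv_endo", "ES")
    return ClinicalParams(
        lvedv_ml=lvedv,
        lvesv_ml=lvesv,
        lvef_pct=ejection_fraction(lvedv, lvesv),
        rvedv_ml=rvedv,
        rvesv_ml=rvesv,
        rvef_pct=ejection_fraction(rvedv, rvesv),
        lvm_g=myocardial_mass(stack, density_g_per_ml),
    )


def params_table(stacks: list[ContourStack], **kwargs) -> pd.DataFrame:
    """Per-case parameter table (index: case_id, columns: :data:`PARAM_COLUMNS`)."""
    rows = {s.case_id: clinical_summary(s, **kwargs).to_dict() for s in stacks}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "case_id"
    return df[list(PARAM_COLUMNS)]
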