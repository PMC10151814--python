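"""Synthetic short-axis contour phantoms with analytic ground truth.

The generator emulates the study conditions this pipeline is designed for:
short-axis stacks of 7 mm slices with no gap, ED and ES phases annotated,
subpixel polygon contours for the LV endocardium, LV epicardium and RV
endocardium. The LV is a stack of circles whose radius follows an
ellipsoid-like taper from apex to base; the RV endocardium is a crescent
built as the difference of an offset disk and the epicardial disk; ES
contours are the ED contours contracted about their centroid by a per-
structure linear scale factor (so areas scale with the square of it and
EF = 100·(1 − c²) for a uniform contraction).

Ground-truth volumes come from closed-form circle areas for the LV and from
the shoelace area of the generated polygon itself for the RV crescent, so
truth is exact with respect to the generated geometry.

Parametric error models reproduce the characteristic CNN failure modes seen
in segmentation QC: basal/apical segmentation-decision errors, radial
over-/under-segmentation bias, contour displacement, fragmentation, and
vertex jitter. Every injected event is book-kept with its expected
volumetric effect so the full pipeline's recovery can be tested against
analytic expectations.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point

from .contour_model import (
    ContourPolygon,
    ContourStack,
    SliceAnnotation,
    shoelace_area,
)
from .errors import ValidationError


# ---------------------------------------------------------------------------
# phantom parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomParams:
    """Geometry of one synthetic case.

    Defaults produce a physiologically plausible adult heart: ~100 ml LVEDV,
    EF ≈ 60% (LV) / 50% (RV), LVM ≈ 90 g, on a 256×256 grid at 1.4 mm
    in-plane resolution with 7 mm slices and no gap. The slice grid carries
    one empty margin slice above the base and below the apex so that
    decision-error models can add false-positive slices.
    """

    n_slices: int = 10
    slice_thickness_mm: float = 7.0
    slice_gap_mm: float = 0.0
    pixel_spacing_mm: tuple[float, float] = (1.4, 1.4)
    image_shape: tuple[int, int] = (256, 256)
    lv_center_px: tuple[float, float] = (110.0, 128.0)  # (x, y)
    lv_base_radius_mm: float = 25.0
    lv_endo_radii_mm: tuple[float, ...] | None = None  # overrides the taper
    wall_thickness_mm: float = 8.0
    rv_outer_radius_mm: float = 30.0
    rv_center_offset_mm: float = 34.0  # RV disk centre left of the LV centre
    lv_contraction: float = 0.632  # ES/ED linear scale -> LVEF ~ 60%
    rv_contraction: float = 0.707  # -> RVEF ~ 50%
    boundary_vertices: int = 256
    margin_slices: int = 1  # empty grid slices beyond apex and base

    def __post_init__(self):
        if self.boundary_vertices < 64:
            raise ValidationError("boundary_vertices must be >= 64")
        if not 0 < self.lv_contraction < 1 or not 0 < self.rv_contraction < 1:
            raise ValidationError("contraction fractions must lie in (0, 1)")
        if self.wall_thickness_mm <= 0:
            raise ValidationError("wall_thickness_mm must be > 0")
        for r in self.endo_radii_mm:
            if r <= 0:
                raise ValidationError("all LV endocardial radii must be > 0")

    @property
    def endo_radii_mm(self) -> tuple[float, ...]:
        """Per-slice ED endocardial radii, apex (index 0) to base."""
        if self.lv_endo_radii_mm is not None:
            return tuple(self.lv_endo_radii_mm)
        n = self.n_slices
        # ellipsoid-like taper: full radius at the base, shrinking apically
        return tuple(
            self.lv_base_radius_mm * math.sqrt(1.0 - ((n - 1 - i) / n) ** 2)
            for i in range(n)
        )


@dataclass
class ErrorEvent:
    """Bookkeeping record of one injected perturbation."""

    kind: str
    structure: str
    slice_index: int
    phase: str
    volume_offset_ml: float = 0.0  # expected signed effect on the disc sum
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ErrorModel:
    """One parametric perturbation applied to a copy of the expert stack.

    ``kind`` is one of ``radial_bias`` (params: delta_mm), ``translation``
    (params: d_mm, direction_deg or random), ``basal_decision`` (params:
    p_drop_anchor, p_add_above), ``apical_decision`` (params: p_drop,
    p_add_below), ``fragmentation`` (params: p, area_fraction) and
    ``vertex_jitter`` (params: sd_mm). ``structures`` restricts the targets;
    ``positions`` (subset of basal/midventricular/apical, anchored to the
    expert's own segmented extremes) restricts the slices for the geometric
    kinds. Models compose in the order they are applied.
    """

    kind: str
    params: dict = field(default_factory=dict)
    structures: tuple[str, ...] = ("lv_endo", "lv_epi", "rv_endo")
    positions: tuple[str, ...] | None = None

    KINDS = (
        "radial_bias",
        "translation",
        "basal_decision",
        "apical_decision",
        "fragmentation",
        "vertex_jitter",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValidationError(
                f"unknown error-model kind {self.kind!r}; expected one of {self.KINDS}"
            )
        for key, value in self.params.items():
            if key.startswith("p") and not 0 <= value <= 1:
                raise ValidationError(f"probability {key}={value} outside [0, 1]")


@dataclass
class PhantomTruth:
    """Analytic ground truth of one synthetic case."""

    case_id: str
    lvedv_ml: float
    lvesv_ml: float
    lvef_pct: float
    rvedv_ml: float
    rvesv_ml: float
    rvef_pct: float
    lvm_g: float
    slice_areas_mm2: dict  # (phase, structure) -> per-slice-index area map
    injected_volume_offset_ml: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lvedv_ml": self.lvedv_ml,
            "lvesv_ml": self.lvesv_ml,
            "lvef_pct": self.lvef_pct,
            "rvedv_ml": self.rvedv_ml,
            "rvesv_ml": self.rvesv_ml,
            "rvef_pct": self.rvef_pct,
            "lvm_g": self.lvm_g,
        }


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _circle_px(
    center_px: tuple[float, float],
    radius_mm: float,
    spacing: tuple[float, float],
    n_vertices: int,
) -> np.ndarray:
    """Vertices of a physically circular contour in (anisotropic) pixel coords."""
    sy, sx = spacing
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    x = center_px[0] + radius_mm * np.cos(theta) / sx
    y = center_px[1] + radius_mm * np.sin(theta) / sy
    return np.column_stack([x, y])


def _crescent_px(
    lv_center_px: tuple[float, float],
    epi_radius_mm: float,
    outer_radius_mm: float,
    center_offset_mm: float,
    spacing: tuple[float, float],
    n_vertices: int,
) -> np.ndarray | None:
    """RV crescent: offset disk minus the epicardial disk, in pixel coords.

    Built in mm coordinates with shapely, then mapped to pixels. Returns the
    exterior ring or ``None`` when the difference is empty.
    """
    quad = max(n_vertices // 4, 16)
    rv_disk = Point(-center_offset_mm, 0.0).buffer(outer_radius_mm, quad_segs=quad)
    lv_disk = Point(0.0, 0.0).buffer(epi_radius_mm, quad_segs=quad)
    crescent = rv_disk.difference(lv_disk)
    if crescent.is_empty:
        return None
    if crescent.geom_type == "MultiPolygon":
        crescent = max(crescent.geoms, key=lambda g: g.area)
    ring_mm = np.asarray(crescent.exterior.coords)[:-1]
    sy, sx = spacing
    ring = np.column_stack(
        [lv_center_px[0] + ring_mm[:, 0] / sx, lv_center_px[1] + ring_mm[:, 1] / sy]
    )
    if shoelace_area(ring) < 0:
        ring = ring[::-1]
    return ring


def _scaled_about_centroid(ring: np.ndarray, factor: float) -> np.ndarray:
    from shapely.geometry import Polygon

    c = Polygon(ring).centroid
    centre = np.array([c.x, c.y])
    return centre + (ring - centre) * factor


def _area_mm2(ring: np.ndarray, spacing: tuple[float, float]) -> float:
    return abs(shoelace_area(ring)) * spacing[0] * spacing[1]


def derive_seed(seed: int, case_id: str) -> int:
    """Stable per-case substream seed (< 2^31) from the run seed and case id."""
    digest = hashlib.blake2s(f"{seed}/{case_id}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(
    params: PhantomParams, seed: int = 0, case_id: str = "phantom"
) -> tuple[ContourStack, PhantomTruth]:
    """Generate the expert annotation stack and its analytic ground truth.

    The geometry is fully determined by ``params``; ``seed`` is carried for
    API symmetry with the error models and cohort sampler.
    """
    radii = params.endo_radii_mm
    epi_radii = tuple(r + params.wall_thickness_mm for r in radii)
    spacing = params.pixel_spacing_mm
    nv = params.boundary_vertices
    margin = params.margin_slices
    th = params.slice_thickness_mm + params.slice_gap_mm

    slices: list[SliceAnnotation] = []
    slice_areas: dict = {}
    rv_ed_areas: dict[int, float] = {}
    for phase, lv_c, rv_c in (
        ("ED", 1.0, 1.0),
        ("ES", params.lv_contraction, params.rv_contraction),
    ):
        areas: dict[str, dict[int, float]] = {"lv_endo": {}, "lv_epi": {}, "rv_endo": {}}
        for grid_idx in range(params.n_slices + 2 * margin):
            i = grid_idx - margin
            if not 0 <= i < params.n_slices:
                slices.append(SliceAnnotation(grid_idx, phase, {}))
                continue
            endo_r = radii[i] * lv_c
            # ES wall thickening conserves myocardial ring area per slice
            epi_r = (
                epi_radii[i]
                if phase == "ED"
                else math.sqrt(endo_r**2 + (epi_radii[i] ** 2 - radii[i] ** 2))
            )
            contours = {
                "lv_endo": ContourPolygon(
                    "lv_endo", [_circle_px(params.lv_center_px, endo_r, spacing, nv)]
                ),
                "lv_epi": ContourPolygon(
                    "lv_epi", [_circle_px(params.lv_center_px, epi_r, spacing, nv)]
                ),
            }
            areas["lv_endo"][grid_idx] = math.pi * endo_r**2
            areas["lv_epi"][grid_idx] = math.pi * epi_r**2
            rv_ring = _crescent_px(
                params.lv_center_px,
                epi_radii[i],
                params.rv_outer_radius_mm * radii[i] / max(radii),
                params.rv_center_offset_mm,
                spacing,
                nv,
            )
            if rv_ring is not None and abs(shoelace_area(rv_ring)) > 1e-9:
                if phase == "ES":
                    rv_ring = _scaled_about_centroid(rv_ring, rv_c)
                contours["rv_endo"] = ContourPolygon("rv_endo", [rv_ring])
                if phase == "ED":
                    rv_ed_areas[grid_idx] = _area_mm2(rv_ring, spacing)
                    areas["rv_endo"][grid_idx] = rv_ed_areas[grid_idx]
                else:
                    areas["rv_endo"][grid_idx] = rv_ed_areas[grid_idx] * rv_c**2
            slices.append(SliceAnnotation(grid_idx, phase, contours))
        for structure in areas:
            slice_areas[(phase, structure)] = areas[structure]

    stack = ContourStack(
        case_id=case_id,
        reader_id="expert",
        pixel_spacing_mm=spacing,
        slice_thickness_mm=params.slice_thickness_mm,
        slice_gap_mm=params.slice_gap_mm,
        slices=slices,
        image_shape=params.image_shape,
    )

    def vol(phase, structure):
        return sum(slice_areas[(phase, structure)].values()) * th / 1000.0

    lvedv, lvesv = vol("ED", "lv_endo"), vol("ES", "lv_endo")
    rvedv, rvesv = vol("ED", "rv_endo"), vol("ES", "rv_endo")
    lvm_ml = vol("ED", "lv_epi") - vol("ED", "lv_endo")
    truth = PhantomTruth(
        case_id=case_id,
        lvedv_ml=lvedv,
        lvesv_ml=lvesv,
        lvef_pct=100.0 * (lvedv - lvesv) / lvedv,
        rvedv_ml=rvedv,
        rvesv_ml=rvesv,
        rvef_pct=100.0 * (rvedv - rvesv) / rvedv if rvedv > 0 else math.nan,
        lvm_g=lvm_ml * 1.05,
        slice_areas_mm2=slice_areas,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# error models
# ---------------------------------------------------------------------------

def _expert_position(stack: ContourStack, structure: str, phase: str, idx: int) -> str:
    """Position of a slice relative to the expert's own segmented extremes."""
    segmented = stack.segmented_indices(structure, phase)
    if not segmented:
        return "unassigned"
    if idx >= max(segmented):
        return "basal"
    if idx <= min(segmented):
        return "apical"
    return "midventricular"


def _px_to_mm(ring: np.ndarray, spacing) -> np.ndarray:
    return ring * np.array([spacing[1], spacing[0]])


def _mm_to_px(ring: np.ndarray, spacing) -> np.ndarray:
    return ring / np.array([spacing[1], spacing[0]])


def apply_error_model(
    stack: ContourStack, model: ErrorModel, seed: int = 0
) -> tuple[ContourStack, list[ErrorEvent]]:
    """Apply one perturbation model to a copy of ``stack``.

    Deterministic given ``seed``. Returns the perturbed stack and the list
    of injected events with their expected volumetric effects.
    """
    rng = np.random.default_rng(derive_seed(seed, f"{stack.case_id}/{model.kind}"))
    spacing = stack.pixel_spacing_mm
    th = stack.slice_spacing_mm
    events: list[ErrorEvent] = []

    # start from a mutable copy of the annotation grid
    grid: dict[tuple[int, str], dict[str, ContourPolygon]] = {
        (a.slice_index, a.phase): dict(a.contours) for a in stack.slices
    }

    if model.kind in ("basal_decision", "apical_decision"):
        at_base = model.kind == "basal_decision"
        p_drop = model.params.get("p_drop_anchor", model.params.get("p_drop", 0.0))
        p_add = model.params.get("p_add_above", model.params.get("p_add_below", 0.0))
        for phase in stack.phases:
            for structure in model.structures:
                segmented = stack.segmented_indices(structure, phase)
                if not segmented:
                    continue
                anchor = max(segmented) if at_base else min(segmented)
                if rng.random() < p_drop:
                    contour = grid[(anchor, phase)].pop(structure, None)
                    if contour is not None:
                        offset = -_area_mm2(contour.rings[0], spacing) * th / 1000.0
                        events.append(
                            ErrorEvent(model.kind, structure, anchor, phase, offset,
                                       {"action": "drop_anchor"})
                        )
                if rng.random() < p_add:
                    target = anchor + 1 if at_base else anchor - 1
                    if (target, phase) in grid and structure not in grid[(target, phase)]:
                        source = stack.annotation(anchor, phase).contours[structure]
                        shrunk = ContourPolygon(
                            structure,
                            [_scaled_about_centroid(source.rings[0], 0.7)],
                        )
                        grid[(target, phase)][structure] = shrunk
                        offset = _area_mm2(shrunk.rings[0], spacing) * th / 1000.0
                        events.append(
                            ErrorEvent(model.kind, structure, target, phase, offset,
                                       {"action": "add_beyond_anchor"})
                        )
        return _rebuild(stack, grid, events, model)

    # geometric perturbations on existing contours
    for (idx, phase), contours in sorted(grid.items()):
        for structure in model.structures:
            contour = contours.get(structure)
            if contour is None:
                continue
            if model.positions is not None:
                if _expert_position(stack, structure, phase, idx) not in model.positions:
                    continue
            if model.kind == "radial_bias":
                delta = float(model.params["delta_mm"])
                ring_mm = _px_to_mm(contour.rings[0], spacing)
                centre = ring_mm.mean(axis=0)
                vec = ring_mm - centre
                norms = np.linalg.norm(vec, axis=1, keepdims=True)
                new_mm = centre + vec + delta * vec / norms
                new_ring = _mm_to_px(new_mm, spacing)
                offset = (
                    (_area_mm2(new_ring, spacing) - _area_mm2(contour.rings[0], spacing))
                    * th / 1000.0
                )
                contours[structure] = ContourPolygon(structure, [new_ring])
                events.append(
                    ErrorEvent(model.kind, structure, idx, phase, offset,
                               {"delta_mm": delta})
                )
            elif model.kind == "translation":
                d = float(model.params["d_mm"])
                angle = model.params.get("direction_deg")
                angle = (
                    math.radians(float(angle))
                    if angle is not None
                    else rng.uniform(0, 2 * math.pi)
                )
                dx_px = d * math.cos(angle) / spacing[1]
                dy_px = d * math.sin(angle) / spacing[0]
                contours[structure] = contour.translated(dx_px, dy_px)
                events.append(
                    ErrorEvent(model.kind, structure, idx, phase, 0.0,
                               {"d_mm": d, "direction_rad": angle})
                )
            elif model.kind == "fragmentation":
                if rng.random() >= model.params.get("p", 1.0):
                    continue
                frac = float(model.params.get("area_fraction", 0.1))
                ring = contour.rings[0]
                pivot = ring[rng.integers(len(ring))]
                fragment = pivot + (ring - pivot) * math.sqrt(frac)
                old = _area_mm2(ring, spacing)
                offset = (old * frac - old) * th / 1000.0
                contours[structure] = ContourPolygon(structure, [fragment])
                events.append(
                    ErrorEvent(model.kind, structure, idx, phase, offset,
                               {"area_fraction": frac})
                )
            elif model.kind == "vertex_jitter":
                # smooth radial boundary noise: low-frequency Fourier modes
                # with total sd ``sd_mm``, so the ring wobbles without the
                # self-intersections iid per-vertex noise would cause
                sd = float(model.params["sd_mm"])
                n_modes = int(model.params.get("n_modes", 6))
                ring_mm = _px_to_mm(contour.rings[0], spacing)
                centre = ring_mm.mean(axis=0)
                vec = ring_mm - centre
                radii = np.linalg.norm(vec, axis=1)
                theta = np.arctan2(vec[:, 1], vec[:, 0])
                for _ in range(8):  # retry until the jittered ring stays simple
                    coeffs = rng.normal(0.0, sd / math.sqrt(n_modes), (n_modes, 2))
                    noise = sum(
                        coeffs[k, 0] * np.cos((k + 1) * theta)
                        + coeffs[k, 1] * np.sin((k + 1) * theta)
                        for k in range(n_modes)
                    )
                    new_radii = np.maximum(radii + noise, 0.1 * radii)
                    noisy = centre + vec * (new_radii / radii)[:, None]
                    new_ring = _mm_to_px(noisy, spacing)
                    if shoelace_area(new_ring) < 0:
                        continue
                    try:
                        candidate = ContourPolygon(structure, [new_ring])
                        break
                    except ValidationError:
                        continue
                else:
                    continue
                offset = (
                    (_area_mm2(new_ring, spacing) - _area_mm2(contour.rings[0], spacing))
                    * th / 1000.0
                )
                contours[structure] = candidate
                events.append(
                    ErrorEvent(model.kind, structure, idx, phase, offset, {"sd_mm": sd})
                )
    return _rebuild(stack, grid, events, model)


def _rebuild(stack, grid, events, model) -> tuple[ContourStack, list[ErrorEvent]]:
    # lv_epi must keep containing lv_endo; a perturbation that breaks the
    # nesting invariant on a slice is resolved by dropping the contour pair
    # from the reader, recorded as a decision error
    slices = []
    for (idx, phase), contours in sorted(grid.items()):
        try:
            slices.append(SliceAnnotation(idx, phase, contours))
        except ValidationError:
            reduced = {k: v for k, v in contours.items() if k == "rv_endo"}
            slices.append(SliceAnnotation(idx, phase, reduced))
            events.append(
                ErrorEvent("containment_fallback", "lv_endo", idx, phase, 0.0,
                           {"caused_by": model.kind})
            )
    reader = ContourStack(
        case_id=stack.case_id,
        reader_id=f"{stack.reader_id}+{model.kind}",
        pixel_spacing_mm=stack.pixel_spacing_mm,
        slice_thickness_mm=stack.slice_thickness_mm,
        slice_gap_mm=stack.slice_gap_mm,
        slices=slices,
        image_shape=stack.image_shape,
    )
    return reader, events


def apply_error_models(
    stack: ContourStack, models, seed: int = 0, reader_id: str = "ai"
) -> tuple[ContourStack, list[ErrorEvent]]:
    """Compose several error models in their declared order."""
    events: list[ErrorEvent] = []
    current = stack
    for i, model in enumerate(models):
        current, new_events = apply_error_model(current, model, seed=seed + i)
        events.extend(new_events)
    current = replace(current, reader_id=reader_id, slices=current.slices)
    return current, events


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def default_params_sampler(rng: np.random.Generator) -> PhantomParams:
    """Case-to-case anatomical variation within a realistic adult range."""
    return PhantomParams(
        n_slices=int(rng.integers(8, 13)),
        lv_base_radius_mm=float(rng.uniform(21.0, 28.0)),
        wall_thickness_mm=float(rng.uniform(6.0, 10.0)),
        rv_outer_radius_mm=float(rng.uniform(27.0, 33.0)),
        lv_contraction=float(rng.uniform(0.55, 0.70)),
        rv_contraction=float(rng.uniform(0.65, 0.78)),
    )


@dataclass
class Cohort:
    expert_stacks: list[ContourStack]
    reader_stacks: list[ContourStack]
    truths: list[PhantomTruth]
    events: dict[str, list[ErrorEvent]]
    manifest: dict


def make_cohort(
    n_cases: int,
    params_sampler=None,
    models=(),
    seed: int = 0,
    reader_id: str = "ai",
) -> Cohort:
    """Generate a paired expert/reader cohort, fully reproducible from ``seed``."""
    if n_cases < 1:
        raise ValidationError("n_cases must be >= 1")
    sampler = params_sampler or default_params_sampler
    experts, readers, truths = [], [], []
    all_events: dict[str, list[ErrorEvent]] = {}
    for i in range(n_cases):
        case_id = f"case_{i:03d}"
        case_seed = derive_seed(seed, case_id)
        rng = np.random.default_rng(case_seed)
        params = sampler(rng)
        expert, truth = generate_phantom(params, seed=case_seed, case_id=case_id)
        reader, events = apply_error_models(
            expert, models, seed=case_seed, reader_id=reader_id
        )
        truth.injected_volume_offset_ml = _offset_summary(events)
        experts.append(expert)
        readers.append(reader)
        truths.append(truth)
        all_events[case_id] = events
    manifest = {
        "n_cases": n_cases,
        "seed": seed,
        "reader_id": reader_id,
        "models": [
            {"kind": m.kind, "params": m.params, "structures": list(m.structures)}
            for m in models
        ],
        "case_ids": [t.case_id for t in truths],
    }
    return Cohort(experts, readers, truths, all_events, manifest)


def _offset_summary(events: list[ErrorEvent]) -> dict:
    """Expected signed volume offset per (structure, phase) from the event log."""
    out: dict[tuple[str, str], float] = {}
    for ev in events:
        key = (ev.structure, ev.phase)
        out[key] = out.get(key, 0.0) + ev.volume_offset_ml
    return {f"{s}/{p}": v for (s, p), v in out.items()}
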