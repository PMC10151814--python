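"""Read/write the contour-stack JSON format and import/export label masks.

The on-disk format is a single JSON document (schema version "1", see
``docs/contour_stack_schema.md``): a header with case/reader identity and
acquisition geometry, plus a flat list of contour records. Floats are
serialised with Python's shortest round-trip representation, so a
write→read cycle reproduces every vertex bit-exactly, and records and keys
are emitted in a fixed sort order, so identical stacks produce identical
bytes.

Raster interchange: per-slice label masks use the channel semantics of the
segmentation maps this pipeline evaluates — 0 background, 1 LV blood pool,
2 LV myocardium, 3 RV blood pool. Vectorisation runs marching squares at
iso-level 0.5 on each label's binary image (subpixel contours) and, when
requested, keeps only the largest connected polygon per structure, mirroring
the evaluated networks' postprocessing. The epicardial contour is recovered
as the boundary of the union of labels 1 and 2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage import measure

from .contour_model import (
    STRUCTURES,
    ContourPolygon,
    ContourStack,
    SliceAnnotation,
    shoelace_area,
)
from .errors import FormatError, IOFailure, ValidationError

SCHEMA_VERSION = "1"

LABELS = {"background": 0, "lv_endo": 1, "lvm": 2, "rv_endo": 3}


# ---------------------------------------------------------------------------
# contour-stack JSON
# ---------------------------------------------------------------------------

def _stack_to_document(stack: ContourStack) -> dict:
    records = []
    for ann in stack.slices:
        for structure in sorted(ann.contours):
            contour = ann.contours[structure]
            records.append(
                {
                    "slice_index": int(ann.slice_index),
                    "phase": ann.phase,
                    "structure": structure,
                    "rings": [
                        [[float(x), float(y)] for x, y in ring]
                        for ring in contour.rings
                    ],
                }
            )
    records.sort(key=lambda r: (r["slice_index"], r["phase"], r["structure"]))
    phase_grids = {
        phase: [min(idx), max(idx)]
        for phase in stack.phases
        if (idx := stack.slice_indices(phase))
    }
    return {
        "schema_version": SCHEMA_VERSION,
        "phase_grids": phase_grids,
        "case_id": stack.case_id,
        "reader_id": stack.reader_id,
        "pixel_spacing_mm": [float(s) for s in stack.pixel_spacing_mm],
        "slice_thickness_mm": float(stack.slice_thickness_mm),
        "slice_gap_mm": float(stack.slice_gap_mm),
        "slice_order": "apex_to_base",
        "image_shape": list(stack.image_shape) if stack.image_shape else None,
        "contours": records,
    }


def write_contour_stack(stack: ContourStack, path) -> None:
    """Serialise a stack to JSON. Byte-deterministic for identical input."""
    doc = _stack_to_document(stack)
    text = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    try:
        Path(path).write_text(text + "\n")
    except OSError as exc:
        raise IOFailure(f"cannot write contour stack to {path}: {exc}") from exc


def _require(doc: dict, key: str, path):
    if key not in doc:
        raise FormatError(f"{path}: missing required field {key!r}")
    return doc[key]


def read_contour_stack(path) -> ContourStack:
    """Read and validate a contour-stack JSON file.

    Stacks stored base-to-apex are re-indexed on read so slice 0 is the most
    apical slice.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOFailure(f"cannot read contour stack from {path}: {exc}") from exc
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc

    version = _require(doc, "schema_version", path)
    if version != SCHEMA_VERSION:
        raise FormatError(f"{path}: unsupported schema_version {version!r}")
    slice_order = _require(doc, "slice_order", path)
    if slice_order not in ("apex_to_base", "base_to_apex"):
        raise FormatError(f"{path}: invalid slice_order {slice_order!r}")
    spacing = _require(doc, "pixel_spacing_mm", path)
    if not (isinstance(spacing, list) and len(spacing) == 2):
        raise FormatError(f"{path}: pixel_spacing_mm must be a [row, col] pair")
    records = _require(doc, "contours", path)

    # group records into slice annotations; the phase grid may include
    # slices with no contours (unsegmented but acquired slices)
    grouped: dict[tuple[int, str], dict[str, ContourPolygon]] = {}
    phase_grids = doc.get("phase_grids", {})
    for phase, (lo, hi) in phase_grids.items():
        for idx in range(int(lo), int(hi) + 1):
            grouped[(idx, str(phase))] = {}
    for i, rec in enumerate(records):
        loc = f"{path}: contour record {i}"
        for key in ("slice_index", "phase", "structure", "rings"):
            if key not in rec:
                raise FormatError(f"{loc}: missing field {key!r}")
        structure = rec["structure"]
        if structure not in STRUCTURES:
            raise FormatError(f"{loc}: unknown structure {structure!r}")
        try:
            contour = ContourPolygon(structure, rec["rings"])
        except ValidationError as exc:
            raise FormatError(
                f"{loc} (slice {rec['slice_index']}, phase {rec['phase']}, "
                f"structure {structure}): {exc}"
            ) from exc
        key = (int(rec["slice_index"]), str(rec["phase"]))
        slot = grouped.setdefault(key, {})
        if structure in slot:
            raise FormatError(
                f"{loc}: duplicate contour for slice {key[0]}, phase {key[1]}, "
                f"structure {structure}"
            )
        slot[structure] = contour

    max_index = max((idx for idx, _ in grouped), default=0)
    if slice_order == "base_to_apex":

        def flip(idx: int, phase: str) -> int:
            if phase in phase_grids:
                lo, hi = phase_grids[phase]
                return int(lo) + int(hi) - idx
            return max_index - idx

        grouped = {
            (flip(idx, phase), phase): contours
            for (idx, phase), contours in grouped.items()
        }

    slices = [
        SliceAnnotation(slice_index=idx, phase=phase, contours=contours)
        for (idx, phase), contours in sorted(grouped.items())
    ]
    image_shape = doc.get("image_shape")
    try:
        return ContourStack(
            case_id=str(_require(doc, "case_id", path)),
            reader_id=str(_require(doc, "reader_id", path)),
            pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
            slice_thickness_mm=float(_require(doc, "slice_thickness_mm", path)),
            slice_gap_mm=float(_require(doc, "slice_gap_mm", path)),
            slices=slices,
            image_shape=tuple(image_shape) if image_shape else None,
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# mask <-> contour conversion
# ---------------------------------------------------------------------------

def _binary_to_loops(binary: np.ndarray) -> list[np.ndarray]:
    """Closed subpixel iso-contours (level 0.5) of a binary image, as [x, y] rings."""
    padded = np.pad(binary.astype(float), 1)
    loops = []
    for rc in measure.find_contours(padded, level=0.5):
        if len(rc) < 4 or not np.allclose(rc[0], rc[-1]):
            continue  # open contour: cannot form a polygon
        ring = rc[:-1][:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding
        if len(ring) >= 3:
            loops.append(ring)
    return loops


def _loops_to_polygon(
    loops: list[np.ndarray], structure: str, keep_largest: bool
) -> ContourPolygon | None:
    """Assemble marching-squares loops into a single contour polygon.

    Loops are classified by absolute area; the largest becomes the outer
    ring and loops nested inside it become holes. With ``keep_largest``
    unset, more than one top-level loop is a format violation because the
    data model stores one polygon per structure.
    """
    if not loops:
        return None
    from shapely.geometry import Point, Polygon as ShapelyPolygon

    oriented = []
    for loop in loops:
        if shoelace_area(loop) < 0:
            loop = loop[::-1]
        oriented.append(loop)
    oriented.sort(key=lambda r: abs(shoelace_area(r)), reverse=True)
    outer = oriented[0]
    outer_poly = ShapelyPolygon(outer)
    holes, others = [], []
    for loop in oriented[1:]:
        if outer_poly.contains(Point(loop[0])):
            holes.append(loop[::-1])  # holes need negative orientation
        else:
            others.append(loop)
    if others and not keep_largest:
        raise FormatError(
            f"structure {structure}: {1 + len(others)} disconnected polygons found; "
            "enable keep_largest to apply largest-polygon postprocessing"
        )
    return ContourPolygon(structure, [outer, *holes])


def mask_to_contours(
    mask: np.ndarray,
    *,
    keep_largest: bool = True,
    slice_index: int = 0,
    phase: str = "ED",
) -> SliceAnnotation:
    """Vectorise a label mask into subpixel contours.

    The LV epicardial contour is reconstructed as the boundary of the union
    of the blood-pool and myocardium labels (1 and 2).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise FormatError(f"label mask must be 2D, got shape {mask.shape}")
    bad = set(np.unique(mask)) - {0, 1, 2, 3}
    if bad:
        raise FormatError(f"label mask contains invalid labels {sorted(bad)}")

    binaries = {
        "lv_endo": mask == 1,
        "lv_epi": (mask == 1) | (mask == 2),
        "rv_endo": mask == 3,
    }
    contours = {}
    for structure, binary in binaries.items():
        if not binary.any():
            continue
        poly = _loops_to_polygon(_binary_to_loops(binary), structure, keep_largest)
        if poly is not None:
            contours[structure] = poly
    return SliceAnnotation(slice_index=slice_index, phase=phase, contours=contours)


def contours_to_mask(ann: SliceAnnotation, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a slice annotation to a label mask.

    A pixel belongs to a region when the polygon covers its centre (boundary
    points count as inside). Myocardium pixels are inside the epicardial and
    outside the endocardial contour.
    """
    import shapely

    rows, cols = int(shape[0]), int(shape[1])
    for structure, contour in ann.contours.items():
        xs_all = np.concatenate([r[:, 0] for r in contour.rings])
        ys_all = np.concatenate([r[:, 1] for r in contour.rings])
        if (
            xs_all.min() < -0.5
            or ys_all.min() < -0.5
            or xs_all.max() > cols - 0.5
            or ys_all.max() > rows - 0.5
        ):
            raise ValidationError(
                f"contour {structure} exceeds image bounds {rows}x{cols}"
            )

    mask = np.zeros((rows, cols), dtype=np.uint8)
    if not ann.contours:
        return mask
    yy, xx = np.mgrid[0:rows, 0:cols]
    xs, ys = xx.ravel().astype(float), yy.ravel().astype(float)

    def covered(structure: str) -> np.ndarray:
        contour = ann.contours.get(structure)
        if contour is None:
            return np.zeros(rows * cols, dtype=bool)
        return shapely.intersects_xy(contour.to_shapely(), xs, ys)

    endo = covered("lv_endo")
    epi = covered("lv_epi")
    rv = covered("rv_endo")
    flat = mask.ravel()
    flat[epi & ~endo] = LABELS["lvm"]
    flat[endo] = LABELS["lv_endo"]
    flat[rv] = LABELS["rv_endo"]
    return flat.reshape(rows, cols)


# ---------------------------------------------------------------------------
# raster file I/O
# ---------------------------------------------------------------------------

def read_label_mask(path, expected_spacing=None) -> tuple[np.ndarray, tuple | None]:
    """Read a 2D label mask from PNG or NIfTI.

    Returns ``(mask, spacing)`` where spacing is ``(row, col)`` mm/pixel from
    the NIfTI header (``None`` for PNG). When ``expected_spacing`` is given,
    a header spacing must match it to within 1e-6 mm.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        if data.ndim != 2:
            raise FormatError(f"{path}: expected a 2D label volume, got {data.shape}")
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]), float(zooms[1]))
        if expected_spacing is not None and not np.allclose(
            spacing, expected_spacing, atol=1e-6
        ):
            raise FormatError(
                f"{path}: NIfTI spacing {spacing} does not match header "
                f"spacing {tuple(expected_spacing)}"
            )
        return data.astype(np.uint8), spacing
    # PNG (or any 8-bit raster imageio can read)
    import imageio.v3 as iio

    data = iio.imread(path)
    if data.ndim == 3:
        data = data[..., 0]
    return data.astype(np.uint8), None


def write_label_mask(mask: np.ndarray, path, spacing=None) -> None:
    """Write a 2D label mask to PNG or NIfTI (chosen by file extension)."""
    path = Path(path)
    mask = np.asarray(mask, dtype=np.uint8)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        if spacing is not None:
            affine[0, 0], affine[1, 1] = spacing[0], spacing[1]
        nib.save(nib.Nifti1Image(mask, affine), str(path))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, mask)
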