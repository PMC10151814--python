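"""Core geometric data model for subpixel cardiac contour annotations.

Contours are stored as polygons in 0-based pixel coordinates (x = column,
y = row, subpixel floats). Physical quantities are obtained by scaling the
coordinates with the anisotropic pixel spacing before any distance or area
computation, so all metrics downstream are in mm / mm² / ml.

Structures follow the short-axis annotation convention: the left-ventricular
endocardial border (``lv_endo``) encloses the blood pool (papillary muscles
and trabeculae included), the epicardial border (``lv_epi``) together with it
delimits the myocardium, and ``rv_endo`` encloses the right-ventricular blood
pool. The myocardium (``lvm``) is always a derived entity — epicardial
polygon minus endocardial polygon — and never stored directly.

Slice index 0 is the most apical acquired slice; indices increase toward the
base. File readers normalise any other acquisition order to this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import (
    ContainmentError,
    DegenerateGeometryError,
    PhaseError,
    ValidationError,
)

#: Structures a reader may annotate on a slice.
STRUCTURES = ("lv_endo", "lv_epi", "rv_endo")

#: Entities metrics are computed for (myocardium is derived, epi is not
#: evaluated on its own).
ENTITIES = ("lv_endo", "lvm", "rv_endo")

#: Cardiac phases carrying annotations in this study design.
PHASES = ("ED", "ES")

#: Relative tolerance for the endo-inside-epi containment check: the part of
#: the endocardial area lying outside the epicardium must stay below this
#: fraction of the endocardial area.
CONTAINMENT_TOLERANCE = 0.01


def shoelace_area(ring: np.ndarray) -> float:
    """Signed shoelace area of a closed ring given as an (n, 2) [x, y] array.

    The first vertex is not repeated at the end; closure is implicit.
    Positive for counter-clockwise rings in (x, y).
    """
    ring = np.asarray(ring, dtype=float)
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _as_ring(vertices: Sequence, *, context: str = "") -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError(f"ring must be an (n, 2) array of [x, y] vertices {context}")
    if arr.shape[0] < 3:
        raise DegenerateGeometryError(
            f"ring has {arr.shape[0]} vertices; at least 3 required {context}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"ring contains non-finite coordinates {context}")
    return arr


@dataclass(frozen=True)
class ContourPolygon:
    """One structure's contour on one slice/phase: outer ring plus optional holes.

    Parameters
    ----------
    structure
        One of :data:`STRUCTURES`.
    rings
        Ordered vertex arrays ``(n, 2)`` of ``[x, y]`` pixel coordinates.
        The first ring is the outer boundary (positive shoelace area);
        subsequent rings are holes (negative shoelace area) lying inside it.
    """

    structure: str
    rings: tuple[np.ndarray, ...]

    def __init__(self, structure: str, rings: Iterable[Sequence]):
        if structure not in STRUCTURES:
            raise ValidationError(
                f"unknown structure {structure!r}; expected one of {STRUCTURES}"
            )
        rings = tuple(
            _as_ring(r, context=f"(structure={structure}, ring {i})")
            for i, r in enumerate(rings)
        )
        if not rings:
            raise DegenerateGeometryError(f"contour for {structure} has no rings")
        if shoelace_area(rings[0]) <= 0:
            raise DegenerateGeometryError(
                f"outer ring of {structure} must have positive signed area"
            )
        for i, hole in enumerate(rings[1:], start=1):
            if shoelace_area(hole) >= 0:
                raise DegenerateGeometryError(
                    f"hole ring {i} of {structure} must have negative signed area"
                )
        poly = Polygon(rings[0], holes=[h for h in rings[1:]])
        if not poly.is_valid:
            raise DegenerateGeometryError(
                f"contour for {structure} is not a simple polygon: "
                f"{shapely.is_valid_reason(poly)}"
            )
        object.__setattr__(self, "structure", structure)
        object.__setattr__(self, "rings", rings)

    # -- geometry ---------------------------------------------------------

    def to_shapely(self, spacing: tuple[float, float] = (1.0, 1.0)) -> Polygon:
        """Shapely polygon in physical coordinates (x·col-spacing, y·row-spacing)."""
        sy, sx = float(spacing[0]), float(spacing[1])
        scale = np.array([sx, sy])
        return Polygon(
            self.rings[0] * scale, holes=[h * scale for h in self.rings[1:]]
        )

    def translated(self, dx: float, dy: float) -> "ContourPolygon":
        shift = np.array([dx, dy], dtype=float)
        return ContourPolygon(self.structure, [r + shift for r in self.rings])

    def centroid(self) -> np.ndarray:
        """Area centroid of the outer ring, pixel coordinates."""
        c = Polygon(self.rings[0]).centroid
        return np.array([c.x, c.y])


def polygon_area(poly: ContourPolygon, spacing: tuple[float, float] = (1.0, 1.0)) -> float:
    """Area of a contour polygon in mm² (outer ring minus holes).

    ``spacing`` is ``(row_spacing, col_spacing)`` in mm/pixel; the shoelace
    area in pixel units is scaled by their product, which is exact for
    anisotropic grids because area scales linearly in each axis.
    """
    sy, sx = float(spacing[0]), float(spacing[1])
    if sy <= 0 or sx <= 0:
        raise ValidationError(f"pixel spacing must be positive, got {spacing!r}")
    signed = sum(shoelace_area(r) for r in poly.rings)
    area = signed * sy * sx
    if area < 0:
        raise DegenerateGeometryError(
            f"holes exceed outer ring area for {poly.structure}"
        )
    return area


def resample_boundary(poly: ContourPolygon, max_step: float) -> list[np.ndarray]:
    """Densify every ring so consecutive boundary points are ≤ ``max_step`` apart.

    Returns one ``(m, 2)`` array per ring (outer first). All original
    vertices are retained; extra points are placed evenly along each edge.
    ``max_step`` is a distance in the same units as the coordinates.
    """
    if max_step <= 0:
        raise ValidationError("max_step must be positive")
    out = []
    for ring in poly.rings:
        pts: list[np.ndarray] = []
        n = len(ring)
        for i in range(n):
            p = ring[i]
            q = ring[(i + 1) % n]
            pts.append(p)
            edge = q - p
            length = float(np.hypot(edge[0], edge[1]))
            k = int(np.ceil(length / max_step))
            for j in range(1, k):
                pts.append(p + edge * (j / k))
        out.append(np.asarray(pts))
    return out


@dataclass
class SliceAnnotation:
    """One reader's contours on a single slice and cardiac phase."""

    slice_index: int
    phase: str
    contours: dict[str, ContourPolygon] = field(default_factory=dict)

    def __post_init__(self):
        for key, contour in self.contours.items():
            if key not in STRUCTURES:
                raise ValidationError(f"unknown structure key {key!r}")
            if contour.structure != key:
                raise ValidationError(
                    f"contour labelled {contour.structure!r} stored under key {key!r}"
                )
        self._check_containment()

    def _check_containment(self):
        endo = self.contours.get("lv_endo")
        epi = self.contours.get("lv_epi")
        if endo is None or epi is None:
            return
        endo_poly = endo.to_shapely()
        epi_poly = epi.to_shapely()
        outside = endo_poly.difference(epi_poly).area
        if endo_poly.area > 0 and outside > CONTAINMENT_TOLERANCE * endo_poly.area:
            raise ContainmentError(
                f"lv_endo extends outside lv_epi by {outside:.3g} px² "
                f"({100 * outside / endo_poly.area:.2f}% of endo area) on slice "
                f"{self.slice_index}, phase {self.phase}"
            )

    def has(self, structure: str) -> bool:
        return structure in self.contours


@dataclass
class ContourStack:
    """One reader's full annotation of one case: slices × phases × structures."""

    case_id: str
    reader_id: str
    pixel_spacing_mm: tuple[float, float]  # (row, col) mm/pixel
    slice_thickness_mm: float
    slice_gap_mm: float
    slices: list[SliceAnnotation] = field(default_factory=list)
    image_shape: tuple[int, int] | None = None  # (rows, cols), optional

    def __post_init__(self):
        sy, sx = self.pixel_spacing_mm
        if sy <= 0 or sx <= 0:
            raise ValidationError("pixel_spacing_mm components must be > 0")
        if self.slice_thickness_mm <= 0:
            raise ValidationError("slice_thickness_mm must be > 0")
        if self.slice_gap_mm < 0:
            raise ValidationError("slice_gap_mm must be >= 0")
        self._index: dict[tuple[int, str], SliceAnnotation] = {}
        for ann in self.slices:
            key = (ann.slice_index, ann.phase)
            if key in self._index:
                raise ValidationError(
                    f"duplicate annotation for slice {ann.slice_index}, phase {ann.phase}"
                )
            self._index[key] = ann
        for phase in self.phases:
            idx = sorted(self.slice_indices(phase))
            if idx and idx != list(range(idx[0], idx[-1] + 1)):
                raise ValidationError(
                    f"slice indices for phase {phase} are not contiguous: {idx}"
                )

    # -- accessors --------------------------------------------------------

    @property
    def phases(self) -> tuple[str, ...]:
        return tuple(sorted({ann.phase for ann in self.slices}))

    @property
    def slice_spacing_mm(self) -> float:
        """Centre-to-centre slice spacing used in disc summation."""
        return self.slice_thickness_mm + self.slice_gap_mm

    def slice_indices(self, phase: str) -> list[int]:
        return sorted(a.slice_index for a in self.slices if a.phase == phase)

    def annotation(self, slice_index: int, phase: str) -> SliceAnnotation | None:
        return self._index.get((slice_index, phase))

    def segmented_indices(self, structure: str, phase: str) -> list[int]:
        """Slice indices where this reader drew the given structure in ``phase``."""
        return sorted(
            a.slice_index
            for a in self.slices
            if a.phase == phase and a.has(structure)
        )

    def require_phase(self, phase: str):
        if phase not in self.phases:
            raise PhaseError(
                f"case {self.case_id}: phase {phase!r} is not annotated "
                f"(available: {self.phases})"
            )

    def same_grid_as(self, other: "ContourStack") -> bool:
        return (
            self.phases == other.phases
            and all(
                self.slice_indices(p) == other.slice_indices(p) for p in self.phases
            )
            and np.allclose(self.pixel_spacing_mm, other.pixel_spacing_mm)
            and np.isclose(self.slice_thickness_mm, other.slice_thickness_mm)
            and np.isclose(self.slice_gap_mm, other.slice_gap_mm)
        )


@dataclass(frozen=True)
class RegionSpec:
    """Derived planar region for metric computation, in physical mm coordinates.

    For ``lv_endo``/``rv_endo`` this is the filled contour; for ``lvm`` it is
    the epicardial polygon minus the endocardial polygon (a ring with a hole).
    """

    entity: str
    geometry: Polygon
    spacing: tuple[float, float]

    @property
    def area_mm2(self) -> float:
        return self.geometry.area

    def boundary_rings(self) -> list[np.ndarray]:
        """All boundary rings (exterior + interiors) as (n, 2) mm-coordinate arrays."""
        rings = [np.asarray(self.geometry.exterior.coords)[:-1]]
        rings.extend(np.asarray(i.coords)[:-1] for i in self.geometry.interiors)
        return rings


def build_region(
    ann: SliceAnnotation,
    entity: str,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> RegionSpec | None:
    """Build the planar region for ``entity`` on a slice, or ``None`` if absent.

    The myocardium region exists only when both epicardial and endocardial
    contours are present; an endocardium protruding outside the epicardium
    beyond the containment tolerance raises :class:`ContainmentError`.
    """
    if entity not in ENTITIES:
        raise ValidationError(f"unknown entity {entity!r}; expected one of {ENTITIES}")
    if entity in ("lv_endo", "rv_endo"):
        contour = ann.contours.get(entity)
        if contour is None:
            return None
        return RegionSpec(entity, contour.to_shapely(spacing), tuple(spacing))
    # lvm
    epi = ann.contours.get("lv_epi")
    endo = ann.contours.get("lv_endo")
    if epi is None or endo is None:
        return None
    epi_poly = epi.to_shapely(spacing)
    endo_poly = endo.to_shapely(spacing)
    outside = endo_poly.difference(epi_poly).area
    if endo_poly.area > 0 and outside > CONTAINMENT_TOLERANCE * endo_poly.area:
        raise ContainmentError(
            f"lv_endo not contained in lv_epi on slice {ann.slice_index}, "
            f"phase {ann.phase}"
        )
    ring = epi_poly.difference(endo_poly)
    if ring.geom_type == "MultiPolygon":  # numerically sliver-split ring
        ring = max(ring.geoms, key=lambda g: g.area)
    return RegionSpec("lvm", ring, tuple(spacing))
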