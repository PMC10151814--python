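# Contour-stack JSON format, schema version "1"

A contour stack is one reader's full annotation of one case: subpixel
polygon contours for up to three structures on a slice × phase grid.
The document is a single JSON object.

## Header fields

| field | type | meaning |
|---|---|---|
| `schema_version` | string | always `"1"` |
| `case_id` | string | case identifier |
| `reader_id` | string | annotating reader (expert, network name, ...) |
| `pixel_spacing_mm` | `[row, col]` floats > 0 | in-plane resolution, mm/pixel |
| `slice_thickness_mm` | float > 0 | slice thickness |
| `slice_gap_mm` | float ≥ 0 | inter-slice gap (0 for contiguous stacks) |
| `slice_order` | `"apex_to_base"` or `"base_to_apex"` | index direction on disk; normalised to apex_to_base (slice 0 = most apical) on read |
| `image_shape` | `[rows, cols]` or `null` | raster dimensions, required for rasterisation |
| `phase_grids` | `{phase: [min_index, max_index]}` | acquired slice range per phase, including unsegmented slices |
| `contours` | array of records | see below |

## Contour records

Each record is one structure's polygon on one slice and phase:

```json
{
  "slice_index": 4,
  "phase": "ED",
  "structure": "lv_endo",
  "rings": [[[x, y], [x, y], ...], ...]
}
```

* `structure` ∈ `{"lv_endo", "lv_epi", "rv_endo"}`.
* `phase`: `"ED"` and `"ES"` carry clinical meaning; other labels are
  allowed but ignored by parameter computation.
* `rings`: the first ring is the outer boundary (counter-clockwise in
  (x, y), i.e. positive shoelace area), subsequent rings are holes
  (clockwise) inside it. Rings are implicitly closed — the first vertex is
  not repeated — and must have ≥ 3 vertices and be simple.
* Coordinates are 0-based pixel coordinates, x = column, y = row, subpixel
  floats at the image's original resolution.
* At most one record per (slice, phase, structure).

## Determinism

Writers emit keys sorted, records sorted by (slice_index, phase,
structure), and floats in shortest round-trip notation, so identical
stacks serialise to identical bytes and a write→read cycle reproduces
every vertex bit-exactly.
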