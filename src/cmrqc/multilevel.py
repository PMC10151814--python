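"""Multilevel breakdown of segmentation agreement by slice position.

Slice positions are anchored to the expert (reference) reader, per structure
and per phase: the expert's most basal segmented slice — plus any slices
above it that the evaluated reader segmented (incorrectly) — form the basal
block; symmetrically at the apex; everything strictly between the two
anchors is midventricular. When the expert segmented nothing, no anchor
exists and all slices are unassigned (the evaluated reader's false-positive
slices are still reported in the unassigned bucket).

Two Dice averaging conventions are provided: ``all_slices`` includes the
convention values (100% for slices segmented by neither reader, 0% for
slices segmented by only one) and reports the mean only, because the zero
values distort the distribution; ``both_only`` restricts to slices segmented
by both readers and reports mean ± sd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contour_model import ENTITIES, PHASES, ContourStack
from .errors import AlignmentError
from .geom_metrics import (
    DEFAULT_MAX_STEP_PX,
    SliceComparison,
    StackMeta,
    compare_slice,
)

POSITIONS = ("basal", "midventricular", "apical")


@dataclass(frozen=True)
class ReaderPair:
    """Expert (reference) and evaluated reader stacks on an identical grid."""

    expert: ContourStack
    reader: ContourStack

    def __post_init__(self):
        if not self.expert.same_grid_as(self.reader):
            raise AlignmentError(
                f"case {self.expert.case_id}: expert and reader stacks do not "
                "share the same slice/phase grid and geometry"
            )


@dataclass
class DecisionConfusion:
    """Slice-level segmentation-decision counts for one bucket (expert = truth)."""

    tp: int = 0  # segmented by both
    fp: int = 0  # reader only
    fn: int = 0  # expert only
    tn: int = 0  # neither

    @property
    def precision_pct(self) -> float | None:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else None

    @property
    def recall_pct(self) -> float | None:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else None


def classify_slice_positions(
    expert: ContourStack, reader: ContourStack, entity: str, phase: str
) -> dict[int, str]:
    """Position label per slice index for one entity and phase.

    Returns a mapping over the full slice grid with values in
    ``{"basal", "midventricular", "apical", "unassigned"}``.
    """
    if not expert.same_grid_as(reader):
        raise AlignmentError("stacks are not on the same slice/phase grid")
    grid = expert.slice_indices(phase)
    expert_idx = set(_segmented(expert, entity, phase))
    reader_idx = set(_segmented(reader, entity, phase))
    if not expert_idx:
        return {s: "unassigned" for s in grid}
    base_anchor = max(expert_idx)
    apex_anchor = min(expert_idx)
    labels = {}
    for s in grid:
        if s == base_anchor or (s > base_anchor and s in reader_idx):
            labels[s] = "basal"
        elif s == apex_anchor or (s < apex_anchor and s in reader_idx):
            labels[s] = "apical"
        elif apex_anchor < s < base_anchor:
            labels[s] = "midventricular"
        else:
            labels[s] = "unassigned"
    return labels


def _segmented(stack: ContourStack, entity: str, phase: str) -> list[int]:
    """Slices where the entity exists; lvm requires both epi and endo."""
    if entity == "lvm":
        epi = set(stack.segmented_indices("lv_epi", phase))
        endo = set(stack.segmented_indices("lv_endo", phase))
        return sorted(epi & endo)
    return stack.segmented_indices(entity, phase)


def decision_metrics(
    expert: ContourStack,
    reader: ContourStack,
    entity: str,
    phase: str,
    labels: dict[int, str] | None = None,
) -> dict[str, DecisionConfusion]:
    """Per-position decision confusion, plus an ``overall`` bucket.

    tp = both segmented, fp = reader only, fn = expert only, tn = neither;
    precision and recall are exposed on each bucket and are ``None`` (an
    undefined marker, never 0) when their denominator is empty.
    """
    if labels is None:
        labels = classify_slice_positions(expert, reader, entity, phase)
    expert_idx = set(_segmented(expert, entity, phase))
    reader_idx = set(_segmented(reader, entity, phase))
    buckets = {pos: DecisionConfusion() for pos in (*POSITIONS, "unassigned", "overall")}
    for s, pos in labels.items():
        in_e, in_r = s in expert_idx, s in reader_idx
        for bucket in (buckets[pos], buckets["overall"]):
            if in_e and in_r:
                bucket.tp += 1
            elif in_r:
                bucket.fp += 1
            elif in_e:
                bucket.fn += 1
            else:
                bucket.tn += 1
    return buckets


def dice_average(
    records: list[SliceComparison], convention: str
) -> tuple[float | None, float | None]:
    """Bucket-level Dice average under one of the two conventions.

    ``all_slices`` averages every record including convention values and
    returns ``(mean, None)`` — no sd is reported for this convention.
    ``both_only`` averages records with decision ``both`` and returns
    ``(mean, sd)`` (sample sd; ``None`` with fewer than two records).
    Empty selections return ``(None, None)``.
    """
    if convention == "all_slices":
        values = [r.dice_pct for r in records]
        if not values:
            return None, None
        return float(np.mean(values)), None
    if convention == "both_only":
        values = [r.dice_pct for r in records if r.decision == "both"]
        if not values:
            return None, None
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
        return float(np.mean(values)), sd
    raise ValueError(f"unknown Dice convention {convention!r}")


def compare_stacks(
    pair: ReaderPair, *, max_step: float = DEFAULT_MAX_STEP_PX
) -> list[SliceComparison]:
    """Per-slice comparison records over all entities, phases and grid slices.

    Every record carries its position label (anchored to the expert) so the
    stratified tables can be built by simple grouping.
    """
    expert, reader = pair.expert, pair.reader
    meta = StackMeta.from_stack(expert)
    records = []
    for entity in ENTITIES:
        for phase in expert.phases:
            labels = classify_slice_positions(expert, reader, entity, phase)
            for s in expert.slice_indices(phase):
                rec = compare_slice(
                    expert.annotation(s, phase),
                    reader.annotation(s, phase),
                    entity,
                    meta,
                    max_step=max_step,
                    slice_index=s,
                    phase=phase,
                )
                rec.position = labels[s]
                rec.case_id = expert.case_id
                records.append(rec)
    return records


def _aggregate_bucket(records: list[SliceComparison]) -> dict:
    """StratifiedTable row fields for one (entity, position) bucket."""
    conf = DecisionConfusion()
    for r in records:
        if r.decision == "both":
            conf.tp += 1
        elif r.decision == "only_b":
            conf.fp += 1
        elif r.decision == "only_a":
            conf.fn += 1
        else:
            conf.tn += 1
    dice_all, _ = dice_average(records, "all_slices")
    dice_both, dice_both_sd = dice_average(records, "both_only")
    hds = [r.hausdorff_mm for r in records if r.hausdorff_mm is not None]
    # per-slice volume error is reported over slices segmented by at least
    # one reader; neither-slices carry no volumetric information
    vols = [r.abs_volume_diff_ml for r in records if r.decision != "neither"]
    return {
        "n_slices": len(records),
        "tp": conf.tp,
        "fp": conf.fp,
        "fn": conf.fn,
        "tn": conf.tn,
        "precision_pct": conf.precision_pct,
        "recall_pct": conf.recall_pct,
        "dice_all_pct": dice_all,
        "dice_both_mean_pct": dice_both,
        "dice_both_sd_pct": dice_both_sd,
        "hd_mean_mm": float(np.mean(hds)) if hds else None,
        "hd_sd_mm": float(np.std(hds, ddof=1)) if len(hds) > 1 else None,
        "abs_vol_diff_mean_ml": float(np.mean(vols)) if vols else None,
        "abs_vol_diff_sd_ml": float(np.std(vols, ddof=1)) if len(vols) > 1 else None,
    }


def stratified_table(records: list[SliceComparison]) -> pd.DataFrame:
    """Position-stratified metric table from per-slice records.

    Rows: (entity, position) for the three entities × basal/mid/apical,
    pooling ED and ES, plus ``overall`` rows pooling the entities per
    position. Unassigned slices are reported in separate rows when present.
    """
    rows = {}
    for entity in ENTITIES:
        for pos in POSITIONS:
            sel = [r for r in records if r.entity == entity and r.position == pos]
            rows[(entity, pos)] = _aggregate_bucket(sel)
        unassigned = [
            r
            for r in records
            if r.entity == entity
            and r.position == "unassigned"
            and r.decision != "neither"
        ]
        if unassigned:
            rows[(entity, "unassigned")] = _aggregate_bucket(unassigned)
    for pos in POSITIONS:
        sel = [r for r in records if r.position == pos]
        rows[("overall", pos)] = _aggregate_bucket(sel)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["entity", "position"])
    return df


def stratified_metrics(
    pair: ReaderPair, *, max_step: float = DEFAULT_MAX_STEP_PX
) -> pd.DataFrame:
    """End-to-end stratified table for one aligned reader pair."""
    return stratified_table(compare_stacks(pair, max_step=max_step))
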