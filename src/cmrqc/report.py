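"""End-to-end comparison driver and report generation.

``compare_readers`` runs the full pipeline for one or more evaluated readers
against the expert: per-case clinical parameters, per-slice geometric
comparison records with position labels, position-stratified tables,
per-parameter statistical comparisons, optional equivalence tests against
configured tolerance intervals, and — when at least two evaluated readers
are supplied — ICC(3,1) among the readers and among readers + expert.

``build_report`` writes the result as CSV tables with a JSON metadata
sidecar plus static figures: candlelight boxplots of parameter errors and
Dice values, correlation scatter plots of per-slice volume difference vs
Dice coloured by slice position (decision errors sit on the Dice-0
baseline; perfect and neither-slices collapse to the top-centre point),
Bland-Altman panels, and a CI-vs-tolerance equivalence chart. A point index
file maps every scatter point back to (case, slice, phase, entity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical_params import PARAM_COLUMNS, params_table
from .contour_model import ContourStack
from .errors import AlignmentError, IOFailure
from .geom_metrics import DEFAULT_MAX_STEP_PX
from .multilevel import ReaderPair, compare_stacks, stratified_table
from .stats import compare_clinical, equivalence_test, fisher_z_mean, icc_3_1

#: Human-readable labels for figures.
PARAM_LABELS = {
    "lvedv_ml": "LVEDV [ml]",
    "lvesv_ml": "LVESV [ml]",
    "lvef_pct": "LVEF [%]",
    "rvedv_ml": "RVEDV [ml]",
    "rvesv_ml": "RVESV [ml]",
    "rvef_pct": "RVEF [%]",
    "lvm_g": "LVM [g]",
}

POSITION_COLORS = {
    "basal": "tab:red",
    "midventricular": "tab:green",
    "apical": "tab:blue",
    "unassigned": "tab:gray",
}


@dataclass
class ComparisonResult:
    """Container for a full multi-reader comparison run."""

    expert_params: pd.DataFrame
    reader_params: dict[str, pd.DataFrame]
    slice_records: pd.DataFrame  # all readers, column reader_id
    stratified: dict[str, pd.DataFrame]
    param_comparisons: dict[str, pd.DataFrame]
    equivalence: dict[str, pd.DataFrame] | None
    icc: pd.DataFrame | None
    metadata: dict = field(default_factory=dict)

    @property
    def reader_ids(self) -> list[str]:
        return sorted(self.reader_params)

    def pooled_correlation(self, reader_id: str) -> float:
        """Fisher-z pooled Pearson correlation over the seven parameters.

        Undefined (NaN) and exactly-perfect correlations are excluded from
        pooling: the Fisher transform is infinite at |r| = 1.
        """
        rs = self.param_comparisons[reader_id]["pearson_r"].to_numpy()
        rs = rs[np.isfinite(rs) & (np.abs(rs) < 1.0)]
        return fisher_z_mean(rs)


def _records_frame(records, reader_id: str) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "reader_id": reader_id,
                "case_id": r.case_id,
                "slice_index": r.slice_index,
                "phase": r.phase,
                "entity": r.entity,
                "position": r.position,
                "decision": r.decision,
                "dice_pct": r.dice_pct,
                "hausdorff_mm": r.hausdorff_mm,
                "area_a_mm2": r.area_a_mm2,
                "area_b_mm2": r.area_b_mm2,
                "volume_diff_ml": r.volume_diff_ml,
                "abs_volume_diff_ml": r.abs_volume_diff_ml,
            }
            for r in records
        ]
    )
    return df


def compare_readers(
    expert_stacks: list[ContourStack],
    reader_sets: dict[str, list[ContourStack]],
    tolerances: dict[str, tuple[float, float]] | None = None,
    *,
    max_step: float = DEFAULT_MAX_STEP_PX,
) -> ComparisonResult:
    """Run the full comparison pipeline for every evaluated reader.

    ``reader_sets`` maps a reader id to its stacks; cases must match the
    expert's case ids one-to-one and share each case's slice/phase grid.
    ``tolerances`` maps parameter names to (low, high) tolerance intervals
    for the equivalence tests.
    """
    expert_by_case = {s.case_id: s for s in expert_stacks}
    expert_df = params_table(expert_stacks)

    reader_params: dict[str, pd.DataFrame] = {}
    stratified: dict[str, pd.DataFrame] = {}
    comparisons: dict[str, pd.DataFrame] = {}
    equivalence: dict[str, pd.DataFrame] = {}
    record_frames = []

    for reader_id, stacks in sorted(reader_sets.items()):
        by_case = {s.case_id: s for s in stacks}
        if set(by_case) != set(expert_by_case):
            raise AlignmentError(
                f"reader {reader_id}: case ids do not match the expert set: "
                f"{sorted(set(by_case) ^ set(expert_by_case))}"
            )
        all_records = []
        for case_id in sorted(expert_by_case):
            pair = ReaderPair(expert_by_case[case_id], by_case[case_id])
            all_records.extend(compare_stacks(pair, max_step=max_step))
        record_frames.append(_records_frame(all_records, reader_id))
        stratified[reader_id] = stratified_table(all_records)
        reader_params[reader_id] = params_table(stacks)
        comparisons[reader_id] = compare_clinical(expert_df, reader_params[reader_id])
        if tolerances:
            rows = []
            for param, tol in tolerances.items():
                diffs = (
                    reader_params[reader_id][param] - expert_df[param]
                ).to_numpy()
                res = equivalence_test(diffs, tol, parameter=param)
                rows.append(asdict(res))
            equivalence[reader_id] = pd.DataFrame(rows).set_index("parameter")

    icc_df = None
    if len(reader_sets) >= 2:
        rows = []
        ids = sorted(reader_sets)
        for param in PARAM_COLUMNS:
            grid = np.column_stack(
                [reader_params[r][param].loc[expert_df.index] for r in ids]
            )
            res = icc_3_1(grid)
            grid_with_expert = np.column_stack([grid, expert_df[param]])
            res_e = icc_3_1(grid_with_expert)
            rows.append(
                {
                    "parameter": param,
                    "icc_readers": res.icc,
                    "ci_low_readers": res.ci_low,
                    "ci_high_readers": res.ci_high,
                    "icc_with_expert": res_e.icc,
                    "ci_low_with_expert": res_e.ci_low,
                    "ci_high_with_expert": res_e.ci_high,
                    "n_subjects": res.n_subjects,
                }
            )
        icc_df = pd.DataFrame(rows).set_index("parameter")

    metadata = {
        "cmrqc_version": __version__,
        "n_cases": len(expert_stacks),
        "readers": sorted(reader_sets),
        "hausdorff_max_step_px": max_step,
        "tolerances": {k: list(v) for k, v in (tolerances or {}).items()},
        "conventions": {
            "dice_neither_pct": 100.0,
            "dice_one_only_pct": 0.0,
            "lvm_hausdorff_rings": "epicardial+endocardial",
            "equivalence_ci": "t-based, 95%",
            "position_rule": "expert-anchored basal/apical blocks",
        },
    }
    return ComparisonResult(
        expert_params=expert_df,
        reader_params=reader_params,
        slice_records=pd.concat(record_frames, ignore_index=True),
        stratified=stratified,
        param_comparisons=comparisons,
        equivalence=equivalence or None,
        icc=icc_df,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# report files
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, float_format="%.10g", lineterminator="\n")


def build_report(result: ComparisonResult, outdir, figures: bool = True) -> list[Path]:
    """Write the CSV tables, metadata sidecar and figures. Returns written paths."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create report directory {outdir}: {exc}") from exc

    written = []

    def emit(df, name):
        path = outdir / name
        _write_csv(df, path)
        written.append(path)

    emit(result.expert_params, "params_expert.csv")
    for rid in result.reader_ids:
        emit(result.reader_params[rid], f"params_{rid}.csv")
        emit(result.param_comparisons[rid], f"param_comparison_{rid}.csv")
        emit(result.stratified[rid], f"stratified_{rid}.csv")
        if result.equivalence and rid in result.equivalence:
            emit(result.equivalence[rid], f"equivalence_{rid}.csv")
    emit(result.slice_records, "slice_records.csv")
    if result.icc is not None:
        emit(result.icc, "icc.csv")

    meta_path = outdir / "metadata.json"
    meta_path.write_text(json.dumps(result.metadata, indent=2, sort_keys=True) + "\n")
    written.append(meta_path)

    # point index mapping scatter points back to their slice
    index_cols = ["reader_id", "case_id", "slice_index", "phase", "entity",
                  "dice_pct", "volume_diff_ml"]
    point_index = result.slice_records[index_cols].reset_index(names="point_id")
    emit(point_index.set_index("point_id"), "correlation_point_index.csv")

    if figures:
        written.extend(_figures(result, outdir))
    return written


def _figures(result: ComparisonResult, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    written = []

    # candlelight boxplots of per-case parameter errors and Dice values
    fig, axes = plt.subplots(2, 4, figsize=(16, 7))
    for ax, param in zip(axes.flat, PARAM_COLUMNS):
        data = [
            (result.reader_params[r][param] - result.expert_params[param]).to_numpy()
            for r in result.reader_ids
        ]
        ax.boxplot(data, tick_labels=result.reader_ids)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_title(f"{PARAM_LABELS[param]} (reader − expert)", fontsize=9)
    ax = axes.flat[-1]
    positions, labels = [], []
    for i, r in enumerate(result.reader_ids):
        sel = result.slice_records[result.slice_records.reader_id == r]
        both = sel[sel.decision == "both"]["dice_pct"].to_numpy()
        all_slices = sel["dice_pct"].to_numpy()
        ax.boxplot([all_slices, both], positions=[2 * i, 2 * i + 0.8], widths=0.6)
        positions.extend([2 * i, 2 * i + 0.8])
        labels.extend([f"{r}\nall", f"{r}\nboth"])
    ax.set_xticks(positions, labels, fontsize=7)
    ax.set_title("Dice [%] by convention", fontsize=9)
    fig.tight_layout()
    path = outdir / "candlelight_boxplots.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    # correlation plots: volume difference vs Dice, coloured by position
    for rid in result.reader_ids:
        sel = result.slice_records[result.slice_records.reader_id == rid]
        entities = sorted(sel.entity.unique())
        fig, axes = plt.subplots(1, len(entities), figsize=(5 * len(entities), 4),
                                 squeeze=False)
        for ax, entity in zip(axes[0], entities):
            sub = sel[sel.entity == entity]
            for pos, color in POSITION_COLORS.items():
                pts = sub[sub.position == pos]
                if len(pts):
                    ax.scatter(pts.volume_diff_ml, pts.dice_pct, s=12, alpha=0.6,
                               color=color, label=pos)
            ax.set_xlabel("volume difference [ml]")
            ax.set_ylabel("Dice [%]")
            ax.set_ylim(-3, 103)
            ax.set_title(f"{rid}: {entity}", fontsize=9)
            ax.legend(fontsize=6)
        fig.tight_layout()
        path = outdir / f"correlation_{rid}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

        # Bland-Altman panels per parameter
        fig, axes = plt.subplots(2, 4, figsize=(16, 7))
        for ax, param in zip(axes.flat, PARAM_COLUMNS):
            e = result.expert_params[param].to_numpy()
            r = result.reader_params[rid][param].loc[result.expert_params.index].to_numpy()
            mean, diff = (e + r) / 2.0, r - e
            bias = diff.mean()
            sd = diff.std(ddof=1) if len(diff) > 1 else 0.0
            ax.scatter(mean, diff, s=14, alpha=0.7)
            for y, style in ((bias, "-"), (bias - 1.96 * sd, "--"), (bias + 1.96 * sd, "--")):
                ax.axhline(y, color="k", ls=style, lw=0.8)
            ax.set_title(PARAM_LABELS[param], fontsize=9)
        axes.flat[-1].axis("off")
        fig.tight_layout()
        path = outdir / f"bland_altman_{rid}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    # equivalence chart: CI vs tolerance interval
    if result.equivalence:
        fig, ax = plt.subplots(figsize=(8, 5))
        y = 0
        ticks, tick_labels = [], []
        for rid in result.reader_ids:
            eq = result.equivalence.get(rid)
            if eq is None:
                continue
            for param, row in eq.iterrows():
                ax.plot([row.tol_low, row.tol_high], [y, y], color="tab:blue", lw=6,
                        alpha=0.3)
                color = "tab:green" if row.equivalent else "tab:red"
                ax.plot([row.ci_low, row.ci_high], [y, y], color=color, lw=2)
                ax.plot(row.mean_diff, y, "o", color=color, ms=4)
                ticks.append(y)
                tick_labels.append(f"{rid}: {PARAM_LABELS.get(param, param)}")
                y += 1
        ax.set_yticks(ticks, tick_labels, fontsize=7)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("mean difference (reader − expert), 95% CI vs tolerance")
        fig.tight_layout()
        path = outdir / "equivalence.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
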