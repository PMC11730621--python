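"""End-to-end processing: fixation tables -> visit runs -> trial statistics.

Glues the event classification and trial-metric layers together for whole
data sets: every trial's fixation sequence is truncated at the response,
attributed to AOIs, stripped of fixations on unoccupied cells, segmented
into visit runs, and reduced to the four trial statistics.  The result is a
trial-statistics table plus a per-stimulus dwell table, ready for outlier
filtering and the regression stage.
"""

from __future__ import annotations

import logging

import pandas as pd

from .events import (
    DisplayLayout,
    FixationEvent,
    assign_aoi_batch,
    drop_unoccupied,
    segment_runs,
    truncate_at_response,
)
from .inference import AnalysisResults, run_paper_models
from .metrics import FilterReport, filter_outliers, trial_statistics

logger = logging.getLogger(__name__)


def build_layouts(layouts_df: pd.DataFrame) -> dict[str, DisplayLayout]:
    """Reconstruct per-trial display layouts from the layout table.

    Stimulus ids follow row order within a trial; a row with stimulus role
    ``target`` marks the trial's target stimulus.
    """
    out: dict[str, DisplayLayout] = {}
    for trial_id, grp in layouts_df.groupby("trial_id", sort=False):
        cells = []
        target = None
        for s_id, row in enumerate(grp.itertuples()):
            cells.append((int(row.grid_index), float(row.center_x), float(row.center_y)))
            if str(row.stimulus_role) == "target":
                target = s_id
        out[str(trial_id)] = DisplayLayout(
            trial_id=str(trial_id), set_size=len(cells), cells=cells,
            target_stimulus=target,
        )
    return out


def process_trial(
    fixs: list[FixationEvent],
    layout: DisplayLayout,
    rt_ms: float,
    correct: bool,
    participant: int,
    similarity: int,
    truncate: bool = True,
):
    """Classify one trial's fixation sequence and aggregate its statistics."""
    if truncate and rt_ms == rt_ms:  # NaN-safe
        fixs = truncate_at_response(fixs, int(rt_ms))
    fixs = assign_aoi_batch(fixs, layout)
    fixs = drop_unoccupied(fixs, layout)
    runs = segment_runs(fixs)
    return trial_statistics(
        runs, layout, rt_ms, correct, participant=participant, similarity=similarity
    )


def process_dataset(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    layouts: pd.DataFrame,
    truncate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the classification pipeline over a whole study.

    Returns the trial-statistics table (one row per trial, in the input
    trial order) and the per-stimulus first-visit dwell table.  Trials with
    no usable fixations come out with skipping 1 and missing dwelling, with
    a warning tally in the log.
    """
    layout_map = build_layouts(layouts)
    fix_groups = {
        tid: grp.sort_values("onset_ms")
        for tid, grp in fixations.groupby("trial_id", sort=False)
    }
    stat_rows = []
    dwell_rows = []
    n_empty = 0
    for tr in trials.itertuples():
        tid = tr.trial_id
        if tid not in layout_map:
            raise ValueError(f"trial {tid}: no layout rows")
        grp = fix_groups.get(tid)
        fixs = (
            [
                FixationEvent(
                    onset=int(r.onset_ms), duration=int(r.duration_ms),
                    x=float(r.x_px), y=float(r.y_px),
                )
                for r in grp.itertuples()
            ]
            if grp is not None
            else []
        )
        stats, dwells = process_trial(
            fixs, layout_map[tid], tr.rt_ms, bool(tr.correct),
            participant=int(tr.participant), similarity=int(tr.similarity),
            truncate=truncate,
        )
        if not dwells:
            n_empty += 1
        row = stats.__dict__ | {"block": getattr(tr, "block", None),
                                "age": getattr(tr, "age", None)}
        stat_rows.append(row)
        dwell_rows.extend(dwells)
    if n_empty:
        logger.warning("%d trials had no on-stimulus fixations (scored as "
                       "all-skipped)", n_empty)
    stats_df = pd.DataFrame(stat_rows)
    dwells_df = pd.DataFrame(
        dwell_rows,
        columns=["participant", "trial_id", "stimulus_id", "dwell_ms",
                 "is_target", "similarity", "set_size", "target_present"],
    )
    return stats_df, dwells_df


def analyze_dataset(
    trial_stats: pd.DataFrame,
    dwells: pd.DataFrame,
    k_sd: float = 2.0,
    rt_floor: float = 300.0,
    dwell_floor: float = 40.0,
) -> tuple[AnalysisResults, FilterReport, pd.DataFrame]:
    """Filter outliers, then fit the correlation and regression stage."""
    filtered, _, report = filter_outliers(
        trial_stats, dwells, k_sd=k_sd, rt_floor=rt_floor, dwell_floor=dwell_floor
    )
    results = run_paper_models(filtered)
    return results, report, filtered
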