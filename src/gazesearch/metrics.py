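"""Trial-level search statistics and outlier filtering.

Each trial is reduced to four statistics:

* **Dwelling** — mean first-visit dwell time (ms) over the distractors that
  were fixated at all; revisit gaze never counts, so dwelling and revisiting
  stay unconfounded.
* **Skipping** — proportion of stimuli never fixated.
* **Revisiting** — proportion of stimuli fixated again after at least one
  intervening fixation on a different stimulus.
* **RT** — time from display onset to the keypress of a correct answer.

Time measures are log-transformed and filtered per participant within each
target-presence x similarity x set-size cell: values at or above the cell
mean + k SD (one-sided, upper tail — the scheme pairs with explicit bottom
cutoffs) are removed, as are raw values below the floors (300 ms for RT,
40 ms for dwell times).  Dwell filtering operates on individual stimulus
dwells; trial Dwelling is recomputed from the survivors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import DisplayLayout, VisitRun

logger = logging.getLogger(__name__)

#: condition cell used for per-participant outlier statistics
CELL_KEYS = ["participant", "target_present", "similarity", "set_size"]


@dataclass
class TrialStats:
    """The four search statistics of one trial plus its condition labels."""

    participant: int
    trial_id: str
    similarity: int  # 0 = dissimilar, 1 = similar (dummy code)
    set_size: int  # raw value, 5 or 10
    target_present: bool
    correct: bool
    rt_ms: float
    dwelling_ms: float | None  # None when every distractor was skipped
    skipping: float
    revisiting: float


@dataclass
class FilterReport:
    """Tally of what outlier filtering removed, per measure."""

    n_rt_in: int = 0
    n_rt_removed: int = 0
    n_dwell_in: int = 0
    n_dwell_removed: int = 0
    n_cells_skipped: int = 0  # cells too small for the SD rule

    @property
    def rt_removed_prop(self) -> float:
        return self.n_rt_removed / self.n_rt_in if self.n_rt_in else 0.0

    @property
    def dwell_removed_prop(self) -> float:
        return self.n_dwell_removed / self.n_dwell_in if self.n_dwell_in else 0.0

    def as_dict(self) -> dict:
        return {
            "n_rt_in": self.n_rt_in,
            "n_rt_removed": self.n_rt_removed,
            "rt_removed_prop": round(self.rt_removed_prop, 6),
            "n_dwell_in": self.n_dwell_in,
            "n_dwell_removed": self.n_dwell_removed,
            "dwell_removed_prop": round(self.dwell_removed_prop, 6),
            "n_cells_skipped": self.n_cells_skipped,
        }


# ---------------------------------------------------------------------------
# Per-trial aggregation
# ---------------------------------------------------------------------------


def stimulus_dwell(runs: list[VisitRun], stimulus_id: int) -> int | None:
    """Dwell time of one stimulus: gaze of its first (non-revisit) run.

    Returns None for a never-fixated stimulus; revisit runs never contribute.
    """
    for run in runs:
        if run.stimulus_id == stimulus_id and not run.is_revisit:
            return run.gaze_ms
    return None


def trial_statistics(
    runs: list[VisitRun],
    layout: DisplayLayout,
    rt_ms: float,
    correct: bool,
    *,
    participant: int = 0,
    similarity: int = 0,
) -> tuple[TrialStats, list[dict]]:
    """Aggregate a trial's visit runs into its four search statistics.

    Skipping and revisiting are proportions of the trial's ``set_size``
    stimuli, so at set size 5 they can only take multiples of 0.2.  Dwelling
    averages first-visit dwells over *fixated distractors* only: a skipped
    stimulus contributes nothing, and in target-present trials the target's
    dwell is excluded so the statistic remains a pure distractor measure.

    Also returns one record per fixated stimulus (its first-visit dwell),
    the unit at which dwell-time outlier filtering operates.
    """
    m = layout.set_size
    if m <= 0:
        raise ValueError("set_size must be positive")

    fixated: set[int] = set()
    revisited: set[int] = set()
    for run in runs:
        if run.is_revisit:
            revisited.add(run.stimulus_id)
        else:
            fixated.add(run.stimulus_id)

    target = layout.target_stimulus
    dwell_records = []
    distractor_dwells = []
    for sid in sorted(fixated):
        d = stimulus_dwell(runs, sid)
        is_target = target is not None and sid == target
        dwell_records.append(
            {
                "participant": participant,
                "trial_id": layout.trial_id,
                "stimulus_id": sid,
                "dwell_ms": d,
                "is_target": is_target,
                "similarity": similarity,
                "set_size": m,
                "target_present": target is not None,
            }
        )
        if not is_target:
            distractor_dwells.append(d)

    stats = TrialStats(
        participant=participant,
        trial_id=layout.trial_id,
        similarity=similarity,
        set_size=m,
        target_present=target is not None,
        correct=correct,
        rt_ms=float(rt_ms),
        dwelling_ms=float(np.mean(distractor_dwells)) if distractor_dwells else None,
        skipping=(m - len(fixated)) / m,
        revisiting=len(revisited) / m,
    )
    return stats, dwell_records


# ---------------------------------------------------------------------------
# Outlier filtering
# ---------------------------------------------------------------------------


def _upper_sd_mask(values: pd.Series, groups: pd.DataFrame, k_sd: float,
                   report_counter: list[int]) -> pd.Series:
    """True where a (positive) value is an upper-tail log-scale outlier.

    Cell mean/SD are computed once on the pre-filter data of each
    participant x condition cell; cells with fewer than two observations are
    skipped for the SD rule (floors still apply) and counted.
    """
    logv = np.log(values)
    cells = logv.groupby([groups[k] for k in CELL_KEYS])
    n = cells.transform("count")
    mu = cells.transform("mean")
    sd = cells.transform("std")  # ddof=1
    report_counter[0] += int(cells.count().lt(2).sum())
    return (n >= 2) & (logv >= mu + k_sd * sd)


def filter_outliers(
    trials: pd.DataFrame,
    dwells: pd.DataFrame,
    k_sd: float = 2.0,
    rt_floor: float = 300.0,
    dwell_floor: float = 40.0,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Apply the log-transform + k-SD + bottom-cutoff outlier rules.

    ``trials`` needs columns participant, trial_id, similarity, set_size,
    target_present, correct, rt_ms, dwelling_ms; ``dwells`` one row per
    fixated stimulus with dwell_ms and the same condition labels.

    RTs of correct trials are filtered at the trial level; removed RTs
    become missing (the trial row is kept for the eye metrics).  Dwell
    filtering removes individual stimulus dwells, after which trial Dwelling
    is recomputed from the surviving distractor dwells.  Both rules evaluate
    cell statistics on the pre-filter data, so floor and SD rule commute.
    """
    trials = trials.copy()
    dwells = dwells.copy()
    report = FilterReport()
    skipped = [0]

    # --- RT, correct trials only (RT is defined for correct answers) ------
    rt_rows = trials["correct"].astype(bool) & trials["rt_ms"].notna()
    report.n_rt_in = int(rt_rows.sum())
    rt = trials.loc[rt_rows, "rt_ms"]
    high = _upper_sd_mask(rt, trials.loc[rt_rows], k_sd, skipped)
    low = rt < rt_floor
    drop_rt = high | low
    report.n_rt_removed = int(drop_rt.sum())
    trials.loc[drop_rt[drop_rt].index, "rt_ms"] = np.nan

    # --- stimulus dwells ---------------------------------------------------
    d_rows = dwells["dwell_ms"].notna()
    report.n_dwell_in = int(d_rows.sum())
    dv = dwells.loc[d_rows, "dwell_ms"]
    high_d = _upper_sd_mask(dv, dwells.loc[d_rows], k_sd, skipped)
    low_d = dv < dwell_floor
    drop_d = high_d | low_d
    report.n_dwell_removed = int(drop_d.sum())
    dwells = dwells.drop(index=drop_d[drop_d].index)

    # Dwelling recomputed from surviving distractor dwells
    surv = dwells[~dwells["is_target"].astype(bool)]
    new_dwelling = surv.groupby("trial_id")["dwell_ms"].mean()
    trials["dwelling_ms"] = trials["trial_id"].map(new_dwelling)

    report.n_cells_skipped = skipped[0]
    if skipped[0]:
        logger.warning(
            "%d participant x condition cells had <2 observations; "
            "SD rule skipped there (floors still applied)", skipped[0],
        )
    logger.info(
        "outlier filter: removed %d/%d RTs (%.1f%%), %d/%d dwells (%.1f%%)",
        report.n_rt_removed, report.n_rt_in, 100 * report.rt_removed_prop,
        report.n_dwell_removed, report.n_dwell_in, 100 * report.dwell_removed_prop,
    )
    return trials, dwells, report


def zscore(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, ddof=1); missing propagate."""
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise ValueError("zero variance: cannot z-transform a constant series")
    mu = finite.mean()
    sd = finite.std(ddof=1)
    out = (arr - mu) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
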