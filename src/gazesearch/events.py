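"""Scanpath event classification for grid-based visual search displays.

Turns raw gaze samples or vendor-style fixation reports into per-stimulus
*visit runs*: maximal continuous series of fixations on one stimulus.  The
geometry is a 7 (horizontal) x 3 (vertical) grid of candidate stimulus
locations at a 200-px pitch; the central cell holds the fixation marker and
never holds a stimulus.  Every fixation is attributed to exactly one of the
21 rectangular areas of interest (AOIs), by containment where possible and
by nearest AOI center otherwise; fixations on unoccupied AOIs are discarded
before visit runs are formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# Display geometry (screen pixels, origin top-left, y grows downward)
# ---------------------------------------------------------------------------

SCREEN_W = 1920
SCREEN_H = 1080
GRID_COLS = 7
GRID_ROWS = 3
GRID_PITCH_PX = 200.0
#: grid index of the central cell (row-major); holds the fixation marker
CENTER_CELL = (GRID_ROWS // 2) * GRID_COLS + GRID_COLS // 2  # == 10
#: AOI rectangle enclosing one stimulus: width x height in px
AOI_W = 101.0
AOI_H = 130.0
#: legal per-axis jitter offsets applied to each occupied cell center
JITTER_OFFSETS = (-10.0, -5.0, 0.0, 5.0, 10.0)

N_CELLS = GRID_COLS * GRID_ROWS


def nominal_center(grid_index: int) -> tuple[float, float]:
    """Unjittered screen-pixel center of a grid cell (row-major index)."""
    if not 0 <= grid_index < N_CELLS:
        raise ValueError(f"grid index {grid_index} outside 0..{N_CELLS - 1}")
    row, col = divmod(grid_index, GRID_COLS)
    x = SCREEN_W / 2 + (col - (GRID_COLS - 1) / 2) * GRID_PITCH_PX
    y = SCREEN_H / 2 + (row - (GRID_ROWS - 1) / 2) * GRID_PITCH_PX
    return x, y


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FixationEvent:
    """One fixation: onset/duration in ms from display onset, position in px.

    ``aoi_id`` is filled by :func:`assign_aoi` (always one of the 21 grid
    indices afterwards); ``stimulus_id`` by :func:`drop_unoccupied` (index of
    the occupying stimulus within the trial's display).
    """

    onset: int
    duration: int
    x: float
    y: float
    aoi_id: int | None = None
    stimulus_id: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")


@dataclass
class DisplayLayout:
    """Occupied grid cells of one trial with their jittered centers.

    ``cells`` maps grid index -> (center_x, center_y) for occupied cells, in
    stimulus order (stimulus_id = position in the list).  ``target_stimulus``
    is the stimulus_id of the target in target-present trials, else None.
    """

    trial_id: str
    set_size: int
    cells: list[tuple[int, float, float]]
    target_stimulus: int | None = None

    def __post_init__(self) -> None:
        idx = [c[0] for c in self.cells]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate grid cells in layout")
        if CENTER_CELL in idx:
            raise ValueError("central cell cannot hold a stimulus")
        if len(self.cells) != self.set_size:
            raise ValueError("|cells| must equal set_size")

    @property
    def grid_to_stimulus(self) -> dict[int, int]:
        return {c[0]: i for i, c in enumerate(self.cells)}

    def full_grid_centers(self) -> np.ndarray:
        """(21, 2) AOI centers: jittered where occupied, nominal elsewhere."""
        centers = np.array([nominal_center(i) for i in range(N_CELLS)])
        for gi, cx, cy in self.cells:
            centers[gi] = (cx, cy)
        return centers


@dataclass
class VisitRun:
    """Maximal continuous series of fixations on one stimulus."""

    stimulus_id: int
    fixations: list[FixationEvent]
    order_index: int
    is_revisit: bool

    @property
    def gaze_ms(self) -> int:
        return sum(f.duration for f in self.fixations)


# ---------------------------------------------------------------------------
# Fixation detection from raw samples (approximate stand-in for the vendor
# parser; bypassed whenever fixation-level input is available)
# ---------------------------------------------------------------------------


def detect_fixations(
    t_ms: np.ndarray,
    x_px: np.ndarray,
    y_px: np.ndarray,
    sampling_rate: float,
    px_per_deg: float,
    speed_thresh: float = 30.0,
    accel_thresh: float = 8000.0,
) -> list[FixationEvent]:
    """Segment a uniformly sampled gaze stream into fixations.

    A sample is saccadic when its speed reaches ``speed_thresh`` (deg/s) or
    its speed derivative reaches ``accel_thresh`` (deg/s^2); maximal
    non-saccadic stretches become fixations.  Both signals use a two-sided,
    3-sample attribution — the minimum of the backward and forward
    difference at each sample — so a displacement interval is charged to the
    samples strictly inside the movement and fixation boundary samples are
    never swallowed: on clean streams detected onsets and durations are
    within one sample period of the generating events.

    Parameters are in screen pixels and milliseconds; ``px_per_deg`` converts
    pixel displacement to degrees of visual angle.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    x_px = np.asarray(x_px, dtype=float)
    y_px = np.asarray(y_px, dtype=float)
    if t_ms.size < 3:
        raise ValueError("insufficient samples")
    if np.any(np.diff(t_ms) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if px_per_deg <= 0 or speed_thresh <= 0 or accel_thresh <= 0:
        raise ValueError("thresholds and px_per_deg must be positive")

    dt = 1.0 / sampling_rate  # seconds per sample
    step = np.hypot(np.diff(x_px), np.diff(y_px)) / px_per_deg / dt  # deg/s
    s_back = np.insert(step, 0, 0.0)
    s_fwd = np.append(step, 0.0)
    speed = np.minimum(s_back, s_fwd)

    dstep = np.abs(np.diff(speed)) / dt  # deg/s^2
    a_back = np.insert(dstep, 0, 0.0)
    a_fwd = np.append(dstep, 0.0)
    accel = np.minimum(a_back, a_fwd)

    saccadic = (speed >= speed_thresh) | (accel >= accel_thresh)

    fixations: list[FixationEvent] = []
    n = t_ms.size
    period_ms = 1000.0 / sampling_rate
    i = 0
    while i < n:
        if saccadic[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not saccadic[j + 1]:
            j += 1
        dur = int(round(t_ms[j] - t_ms[i] + period_ms))
        if dur > 0:
            fixations.append(
                FixationEvent(
                    onset=int(round(t_ms[i])),
                    duration=dur,
                    x=float(np.mean(x_px[i : j + 1])),
                    y=float(np.mean(y_px[i : j + 1])),
                )
            )
        i = j + 1
    return fixations


# ---------------------------------------------------------------------------
# AOI assignment
# ---------------------------------------------------------------------------


def assign_aoi(fix: FixationEvent, layout: DisplayLayout) -> FixationEvent:
    """Attribute a fixation to exactly one of the 21 AOIs.

    Containment in an AOI rectangle wins; a fixation outside every rectangle
    goes to the AOI with the nearest center (Euclidean), ties broken by the
    lowest grid index.  Rectangles are closed on all edges and cannot overlap
    (101-px width against a >= 180-px minimum center separation), so
    containment is unambiguous.  Assignment is total: every fixation gets an
    ``aoi_id``.
    """
    centers = layout.full_grid_centers()
    dx = np.abs(fix.x - centers[:, 0])
    dy = np.abs(fix.y - centers[:, 1])
    inside = (dx <= AOI_W / 2) & (dy <= AOI_H / 2)
    if inside.any():
        aoi = int(np.argmax(inside))
    else:
        d2 = dx * dx + dy * dy
        aoi = int(np.argmin(d2))  # argmin returns the lowest index on ties
    return replace(fix, aoi_id=aoi)


def assign_aoi_batch(
    fixs: list[FixationEvent], layout: DisplayLayout
) -> list[FixationEvent]:
    """Vectorized :func:`assign_aoi` over all fixations of one trial."""
    if not fixs:
        return []
    centers = layout.full_grid_centers()
    pts = np.array([[f.x, f.y] for f in fixs])
    dx = np.abs(pts[:, 0, None] - centers[None, :, 0])
    dy = np.abs(pts[:, 1, None] - centers[None, :, 1])
    inside = (dx <= AOI_W / 2) & (dy <= AOI_H / 2)
    nearest = np.argmin(dx * dx + dy * dy, axis=1)
    contained = inside.argmax(axis=1)
    aoi = np.where(inside.any(axis=1), contained, nearest)
    return [replace(f, aoi_id=int(a)) for f, a in zip(fixs, aoi)]


def drop_unoccupied(
    fixs: list[FixationEvent], layout: DisplayLayout
) -> list[FixationEvent]:
    """Remove fixations on empty AOIs; label survivors with stimulus ids.

    The central fixation-marker cell counts as unoccupied like any other
    empty cell.  Order is preserved.
    """
    g2s = layout.grid_to_stimulus
    out = []
    for f in fixs:
        if f.aoi_id is None:
            raise ValueError("fixation lacks aoi_id; run assign_aoi first")
        if f.aoi_id in g2s:
            out.append(replace(f, stimulus_id=g2s[f.aoi_id]))
    return out


# ---------------------------------------------------------------------------
# Run segmentation
# ---------------------------------------------------------------------------


def segment_runs(fixs: list[FixationEvent]) -> list[VisitRun]:
    """Group stimulus-labeled fixations into maximal same-stimulus runs.

    A run is a revisit iff its stimulus already owns an earlier run in the
    trial; because runs are maximal, a revisit is by construction separated
    from the previous visit by at least one fixation on a different stimulus.
    """
    runs: list[VisitRun] = []
    seen: set[int] = set()
    i = 0
    while i < len(fixs):
        sid = fixs[i].stimulus_id
        if sid is None:
            raise ValueError("fixation lacks stimulus_id; run drop_unoccupied first")
        j = i
        while j + 1 < len(fixs) and fixs[j + 1].stimulus_id == sid:
            j += 1
        runs.append(
            VisitRun(
                stimulus_id=sid,
                fixations=fixs[i : j + 1],
                order_index=len(runs),
                is_revisit=sid in seen,
            )
        )
        seen.add(sid)
        i = j + 1
    return runs


def truncate_at_response(
    fixs: list[FixationEvent], rt_ms: int
) -> list[FixationEvent]:
    """Clip the fixation sequence at the response keypress.

    Gaze after the decision is not search: fixations starting at or after
    ``rt_ms`` are dropped, a fixation ongoing at ``rt_ms`` is truncated.
    """
    out = []
    for f in fixs:
        if f.onset >= rt_ms:
            continue
        if f.onset + f.duration > rt_ms:
            clipped = rt_ms - f.onset
            if clipped > 0:
                out.append(replace(f, duration=clipped))
        else:
            out.append(f)
    return out
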