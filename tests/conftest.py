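import numpy as np
import pytest
from hypothesis import settings

import gazesearch as gs

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def paper_like():
    return gs.load_preset("paper_like")


@pytest.fixture(scope="session")
def null_params():
    return gs.load_preset("null")


@pytest.fixture(scope="session")
def small_study(paper_like):
    """One small event-level study shared by read-only tests."""
    return gs.simulate_study(paper_like, n_subjects=4, n_blocks=2, seed=11,
                             events=True)


def make_layout(grid_indices, trial_id="T0", jitter=None, target=None):
    """Layout at nominal centers (optionally jittered) for given cells."""
    from gazesearch.events import nominal_center

    cells = []
    for k, gi in enumerate(grid_indices):
        cx, cy = nominal_center(gi)
        if jitter:
            cx += jitter[k][0]
            cy += jitter[k][1]
        cells.append((gi, cx, cy))
    return gs.DisplayLayout(trial_id=trial_id, set_size=len(cells),
                            cells=cells, target_stimulus=target)


def fixations_from_labels(stimulus_ids, durations, layout, gap_ms=40):
    """Build a stimulus-labeled fixation sequence at the layout's centers."""
    fixs = []
    t = 0
    for sid, dur in zip(stimulus_ids, durations):
        gi, cx, cy = layout.cells[sid]
        fixs.append(
            gs.FixationEvent(onset=t, duration=int(dur), x=cx, y=cy,
                             aoi_id=gi, stimulus_id=sid)
        )
        t += int(dur) + gap_ms
    return fixs


def brute_force_runs(labels):
    """Independent scanner re-deriving runs and revisit flags from scratch.

    For each position, a new run starts whenever the label differs from the
    previous one; a run is a revisit iff its stimulus occurred at any earlier
    position that is separated from this run by at least one other label.
    """
    runs = []
    for i, lab in enumerate(labels):
        if i == 0 or labels[i - 1] != lab:
            runs.append({"stimulus": lab, "start": i, "end": i})
        else:
            runs[-1]["end"] = i
    for k, run in enumerate(runs):
        run["is_revisit"] = any(r["stimulus"] == run["stimulus"] for r in runs[:k])
    return runs


def brute_force_first_dwell(labels, durations, stimulus):
    """Sum of durations over the first maximal block of `stimulus`."""
    total = None
    for i, lab in enumerate(labels):
        if lab != stimulus:
            if total is not None:
                return total
            continue
        if total is None and (i == 0 or labels[i - 1] != stimulus):
            total = 0
        if total is not None:
            total += durations[i]
    return total  # block ran to the end (or stimulus never fixated -> None)
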