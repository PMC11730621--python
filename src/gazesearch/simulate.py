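"""Synthetic visual-search displays, scanpaths, and trial outcomes.

The generator emulates a face-in-crowd search study: 7 x 3 grid displays
(center excluded) at set sizes 5 and 10 with +/-10 px positional jitter,
45 observers aged 19-85, eight 20-trial blocks alternating target-distractor
similarity, half target-present.  The observer model is deliberately
phenomenological: on each trial the stimuli are inspected in a uniformly
random order; each is independently *skipped* with an inverse-logit
probability, each inspected stimulus draws a log-normal first-visit dwell,
and each visited stimulus is independently *revisited* after the first pass.
Standardized age, the similarity dummy, the set-size dummy, and the two
age x difficulty products shift the three channels linearly on their link
scales (logit-skip, logit-revisit, log-dwell), with per-subject Gaussian
intercepts on every channel.  RT is assembled mechanistically, and exactly::

    RT = sum(first-visit dwells) + sum(revisit gazes)
         + sum(per-run transition times) + motor residual

so the decomposition invariant holds for every simulated trial.  Ground
truth (visit order, per-stimulus skip/revisit flags, first-visit dwells, RT
components) is recorded next to the emitted data, which makes the whole
classification pipeline verifiable without any external data set.

Truth generation is vectorized across all trials of a study; rendering the
truth into fixation events (and gaze-sample streams) is a separate pass, so
a given seed yields the identical study whether or not events are rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .events import (
    AOI_H,
    AOI_W,
    CENTER_CELL,
    JITTER_OFFSETS,
    N_CELLS,
    DisplayLayout,
    FixationEvent,
    nominal_center,
)

#: order of the covariates every effect vector refers to
EFFECT_TERMS = ("age", "similarity", "set_size", "age_x_similarity", "age_x_set_size")

#: standardized effect targets of the "paper-like" preset (eye-metric models)
PAPER_LIKE_TARGETS: dict[str, dict[str, float]] = {
    "skipping": {"age": 0.11, "similarity": -0.14, "set_size": 0.37,
                 "age_x_similarity": 0.10, "age_x_set_size": -0.07},
    "dwelling": {"age": 0.36, "similarity": 0.54, "set_size": -0.27,
                 "age_x_similarity": 0.05, "age_x_set_size": -0.08},
    "revisiting": {"age": 0.20, "similarity": 0.32, "set_size": -0.09,
                   "age_x_similarity": 0.03, "age_x_set_size": -0.04},
}


@dataclass
class ObserverParams:
    """Tunable parameters of the phenomenological search observer.

    Link-scale baselines and effect vectors (over :data:`EFFECT_TERMS`) for
    the three eye-metric channels, the RT assembly components, per-condition
    error rates, and nuisance settings.  All times in ms.
    """

    # channel baselines (link scale)
    p_skip_base: float = logit(0.30)
    p_revisit_base: float = logit(0.20)
    mu_dwell_log: float = math.log(250.0)
    sigma_dwell_log: float = 0.45

    # covariate effects on the link scales
    beta_skip: dict[str, float] = field(default_factory=dict)
    beta_revisit: dict[str, float] = field(default_factory=dict)
    beta_dwell: dict[str, float] = field(default_factory=dict)

    # between-subject intercept SDs per channel
    subject_sd_skip: float = 0.40
    subject_sd_revisit: float = 0.40
    subject_sd_dwell: float = 0.20
    subject_sd_motor: float = 60.0

    # RT assembly: per-run transition (saccade + travel) and motor residual
    transition_mean_ms: float = 45.0
    transition_sd_ms: float = 15.0
    motor_mean_ms: float = 500.0
    motor_sd_ms: float = 100.0
    #: motor slowing per SD of age (direct, non-oculomotor age effect on RT)
    beta_age_motor_ms: float = 100.0

    #: error rate per (target_present, similarity, set_size) condition
    error_rates: dict[tuple[bool, int, int], float] = field(default_factory=dict)

    revisit_gaze_scale: float = 0.7
    fix_noise_sd: float = 10.0
    #: probability that a visit run is rendered as two fixations
    p_split_fixation: float = 0.3

    def __post_init__(self) -> None:
        for name in ("beta_skip", "beta_revisit", "beta_dwell"):
            b = dict.fromkeys(EFFECT_TERMS, 0.0) | getattr(self, name)
            unknown = set(b) - set(EFFECT_TERMS)
            if unknown:
                raise ValueError(f"unknown effect terms in {name}: {unknown}")
            setattr(self, name, b)
        if not self.error_rates:
            # proportion-incorrect pattern typical of this design: near-perfect
            # rejection in target-absent, more misses in hard present trials
            self.error_rates = {
                (False, 0, 5): 0.01, (False, 0, 10): 0.005,
                (False, 1, 5): 0.005, (False, 1, 10): 0.01,
                (True, 0, 5): 0.06, (True, 0, 10): 0.11,
                (True, 1, 5): 0.08, (True, 1, 10): 0.10,
            }
        if self.sigma_dwell_log <= 0:
            raise ValueError("sigma_dwell_log must be positive")

    def beta_array(self, channel: str) -> np.ndarray:
        b = getattr(self, f"beta_{channel}")
        return np.array([b[t] for t in EFFECT_TERMS])


@dataclass
class StudyData:
    """One simulated study: emitted tables plus the generating ground truth."""

    trials: pd.DataFrame  # participant, trial_id, block, similarity, set_size,
    #                        target_present, correct, rt_ms, age
    truth_trials: pd.DataFrame  # per-trial stats + RT components
    truth_stimuli: pd.DataFrame  # per-stimulus flags, dwells, order, transitions
    fixations: pd.DataFrame | None = None  # event rendering (events=True)
    layouts: pd.DataFrame | None = None
    seed: int | None = None

    def truth_trial_stats(self) -> pd.DataFrame:
        """Trial-statistics table derived from ground truth labels."""
        cols = ["participant", "trial_id", "similarity", "set_size",
                "target_present", "correct", "rt_ms", "dwelling_ms",
                "skipping", "revisiting", "age"]
        return self.truth_trials[cols].copy()

    def truth_dwells(self) -> pd.DataFrame:
        """Per-stimulus first-visit dwell table derived from ground truth."""
        s = self.truth_stimuli
        fixated = s[~s["skipped"]]
        out = fixated[["participant", "trial_id", "stimulus_id", "dwell_ms",
                       "is_target", "similarity", "set_size", "target_present"]]
        return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Displays
# ---------------------------------------------------------------------------


def generate_display(
    set_size: int,
    rng: np.random.Generator,
    trial_id: str = "T000",
    target_stimulus: int | None = None,
) -> DisplayLayout:
    """Sample one search display.

    ``set_size`` distinct cells are drawn uniformly from the 20 non-central
    cells of the 7 x 3 grid; each occupied center is jittered independently
    per axis by one of {-10, -5, 0, 5, 10} px.  Any two stimulus centers are
    therefore at least 200 - 2*10 = 180 px apart.
    """
    candidates = [i for i in range(N_CELLS) if i != CENTER_CELL]
    if not 0 < set_size <= len(candidates):
        raise ValueError(f"set_size must be in 1..{len(candidates)}")
    cells_idx = rng.choice(len(candidates), size=set_size, replace=False)
    jit = rng.choice(JITTER_OFFSETS, size=(set_size, 2))
    cells = []
    for k, ci in enumerate(cells_idx):
        gi = candidates[ci]
        cx, cy = nominal_center(gi)
        cells.append((gi, cx + jit[k, 0], cy + jit[k, 1]))
    return DisplayLayout(trial_id=trial_id, set_size=set_size, cells=cells,
                         target_stimulus=target_stimulus)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------


def build_design(
    n_subjects: int,
    n_blocks: int,
    trials_per_block: int,
    ages: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Trial list: blocks alternate similarity (counterbalanced start),
    target presence and set size balanced and shuffled within block."""
    if trials_per_block % 4:
        raise ValueError("trials_per_block must be divisible by 4")
    reps = trials_per_block // 4
    rows = []
    for s in range(n_subjects):
        start_similar = s % 2  # half of the subjects start with a similar block
        t = 0
        for b in range(n_blocks):
            similarity = (b + start_similar) % 2
            cells = [(tp, m) for tp in (False, True) for m in (5, 10)] * reps
            order = rng.permutation(len(cells))
            for k in order:
                tp, m = cells[k]
                rows.append(
                    {
                        "participant": s,
                        "trial_id": f"P{s:03d}T{t:03d}",
                        "block": b,
                        "similarity": similarity,
                        "set_size": m,
                        "target_present": tp,
                        "age": float(ages[s]),
                    }
                )
                t += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground-truth simulation (vectorized over all trials of a study)
# ---------------------------------------------------------------------------


def _covariate_matrix(design: pd.DataFrame, age_z: np.ndarray) -> np.ndarray:
    """(n_trials, 5) matrix over EFFECT_TERMS for the link-scale predictors."""
    sim = design["similarity"].to_numpy(dtype=float)
    setd = (design["set_size"].to_numpy() == 10).astype(float)
    a = age_z[design["participant"].to_numpy()]
    return np.column_stack([a, sim, setd, a * sim, a * setd])


def _simulate_truth(
    design: pd.DataFrame,
    params: ObserverParams,
    age_z: np.ndarray,
    subj_fx: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every trial's ground truth; returns (trials, stimuli) tables."""
    n = len(design)
    m = design["set_size"].to_numpy()
    part = design["participant"].to_numpy()
    X = _covariate_matrix(design, age_z)

    eta_skip = params.p_skip_base + X @ params.beta_array("skip") + subj_fx["skip"][part]
    eta_rev = params.p_revisit_base + X @ params.beta_array("revisit") + subj_fx["revisit"][part]
    loc_dwell = params.mu_dwell_log + X @ params.beta_array("dwell") + subj_fx["dwell"][part]

    # flat per-stimulus rows
    trial_row = np.repeat(np.arange(n), m)
    sid = np.concatenate([np.arange(k) for k in m])
    n_rows = trial_row.size

    # uniform visit order; in target-present trials search ends at the target
    order_u = rng.random(n_rows)
    target_sid = np.where(design["target_present"].to_numpy(),
                          rng.integers(0, m), -1)
    is_target = sid == target_sid[trial_row]
    # rank of each stimulus in the inspection order, within trial
    target_u = np.full(n, np.inf)
    target_u[trial_row[is_target]] = order_u[is_target]
    inspected = (order_u <= target_u[trial_row]) | is_target

    p_skip = expit(eta_skip)[trial_row]
    skip_draw = rng.random(n_rows) < p_skip
    skipped = ~inspected | (skip_draw & ~is_target)
    fixated = ~skipped

    dwell = np.zeros(n_rows)
    nf = int(fixated.sum())
    dwell[fixated] = np.maximum(
        1, np.round(rng.lognormal(loc_dwell[trial_row][fixated], params.sigma_dwell_log))
    )

    # revisits: target-absent only; a planned revisit of the only revisited
    # stimulus that was also visited last cannot be interrupted and is void
    absent_row = target_sid[trial_row] < 0
    p_rev = expit(eta_rev)[trial_row]
    revisit = fixated & absent_row & (rng.random(n_rows) < p_rev)

    df = pd.DataFrame(
        {
            "trial_row": trial_row,
            "stimulus_id": sid,
            "order_u": order_u,
            "is_target": is_target,
            "skipped": skipped,
            "dwell_ms": np.where(fixated, dwell, np.nan),
            "revisited": revisit,
        }
    )
    # visit rank among fixated stimuli (inspection order)
    df["visit_rank"] = (
        df[df["dwell_ms"].notna()].groupby("trial_row")["order_u"].rank() - 1
    )
    last_rank = df.groupby("trial_row")["visit_rank"].transform("max")
    is_last_visited = df["visit_rank"].notna() & (df["visit_rank"] == last_rank)
    n_planned = df.groupby("trial_row")["revisited"].transform("sum")
    n_fixated = last_rank + 1
    # a lone planned revisit of the very last visited stimulus could not be
    # interrupted; demote that stimulus one slot in the first pass instead
    # (order is exchangeable, so no trial statistic is perturbed), and void
    # the revisit only in the degenerate one-stimulus-visited case
    conflict = df["revisited"] & is_last_visited & (n_planned == 1)
    void = conflict & (n_fixated == 1)
    df.loc[void, "revisited"] = False
    swap_rows = conflict & (n_fixated >= 2)
    if swap_rows.any():
        swap_trials = df.loc[swap_rows, "trial_row"].unique()
        in_swap = df["trial_row"].isin(swap_trials)
        at_last = in_swap & is_last_visited
        at_prev = in_swap & df["visit_rank"].notna() & (
            df["visit_rank"] == last_rank - 1)
        df.loc[at_last, "visit_rank"] = last_rank[at_last] - 1
        df.loc[at_prev, "visit_rank"] = last_rank[at_prev]
        is_last_visited = df["visit_rank"].notna() & (
            df["visit_rank"] == last_rank)

    # revisit order: random, but never starting with the last-visited stimulus
    rev_u = rng.random(n_rows)
    df["rev_u"] = np.where(df["revisited"], rev_u, np.nan)
    df.loc[is_last_visited & df["revisited"], "rev_u"] += 1.0  # push to the back of the tie range
    df["revisit_rank"] = df[df["revisited"]].groupby("trial_row")["rev_u"].rank() - 1

    rev_gaze = np.zeros(n_rows)
    rev_mask = df["revisited"].to_numpy()
    rev_gaze[rev_mask] = np.maximum(
        1,
        np.round(
            params.revisit_gaze_scale
            * rng.lognormal(loc_dwell[trial_row][rev_mask], params.sigma_dwell_log)
        ),
    )
    df["revisit_gaze_ms"] = np.where(rev_mask, rev_gaze, np.nan)

    # per-run transition times (saccade + travel into each run)
    fx_mask = fixated
    trans_first = np.zeros(n_rows)
    trans_first[fx_mask] = np.maximum(
        5, np.round(rng.normal(params.transition_mean_ms, params.transition_sd_ms,
                               int(fx_mask.sum())))
    )
    trans_rev = np.zeros(n_rows)
    trans_rev[rev_mask] = np.maximum(
        5, np.round(rng.normal(params.transition_mean_ms, params.transition_sd_ms,
                               int(rev_mask.sum())))
    )
    df["transition_first_ms"] = np.where(fx_mask, trans_first, np.nan)
    df["transition_revisit_ms"] = np.where(rev_mask, trans_rev, np.nan)

    # ---- per-trial assembly ------------------------------------------------
    grp = df.groupby("trial_row")
    gaze_total = grp["dwell_ms"].sum().reindex(range(n), fill_value=0.0)
    rev_total = grp["revisit_gaze_ms"].sum().reindex(range(n), fill_value=0.0)
    trans_total = (
        grp["transition_first_ms"].sum().reindex(range(n), fill_value=0.0)
        + grp["transition_revisit_ms"].sum().reindex(range(n), fill_value=0.0)
    )
    u_motor = subj_fx["motor"][part]
    motor = np.maximum(
        50,
        np.round(
            rng.normal(
                params.motor_mean_ms
                + params.beta_age_motor_ms * age_z[part]
                + u_motor,
                params.motor_sd_ms,
            )
        ),
    )
    rt = gaze_total.to_numpy() + rev_total.to_numpy() + trans_total.to_numpy() + motor

    err = np.array(
        [params.error_rates[(bool(tp), int(s), int(mm))]
         for tp, s, mm in zip(design["target_present"], design["similarity"], m)]
    )
    correct = rng.random(n) >= err

    n_fixated = grp["dwell_ms"].count().reindex(range(n), fill_value=0).to_numpy()
    n_revisited = grp["revisited"].sum().reindex(range(n), fill_value=0).to_numpy()
    distractor = df["dwell_ms"].notna() & ~df["is_target"]
    dwelling = (
        df[distractor].groupby("trial_row")["dwell_ms"].mean().reindex(range(n))
    ).to_numpy()

    truth_trials = design.copy()
    truth_trials["correct"] = correct
    truth_trials["rt_ms"] = rt
    truth_trials["skipping"] = (m - n_fixated) / m
    truth_trials["revisiting"] = n_revisited / m
    truth_trials["dwelling_ms"] = dwelling
    truth_trials["gaze_ms"] = gaze_total.to_numpy()
    truth_trials["revisit_gaze_total_ms"] = rev_total.to_numpy()
    truth_trials["transition_total_ms"] = trans_total.to_numpy()
    truth_trials["motor_ms"] = motor
    truth_trials["target_stimulus"] = np.where(target_sid >= 0, target_sid, -1)

    stim = df.drop(columns=["order_u", "rev_u"])
    stim["trial_id"] = design["trial_id"].to_numpy()[stim["trial_row"]]
    stim["participant"] = design["participant"].to_numpy()[stim["trial_row"]]
    stim["similarity"] = design["similarity"].to_numpy()[stim["trial_row"]]
    stim["set_size"] = m[stim["trial_row"]]
    stim["target_present"] = design["target_present"].to_numpy()[stim["trial_row"]]
    return truth_trials, stim


# ---------------------------------------------------------------------------
# Event rendering
# ---------------------------------------------------------------------------


def _render_trial_events(
    stim: pd.DataFrame,
    layout: DisplayLayout,
    motor_ms: int,
    params: ObserverParams,
    rng: np.random.Generator,
) -> list[FixationEvent]:
    """Render one trial's truth into a fixation-event sequence.

    Runs are laid out in visit order, revisit runs after the first pass; a
    run is one or occasionally two consecutive fixations at the stimulus'
    jittered center plus isotropic positional noise.  Onsets accumulate the
    stored per-run transition times so the emitted events reproduce the
    trial's RT decomposition exactly.
    """
    centers = {i: (cx, cy) for i, (gi, cx, cy) in enumerate(layout.cells)}
    fixs: list[FixationEvent] = []
    t = 0

    first = stim[stim["dwell_ms"].notna()].sort_values("visit_rank")
    runs = [
        (int(r.stimulus_id), int(r.dwell_ms), int(r.transition_first_ms))
        for r in first.itertuples()
    ]
    rev = stim[stim["revisit_rank"].notna()].sort_values("revisit_rank")
    runs += [
        (int(r.stimulus_id), int(r.revisit_gaze_ms), int(r.transition_revisit_ms))
        for r in rev.itertuples()
    ]

    for sid, gaze, trans in runs:
        t += trans
        cx, cy = centers[sid]
        if gaze >= 80 and rng.random() < params.p_split_fixation:
            d1 = int(round(gaze * rng.uniform(0.3, 0.7)))
            parts = [d1, gaze - d1]
        else:
            parts = [gaze]
        for d in parts:
            x, y = rng.normal([cx, cy], params.fix_noise_sd)
            fixs.append(FixationEvent(onset=t, duration=d, x=float(x), y=float(y)))
            t += d
    return fixs


def render_samples(
    fixs: list[FixationEvent],
    sampling_rate: float = 1000.0,
    noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render fixation events into a uniformly sampled gaze stream.

    Gaze is held at the fixation position for its duration and sweeps
    linearly to the next fixation during the inter-fixation gap.  The stream
    starts at the first fixation's onset and ends at the last one's offset.
    """
    if not fixs:
        raise ValueError("no fixations to render")
    period = 1000.0 / sampling_rate
    t0, t1 = fixs[0].onset, fixs[-1].onset + fixs[-1].duration
    t = np.arange(t0, t1, period)
    x = np.empty_like(t)
    y = np.empty_like(t)
    for i, f in enumerate(fixs):
        inside = (t >= f.onset) & (t < f.onset + f.duration)
        x[inside], y[inside] = f.x, f.y
        if i + 1 < len(fixs):
            nxt = fixs[i + 1]
            gap = (t >= f.onset + f.duration) & (t < nxt.onset)
            if gap.any():
                frac = (t[gap] - (f.onset + f.duration)) / (nxt.onset - (f.onset + f.duration))
                x[gap] = f.x + frac * (nxt.x - f.x)
                y[gap] = f.y + frac * (nxt.y - f.y)
    if noise_px > 0:
        rng = rng or np.random.default_rng()
        x = x + rng.normal(0, noise_px, t.size)
        y = y + rng.normal(0, noise_px, t.size)
    return t, x, y


def simulate_trial(
    layout: "DisplayLayout",
    condition: dict,
    age_z: float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> tuple[list[FixationEvent], int, bool, dict]:
    """Simulate a single trial on a given display.

    ``condition`` needs ``similarity`` (0/1) and ``target_present``;
    set size comes from the layout.  Subject-level intercepts are zero here
    (they are a property of the study sampler, not of one trial).  Returns
    the rendered fixation events, the RT in ms, the correctness flag, and
    the ground truth as ``{"trial": Series, "stimuli": DataFrame}``; the
    RT always decomposes exactly into dwells + revisit gazes + transitions
    + motor.
    """
    design = pd.DataFrame(
        {
            "participant": [0],
            "trial_id": [layout.trial_id],
            "block": [0],
            "similarity": [int(condition["similarity"])],
            "set_size": [layout.set_size],
            "target_present": [bool(condition["target_present"])],
            "age": [np.nan],
        }
    )
    zeros = {k: np.zeros(1) for k in ("skip", "revisit", "dwell", "motor")}
    truth_trials, truth_stimuli = _simulate_truth(
        design, params, np.array([float(age_z)]), zeros, rng
    )
    tr = truth_trials.iloc[0]
    fixs = _render_trial_events(truth_stimuli, layout, int(tr["motor_ms"]),
                                params, rng)
    return (
        fixs,
        int(tr["rt_ms"]),
        bool(tr["correct"]),
        {"trial": tr, "stimuli": truth_stimuli},
    )


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


def simulate_study(
    params: ObserverParams,
    n_subjects: int = 45,
    n_blocks: int = 8,
    trials_per_block: int = 20,
    age_range: tuple[float, float] = (19.0, 85.0),
    age_gap: tuple[float, float] | None = None,
    seed: int | None = None,
    events: bool = True,
) -> StudyData:
    """Simulate a complete study with ground truth.

    Ages are uniform over ``age_range`` (optionally excluding ``age_gap``,
    mirroring samples with few middle-aged participants).  With
    ``events=False`` only the ground-truth tables are produced — the same
    truth the event rendering would reproduce, drawn before any rendering
    randomness, so a seed pins the study identically in both modes.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)

    ages = rng.uniform(*age_range, size=n_subjects)
    if age_gap is not None:
        lo, hi = age_gap
        gap = (ages > lo) & (ages < hi)
        while gap.any():
            ages[gap] = rng.uniform(*age_range, size=int(gap.sum()))
            gap = (ages > lo) & (ages < hi)
    age_z = (ages - ages.mean()) / ages.std(ddof=1)

    subj_fx = {
        "skip": rng.normal(0, params.subject_sd_skip, n_subjects),
        "revisit": rng.normal(0, params.subject_sd_revisit, n_subjects),
        "dwell": rng.normal(0, params.subject_sd_dwell, n_subjects),
        "motor": rng.normal(0, params.subject_sd_motor, n_subjects),
    }

    design = build_design(n_subjects, n_blocks, trials_per_block, ages, rng)
    truth_trials, truth_stimuli = _simulate_truth(design, params, age_z, subj_fx, rng)

    trials = truth_trials[
        ["participant", "trial_id", "block", "similarity", "set_size",
         "target_present", "correct", "rt_ms", "age"]
    ].copy()

    fixations_df = None
    layouts_df = None
    if events:
        fix_rows = []
        layout_rows = []
        stim_by_trial = dict(iter(truth_stimuli.groupby("trial_row", sort=True)))
        for i, tr in enumerate(truth_trials.itertuples()):
            tgt = int(tr.target_stimulus) if tr.target_stimulus >= 0 else None
            layout = generate_display(int(tr.set_size), rng,
                                      trial_id=tr.trial_id, target_stimulus=tgt)
            for s_id, (gi, cx, cy) in enumerate(layout.cells):
                layout_rows.append(
                    {
                        "trial_id": tr.trial_id,
                        "grid_index": gi,
                        "center_x": cx,
                        "center_y": cy,
                        "stimulus_role": "target" if tgt == s_id else "distractor",
                    }
                )
            fixs = _render_trial_events(
                stim_by_trial[i], layout, int(tr.motor_ms), params, rng
            )
            for k, f in enumerate(fixs):
                fix_rows.append(
                    {
                        "trial_id": tr.trial_id,
                        "participant": tr.participant,
                        "fix_index": k,
                        "onset_ms": f.onset,
                        "duration_ms": f.duration,
                        "x_px": round(f.x, 2),
                        "y_px": round(f.y, 2),
                    }
                )
        fixations_df = pd.DataFrame(fix_rows)
        layouts_df = pd.DataFrame(layout_rows)

    return StudyData(
        trials=trials,
        truth_trials=truth_trials,
        truth_stimuli=truth_stimuli,
        fixations=fixations_df,
        layouts=layouts_df,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def params_to_text(params: ObserverParams, header: str = "") -> str:
    """Serialize observer parameters to the plain-text key=value format."""
    lines = [f"# {h}" for h in header.splitlines() if h]
    simple = [
        "p_skip_base", "p_revisit_base", "mu_dwell_log", "sigma_dwell_log",
        "subject_sd_skip", "subject_sd_revisit", "subject_sd_dwell",
        "subject_sd_motor", "transition_mean_ms", "transition_sd_ms",
        "motor_mean_ms", "motor_sd_ms", "beta_age_motor_ms",
        "revisit_gaze_scale", "fix_noise_sd", "p_split_fixation",
    ]
    for k in simple:
        lines.append(f"{k} = {float(getattr(params, k))!r}")
    for ch in ("skip", "revisit", "dwell"):
        for t in EFFECT_TERMS:
            lines.append(f"beta_{ch}.{t} = {float(getattr(params, f'beta_{ch}')[t])!r}")
    for (tp, s, m), v in sorted(params.error_rates.items()):
        lines.append(f"error_rate.{'present' if tp else 'absent'}.{s}.{m} = {float(v)!r}")
    return "\n".join(lines) + "\n"


def params_from_text(text: str) -> ObserverParams:
    """Parse the plain-text key=value preset format."""
    simple: dict[str, float] = {}
    betas: dict[str, dict[str, float]] = {"skip": {}, "revisit": {}, "dwell": {}}
    errors: dict[tuple[bool, int, int], float] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, v = key.strip(), float(val.strip())
        if key.startswith("beta_") and "." in key:
            ch, term = key[5:].split(".", 1)
            betas[ch][term] = v
        elif key.startswith("error_rate."):
            _, tp, s, m = key.split(".")
            errors[(tp == "present", int(s), int(m))] = v
        else:
            simple[key] = v
    return ObserverParams(
        beta_skip=betas["skip"], beta_revisit=betas["revisit"],
        beta_dwell=betas["dwell"], error_rates=errors, **simple,
    )


def load_preset(name: str) -> ObserverParams:
    """Load a shipped preset ('paper_like' or 'null') or a file path."""
    pkg = resources.files("gazesearch") / "presets" / f"{name}.params"
    if pkg.is_file():
        return params_from_text(pkg.read_text())
    try:
        with open(name) as fh:
            return params_from_text(fh.read())
    except OSError as e:
        raise ValueError(f"unknown preset {name!r}") from e


# ---------------------------------------------------------------------------
# Calibration of link-scale effects to standardized targets
# ---------------------------------------------------------------------------


def calibrate_preset(
    targets: dict[str, dict[str, float]] | None = None,
    base: ObserverParams | None = None,
    n_subjects: int = 250,
    n_iter: int = 5,
    final_pilots: int = 4,
    damping: float = 0.8,
    seed: int = 0,
) -> ObserverParams:
    """Solve for link-scale effects whose *standardized* regression
    coefficients match the given targets.

    The observer model acts on logit/log link scales while the analysis
    reports standardized linear coefficients, so target magnitudes cannot be
    written into the betas directly.  This routine iterates a stochastic
    fixed point: simulate pilot studies, run the trial pipeline and the
    eye-metric regressions, estimate each coefficient's link-to-standardized
    gain, and rescale with damping.  Between-subject (age) coefficients are
    the noisiest, so the last two iterations average the realized
    coefficients over ``final_pilots`` independent pilots, keeping the
    frozen preset's residual calibration error well below the bias budget
    of downstream recovery checks.
    """
    from .metrics import filter_outliers
    from .inference import EYE_TERMS, fit_random_intercept, prepare_analysis_table

    targets = targets or PAPER_LIKE_TARGETS
    params = base or ObserverParams()
    chan = {"skipping": "skip", "dwelling": "dwell", "revisiting": "revisit"}
    # initial guess: targets verbatim on the link scale (gain ~1)
    for metric, ch in chan.items():
        setattr(params, f"beta_{ch}", dict(targets[metric]))

    def realized_coefs(n_pilots: int, seeds: np.ndarray) -> dict[str, dict[str, float]]:
        acc = {m: {t: 0.0 for t in EYE_TERMS} for m in chan}
        for k in range(n_pilots):
            study = simulate_study(params, n_subjects=n_subjects, events=False,
                                   seed=int(seeds[k] % 2**31))
            trials, _, _ = filter_outliers(study.truth_trial_stats(),
                                           study.truth_dwells())
            analysis = prepare_analysis_table(trials)
            for metric in chan:
                fit = fit_random_intercept(analysis, metric, list(EYE_TERMS))
                for t in EYE_TERMS:
                    acc[metric][t] += fit.coefficients[t].b / n_pilots
        return acc

    ss = np.random.SeedSequence(seed).generate_state(n_iter * final_pilots)
    for it in range(n_iter):
        pilots = final_pilots if it >= n_iter - 2 else 1
        realized = realized_coefs(pilots, ss[it * final_pilots:(it + 1) * final_pilots])
        for metric, ch in chan.items():
            beta = dict(getattr(params, f"beta_{ch}"))
            for term in EYE_TERMS:
                r = realized[metric][term]
                want = targets[metric][term]
                if beta[term] != 0 and r / beta[term] > 0.05:
                    gain = r / beta[term]
                    new = want / gain
                    beta[term] += damping * (new - beta[term])
                else:  # gain not identifiable; nudge additively
                    beta[term] += damping * (want - r)
            setattr(params, f"beta_{ch}", beta)
    return params
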