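"""Readers and writers for the pipeline's on-disk table formats.

Fixation reports and display layouts travel as tab-separated files that
mirror a vendor fixation-report export (uppercase headers, one row per
fixation / per occupied grid cell); trial statistics and model output as
comma-separated tables.  Files written by the simulator carry the seed in a
leading ``#`` comment line; all readers skip ``#`` comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .metrics import FilterReport

FIXATION_COLS = {
    "trial_id": "TRIAL_ID", "participant": "PARTICIPANT",
    "fix_index": "FIX_INDEX", "onset_ms": "ONSET_MS",
    "duration_ms": "DURATION_MS", "x_px": "X_PX", "y_px": "Y_PX",
}
LAYOUT_COLS = {
    "trial_id": "TRIAL_ID", "grid_index": "GRID_INDEX",
    "center_x": "CENTER_X", "center_y": "CENTER_Y",
    "stimulus_role": "STIMULUS_ROLE",
}
TRIAL_COLS = {
    "trial_id": "TRIAL_ID", "participant": "PARTICIPANT", "block": "BLOCK",
    "similarity": "SIMILARITY", "set_size": "SET_SIZE",
    "target_present": "TARGET_PRESENT", "correct": "CORRECT",
    "rt_ms": "RT_MS", "age": "AGE",
}
STATS_COLS = {
    "participant": "PARTICIPANT", "trial_id": "TRIAL",
    "similarity": "SIMILARITY", "set_size": "SET_SIZE",
    "target_present": "TARGET_PRESENT", "correct": "CORRECT",
    "rt_ms": "RT_MS", "dwelling_ms": "DWELLING_MS",
    "skipping": "SKIPPING", "revisiting": "REVISITING", "age": "AGE",
}


def _write(df: pd.DataFrame, path: Path, mapping: dict, sep: str,
           seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in mapping if c in df.columns]
    out = df[cols].rename(columns=mapping)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, sep=sep, index=False)


def _read(path: Path, mapping: dict, sep: str, required: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#")
    inv = {v: k for k, v in mapping.items()}
    missing = [c for c in inv if c not in df.columns]
    if missing and required:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df.rename(columns=inv)


def write_fixations(df, path, seed=None):
    _write(df, path, FIXATION_COLS, "\t", seed)


def read_fixations(path) -> pd.DataFrame:
    return _read(path, FIXATION_COLS, "\t")


def write_layouts(df, path, seed=None):
    _write(df, path, LAYOUT_COLS, "\t", seed)


def read_layouts(path) -> pd.DataFrame:
    return _read(path, LAYOUT_COLS, "\t")


def write_trials(df, path, seed=None):
    _write(df, path, TRIAL_COLS, "\t", seed)


def read_trials(path) -> pd.DataFrame:
    df = _read(path, TRIAL_COLS, "\t")
    df["target_present"] = df["target_present"].astype(bool)
    df["correct"] = df["correct"].astype(bool)
    return df


def write_trial_stats(df, path, seed=None):
    _write(df, path, STATS_COLS, ",", seed)


def read_trial_stats(path) -> pd.DataFrame:
    df = _read(path, STATS_COLS, ",", required=False)
    for c in ("target_present", "correct"):
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return df


def write_dwells(df, path, seed=None):
    cols = ["participant", "trial_id", "stimulus_id", "dwell_ms", "is_target",
            "similarity", "set_size", "target_present"]
    _write(df, path, {c: c.upper() for c in cols}, ",", seed)


def read_dwells(path) -> pd.DataFrame:
    cols = ["participant", "trial_id", "stimulus_id", "dwell_ms", "is_target",
            "similarity", "set_size", "target_present"]
    df = _read(path, {c: c.upper() for c in cols}, ",")
    for c in ("is_target", "target_present"):
        df[c] = df[c].astype(bool)
    return df


def write_filter_report(report: FilterReport, txt_path, kv_path) -> None:
    """Emit the filter tally as a human-readable block and a key=value file."""
    d = report.as_dict()
    txt = (
        "Outlier filtering\n"
        "-----------------\n"
        f"RTs removed:    {d['n_rt_removed']} of {d['n_rt_in']} "
        f"({100 * d['rt_removed_prop']:.1f}%)\n"
        f"Dwells removed: {d['n_dwell_removed']} of {d['n_dwell_in']} "
        f"({100 * d['dwell_removed_prop']:.1f}%)\n"
        f"Cells skipped (<2 obs): {d['n_cells_skipped']}\n"
    )
    Path(txt_path).parent.mkdir(parents=True, exist_ok=True)
    Path(txt_path).write_text(txt)
    Path(kv_path).write_text("".join(f"{k} = {v}\n" for k, v in d.items()))


def write_model_table(fit, path, seed=None, extra: dict | None = None) -> None:
    """Coefficient table (term, b, sd_b, t, significant, effect size) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        meta = {
            "response": fit.response, "n_obs": fit.n_obs,
            "n_groups": fit.n_groups,
            "var_random_intercept": round(fit.var_random_intercept, 6),
            "var_residual": round(fit.var_residual, 6),
            "marginal_r2": round(fit.marginal_r2, 6),
        } | (extra or {})
        if seed is not None:
            meta["seed"] = seed
        fh.write("# " + json.dumps(meta) + "\n")
        fit.table().round(6).to_csv(fh, index=False)


def write_correlations(corr: pd.DataFrame, path, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        corr.round(4).to_csv(fh)


def write_path_summary(edges: list[dict], path) -> None:
    """Two-stage regression summary as a JSON-lines edge list."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for e in edges:
            fh.write(json.dumps(e) + "\n")
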