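"""Trial-table schema, validation and TSV input/output.

One row per completed trial.  Mandatory columns::

    bird_id, session_id, trial_index, load, cue, delay_class, delay_s,
    target_idx, wheel_rotation, response_angle, response_idx, reward_pellets

plus ``nontarget_idx`` (load-2 trials only) and ``prev_target_idx`` (absent on
the first trial of a session).  Angles are radians; ``response_angle`` is the
peck angle on the rotated wheel, so the reported color angle is
``response_angle - wheel_rotation``.  Unknown extra columns are preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .wheel import (
    DELAY_SECONDS,
    ColorWheelSpec,
    angle_to_index,
    signed_angular_error,
    index_to_angle,
    wrap_angle,
)

MANDATORY_COLUMNS = [
    "bird_id",
    "session_id",
    "trial_index",
    "load",
    "cue",
    "delay_class",
    "delay_s",
    "target_idx",
    "nontarget_idx",
    "wheel_rotation",
    "response_angle",
    "response_idx",
    "prev_target_idx",
    "reward_pellets",
]

VALID_CUES = {"none", "simultaneous", "retro"}
VALID_DELAY_CLASSES = set(DELAY_SECONDS)


class TrialTableError(ValueError):
    """Raised when a trial table violates the schema, with row diagnostics."""


def response_color_angle(table: pd.DataFrame) -> np.ndarray:
    """Reported color angle in [0, 2pi): peck angle minus wheel rotation."""
    return wrap_angle(table["response_angle"].to_numpy(float) - table["wheel_rotation"].to_numpy(float))


def response_errors(table: pd.DataFrame, wheel: ColorWheelSpec = ColorWheelSpec()) -> np.ndarray:
    """Signed angular error of each response relative to its target, (-pi, pi]."""
    target = index_to_angle(table["target_idx"].to_numpy(int), wheel)
    return signed_angular_error(response_color_angle(table), target)


def nontarget_errors(table: pd.DataFrame, wheel: ColorWheelSpec = ColorWheelSpec()) -> np.ndarray:
    """Signed angular error relative to the non-target; NaN for load-1 trials."""
    out = np.full(len(table), np.nan)
    has = table["nontarget_idx"].notna().to_numpy()
    if has.any():
        nt = index_to_angle(table.loc[has, "nontarget_idx"].to_numpy(int), wheel)
        out[has] = signed_angular_error(response_color_angle(table.loc[has]), nt)
    return out


def validate_trials(
    table: pd.DataFrame,
    wheel: ColorWheelSpec = ColorWheelSpec(),
    delay_seconds: dict | None = None,
    check_responses: bool = True,
) -> pd.DataFrame:
    """Validate a trial table against the schema; returns a normalized copy.

    Raises :class:`TrialTableError` listing up to 10 offending rows per rule.
    ``delay_s`` is filled from ``delay_class`` where missing.
    """
    delay_seconds = dict(DELAY_SECONDS if delay_seconds is None else delay_seconds)
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns and c not in ("nontarget_idx", "prev_target_idx", "delay_s")]
    if missing:
        raise TrialTableError(f"missing mandatory columns: {missing}")
    t = table.copy()
    for opt in ("nontarget_idx", "prev_target_idx"):
        if opt not in t.columns:
            t[opt] = pd.array([pd.NA] * len(t), dtype="Int64")
        else:
            t[opt] = t[opt].astype("Int64")
    t["target_idx"] = t["target_idx"].astype(int)

    problems: list[str] = []

    def check(mask: np.ndarray, rule: str) -> None:
        mask = np.asarray(mask)
        if mask.any():
            rows = np.nonzero(mask)[0][:10].tolist()
            problems.append(f"{rule} (rows {rows}{'...' if mask.sum() > 10 else ''})")

    check(~t["load"].isin([1, 2]).to_numpy(), "load must be 1 or 2")
    check(~t["cue"].isin(VALID_CUES).to_numpy(), f"cue must be one of {sorted(VALID_CUES)}")
    check(~t["delay_class"].isin(VALID_DELAY_CLASSES).to_numpy(), f"delay_class must be one of {sorted(VALID_DELAY_CLASSES)}")
    load1 = (t["load"] == 1).to_numpy()
    check(load1 & t["nontarget_idx"].notna().to_numpy(), "load-1 trials must not carry nontarget_idx")
    check(load1 & (t["cue"] != "none").to_numpy(), "load-1 trials must have cue='none'")
    check(~load1 & t["nontarget_idx"].isna().to_numpy(), "load-2 trials require nontarget_idx")
    check(~load1 & ~t["cue"].isin(["simultaneous", "retro"]).to_numpy(), "load-2 trials require a simultaneous or retro cue")
    for col in ("target_idx", "nontarget_idx", "prev_target_idx"):
        vals = t[col]
        bad = vals.notna() & ((vals < 1) | (vals > wheel.n_colors))
        check(bad.to_numpy(), f"{col} outside 1..{wheel.n_colors}")

    # fill / check delay_s
    expected = t["delay_class"].map(delay_seconds)
    if "delay_s" not in t.columns:
        t["delay_s"] = expected
    else:
        t["delay_s"] = t["delay_s"].where(t["delay_s"].notna(), expected).astype(float)
        known = t["delay_class"].isin(delay_seconds)
        check((known & ~np.isclose(t["delay_s"], expected.astype(float))).to_numpy(), "delay_s inconsistent with delay_class")

    if check_responses and t["response_angle"].notna().all():
        color_angle = response_color_angle(t)
        expect_idx = angle_to_index(color_angle, wheel)
        check(expect_idx != t["response_idx"].to_numpy(int), "response_idx is not the nearest wedge to response_angle - wheel_rotation")
        check(
            ~t["reward_pellets"].isin([0, 1, 2, 3]).to_numpy(),
            "reward_pellets must be in {0,1,2,3}",
        )

    if problems:
        raise TrialTableError("trial table invalid: " + "; ".join(problems))
    return t


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_trials(path, wheel: ColorWheelSpec = ColorWheelSpec(), **kwargs) -> pd.DataFrame:
    """Read and validate a trial TSV; violations raise with row diagnostics."""
    table = pd.read_csv(path, sep="\t")
    return validate_trials(table, wheel, **kwargs)
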