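"""Synthetic task sessions and responses from a known generative attractor model.

The generator emulates the delayed-estimation task: targets drawn uniformly
from 64 hues, nine trial types crossing three load conditions (load 1, load 2
with simultaneous cue, load 2 with retro cue) with three delays (0.45 s
"simultaneous", 1.2 s short, 3.2 s long), responses produced by Euler-Maruyama
simulation of the attractor Langevin dynamics through a 1-s encoding phase and
the trial's delay, plus swap responses to the non-target and uniform guesses.
It doubles as the Monte-Carlo oracle for the Fokker-Planck engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fokker_planck import DriftField
from .wheel import (
    DELAY_SECONDS,
    TWO_PI,
    ColorWheelSpec,
    angle_to_index,
    index_to_angle,
    signed_angular_error,
    signed_index_error,
    reward_level,
    wrap_angle,
)

#: The nine trial types as (load, cue, delay_class); loads 2 carry a cue.
TRIAL_TYPES = tuple(
    (load, cue, delay)
    for load, cue in ((1, "none"), (2, "simultaneous"), (2, "retro"))
    for delay in ("simultaneous", "short", "long")
)


@dataclass
class SessionConfig:
    """Configuration for session generation (targets and trial schedule only)."""

    n_trials: int = 1000
    trial_type_weights: np.ndarray | None = None  # 9 non-negative weights
    n_colors: int = 64
    seed: int = 0
    serial_bias_gain: float = 0.0  # radians; 0 disables serial dependence
    bird_id: str = "SYN"
    session_id: str = "s001"
    delay_seconds: dict = dc_field(default_factory=lambda: dict(DELAY_SECONDS))

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trial_type_weights is None:
            self.trial_type_weights = np.ones(len(TRIAL_TYPES))
        self.trial_type_weights = np.asarray(self.trial_type_weights, dtype=float)
        if self.trial_type_weights.shape != (len(TRIAL_TYPES),):
            raise ValueError(f"need {len(TRIAL_TYPES)} trial-type weights")
        if np.any(self.trial_type_weights < 0) or self.trial_type_weights.sum() <= 0:
            raise ValueError("trial-type weights must be non-negative with positive sum")


@dataclass
class GenerativeModelSpec:
    """Ground-truth attractor model used to draw responses.

    beta/sigma are dictionaries keyed by load (1, 2) giving the drift gain
    (1/s) and diffusion (rad/sqrt(s)) for the encoding and memory phases.
    Defaults emulate a bird-like regime: a six-attractor landscape, stronger
    drift and noise under load 2, a modest swap rate and some guessing.
    """

    drift: DriftField | None = None
    beta_encode: dict = dc_field(default_factory=lambda: {1: 1.2, 2: 1.2})
    sigma_encode: dict = dc_field(default_factory=lambda: {1: 0.25, 2: 0.35})
    beta_memory: dict = dc_field(default_factory=lambda: {1: 0.6, 2: 0.8})
    sigma_memory: dict = dc_field(default_factory=lambda: {1: 0.35, 2: 0.5})
    p_swap: float = 0.1
    p_guess: dict = dc_field(default_factory=lambda: {1: 0.05, 2: 0.1})
    encode_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if self.drift is None:
            self.drift = six_attractor_drift()
        for d in (self.sigma_encode, self.sigma_memory):
            if any(v < 0 for v in d.values()):
                raise ValueError("sigma must be >= 0")
        if not (0 <= self.p_swap <= 1):
            raise ValueError("p_swap must be a probability")
        for v in self.p_guess.values():
            if not (0 <= v <= 1) or self.p_swap + v > 1:
                raise ValueError("require 0 <= p_guess and p_swap + p_guess <= 1")


def six_attractor_drift(amplitude: float = 1.0) -> DriftField:
    """Drift landscape with six evenly spaced attractors (G ~ -sin(6*theta))."""
    from .fokker_planck import project_on_basis

    field, _ = project_on_basis(lambda th: -np.sin(6 * th)).normalized()
    field.weights *= amplitude
    return field


def generate_sessions(config: SessionConfig) -> pd.DataFrame:
    """Draw a trial table (responses absent) from the task schedule.

    Trial types follow the given weights; target (and non-target, load 2)
    indices are i.i.d. uniform over the wheel; the wheel rotation is uniform
    on [0, 2pi).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    w = config.trial_type_weights / config.trial_type_weights.sum()
    types = rng.choice(len(TRIAL_TYPES), size=n, p=w)
    load = np.array([TRIAL_TYPES[t][0] for t in types])
    cue = np.array([TRIAL_TYPES[t][1] for t in types])
    delay_class = np.array([TRIAL_TYPES[t][2] for t in types])
    target = rng.integers(1, config.n_colors + 1, size=n)
    nontarget = np.where(load == 2, rng.integers(1, config.n_colors + 1, size=n), 0)
    table = pd.DataFrame(
        {
            "bird_id": config.bird_id,
            "session_id": config.session_id,
            "trial_index": np.arange(1, n + 1),
            "load": load,
            "cue": cue,
            "delay_class": delay_class,
            "delay_s": [config.delay_seconds[d] for d in delay_class],
            "target_idx": target,
            "nontarget_idx": pd.array(np.where(load == 2, nontarget, -1), dtype="Int64"),
            "wheel_rotation": rng.uniform(0, TWO_PI, size=n),
        }
    )
    table.loc[table["load"] == 1, "nontarget_idx"] = pd.NA
    prev = table["target_idx"].shift(1)
    table["prev_target_idx"] = pd.array(prev, dtype="Int64")
    return table


def simulate_trajectory(
    theta0,
    drift: DriftField | None,
    beta: float,
    sigma: float,
    duration_s: float,
    dt: float = 0.01,
    rng: np.random.Generator | None = None,
    lookup_size: int = 4096,
):
    """Euler-Maruyama endpoints of the Langevin dynamics, vectorized.

    ``theta0`` may be scalar or an array of starting angles; one endpoint per
    start is returned, wrapped to [0, 2pi).  Drift is evaluated via a dense
    precomputed lookup table (linear interpolation) for speed.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    theta = wrap_angle(np.array(theta0, dtype=float, copy=True))
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)
    if duration_s == 0:
        return theta[0] if scalar else theta
    n_steps = int(round(duration_s / dt))
    n_steps = max(n_steps, 1)
    dt_eff = duration_s / n_steps
    use_drift = drift is not None and beta != 0.0
    if use_drift:
        grid = np.arange(lookup_size + 1) * (TWO_PI / lookup_size)
        gtab = beta * drift(grid)
        gtab[-1] = gtab[0]
    sqdt = np.sqrt(dt_eff)
    for _ in range(n_steps):
        if use_drift:
            theta += np.interp(theta, grid, gtab) * dt_eff
        if sigma > 0:
            theta += sigma * sqdt * rng.standard_normal(theta.shape)
        theta = wrap_angle(theta)
    return theta[0] if scalar else theta


def generate_responses(
    table: pd.DataFrame,
    model: GenerativeModelSpec,
    dt: float = 0.01,
    rng: np.random.Generator | None = None,
    wheel: ColorWheelSpec | None = None,
) -> pd.DataFrame:
    """Fill responses into a trial table by simulating the generative model.

    Per trial: with probability ``p_guess`` the response is uniform; otherwise
    with probability ``p_swap`` (load-2 only) the NON-target is remembered;
    otherwise the target.  Remembered items evolve through the encoding phase
    (1 s, encode parameters of the trial's load) and the delay (memory
    parameters).  Serial dependence, when configured on the session, is
    applied afterwards as a first-harmonic attraction toward the previous
    target.  ``response_idx`` and ``reward_pellets`` are filled consistently.
    """
    rng = np.random.default_rng() if rng is None else rng
    wheel = wheel or ColorWheelSpec(n_colors=int(max(table["target_idx"].max(), 64)))
    t = table.copy()
    n = len(t)
    load = t["load"].to_numpy(int)
    if model.p_swap > 0 and (load == 1).all():
        raise ValueError("p_swap > 0 requires load-2 trials")

    target_angle = index_to_angle(t["target_idx"].to_numpy(int), wheel)
    nt_idx = t["nontarget_idx"].to_numpy(dtype=float, na_value=np.nan)
    has_nt = ~np.isnan(nt_idx)
    nt_angle = np.zeros(n)
    if has_nt.any():
        nt_angle[has_nt] = index_to_angle(nt_idx[has_nt].astype(int), wheel)

    u = rng.uniform(size=n)
    p_guess = np.array([model.p_guess[l] for l in load])
    is_guess = u < p_guess
    is_swap = (~is_guess) & (load == 2) & has_nt & (u < p_guess + model.p_swap)
    start = np.where(is_swap, nt_angle, target_angle)

    response = np.empty(n)
    delays = t["delay_s"].to_numpy(float)
    for ld in (1, 2):
        for delay in np.unique(delays):
            sel = (~is_guess) & (load == ld) & np.isclose(delays, delay)
            if not sel.any():
                continue
            th = simulate_trajectory(
                start[sel], model.drift, model.beta_encode[ld], model.sigma_encode[ld],
                model.encode_duration_s, dt, rng,
            )
            th = simulate_trajectory(
                th, model.drift, model.beta_memory[ld], model.sigma_memory[ld],
                float(delay), dt, rng,
            )
            response[sel] = th
    response[is_guess] = rng.uniform(0, TWO_PI, size=int(is_guess.sum()))
    return _finalize_responses(t, response, wheel)


def apply_serial_bias(
    table: pd.DataFrame,
    response_color_angle: np.ndarray,
    gain: float,
    wheel: ColorWheelSpec,
) -> np.ndarray:
    """Shift responses toward the previous target by gain*sin(prev - current).

    First-harmonic form: the attraction is maximal when the previous target
    sits a quarter-circle away and vanishes for identical or opposite targets.
    """
    prev = table["prev_target_idx"].to_numpy(dtype=float, na_value=np.nan)
    shift = np.zeros(len(table))
    has_prev = ~np.isnan(prev)
    if has_prev.any():
        delta = signed_angular_error(
            index_to_angle(prev[has_prev].astype(int), wheel),
            index_to_angle(table.loc[has_prev, "target_idx"].to_numpy(int), wheel),
        )
        shift[has_prev] = gain * np.sin(delta)
    return wrap_angle(response_color_angle + shift)


def _finalize_responses(t: pd.DataFrame, color_angle: np.ndarray, wheel: ColorWheelSpec) -> pd.DataFrame:
    """Attach response columns (peck angle on the rotated wheel, index, reward)."""
    color_angle = wrap_angle(color_angle)
    t["response_angle"] = wrap_angle(color_angle + t["wheel_rotation"].to_numpy(float))
    t["response_idx"] = angle_to_index(color_angle, wheel)
    err_idx = signed_index_error(t["response_idx"].to_numpy(int), t["target_idx"].to_numpy(int), wheel)
    t["reward_pellets"] = reward_level(err_idx)
    return t


def generate_dataset(
    config: SessionConfig,
    model: GenerativeModelSpec,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Sessions plus simulated responses (and serial bias, if configured)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    table = generate_sessions(config)
    wheel = ColorWheelSpec(config.n_colors)
    table = generate_responses(table, model, dt=dt, rng=rng, wheel=wheel)
    if config.serial_bias_gain != 0.0:
        from .trials import response_color_angle as _rca

        shifted = apply_serial_bias(table, _rca(table), config.serial_bias_gain, wheel)
        table = _finalize_responses(table, shifted, wheel)
    return table
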