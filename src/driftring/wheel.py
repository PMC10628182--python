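"""Color-wheel geometry, angular-error conventions and reward scoring.

The task presents 64 hues uniformly spaced on a circle.  Colors are indexed
1..n_colors with index 1 anchored at angle 0 and angles increasing
counterclockwise; a report is scored by its signed angular deviation from the
target, positive meaning a counterclockwise displacement.  Graded reward:
3 pellets for the exact color, 2 within the inner range (+/-1 color), 1 within
the full range (+/-3 colors), nothing beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi

#: Delay classes and their default durations in seconds.  The shortest delay
#: re-displays the target inside the choice wheel and approximates undelayed
#: estimation, hence the name "simultaneous".
DELAY_SECONDS = {"simultaneous": 0.45, "short": 1.2, "long": 3.2}

#: Accuracy levels as half-widths in color indices around the target.
ACCURACY_WINDOWS = {"exact": 0, "inner": 1, "full": 3}


@dataclass(frozen=True)
class ColorWheelSpec:
    """Geometry of the circular choice stimulus.

    Parameters
    ----------
    n_colors : int
        Number of equidistant hues on the wheel (default 64).
    """

    n_colors: int = 64

    def __post_init__(self) -> None:
        if self.n_colors < 4:
            raise ValueError(f"n_colors must be >= 4, got {self.n_colors}")

    @property
    def step(self) -> float:
        """Angular width of one color wedge in radians."""
        return TWO_PI / self.n_colors

    def chance_level(self, window: int) -> float:
        """Chance probability of landing within ``window`` indices of target.

        With uniform guessing over ``n_colors`` wedges, the probability of a
        response within +/-window colors is (2*window + 1) / n_colors:
        7/64 ~ 11% for the full reward range, 3/64 ~ 5% inner, 1/64 ~ 1.6%
        for the exact color.
        """
        if window < 0 or 2 * window + 1 > self.n_colors:
            raise ValueError(f"invalid accuracy window {window}")
        return (2 * window + 1) / self.n_colors


def index_to_angle(idx, wheel: ColorWheelSpec = ColorWheelSpec()):
    """Angle (radians in [0, 2pi)) of 1-based color index ``idx``."""
    idx = np.asarray(idx)
    if np.any((idx < 1) | (idx > wheel.n_colors)):
        bad = np.atleast_1d(idx)[(np.atleast_1d(idx) < 1) | (np.atleast_1d(idx) > wheel.n_colors)]
        raise ValueError(
            f"color index out of range 1..{wheel.n_colors}: {bad[:5].tolist()}"
        )
    return (idx - 1) * wheel.step


def angle_to_index(angle, wheel: ColorWheelSpec = ColorWheelSpec()):
    """Nearest 1-based color index for an angle (radians, any real).

    A peck exactly on a wedge boundary is assigned to the lower index
    (deterministic tie-break).
    """
    angle = np.asarray(angle, dtype=float)
    k = np.floor(angle / wheel.step + 0.5)
    # exact boundary (half-integer multiples of step) rounds down
    boundary = np.isclose(np.mod(angle / wheel.step + 0.5, 1.0), 0.0)
    k = np.where(boundary, k - 1, k)
    return (np.mod(k, wheel.n_colors)).astype(int) + 1


def wrap_angle(angle):
    """Wrap to [0, 2pi)."""
    return np.mod(angle, TWO_PI)


def signed_angular_error(reported, target):
    """Signed angular deviation of report from target, in (-pi, pi].

    Positive values are counterclockwise displacements of the report relative
    to the target.  Antisymmetric except exactly at pi.
    """
    reported = np.asarray(reported, dtype=float)
    target = np.asarray(target, dtype=float)
    if not (np.all(np.isfinite(reported)) and np.all(np.isfinite(target))):
        raise ValueError("angles must be finite")
    d = np.mod(reported - target, TWO_PI)
    return np.where(d > np.pi, d - TWO_PI, d)


def signed_index_error(response_idx, target_idx, wheel: ColorWheelSpec = ColorWheelSpec()):
    """Signed error in color-index units, in (-n/2, n/2]."""
    d = np.mod(np.asarray(response_idx) - np.asarray(target_idx), wheel.n_colors)
    return np.where(d > wheel.n_colors // 2, d - wheel.n_colors, d).astype(int)


def reward_level(error_in_indices):
    """Pellet count for a signed error in color indices.

    Exact hit -> 3 pellets, +/-1 color -> 2, +/-2 or +/-3 -> 1, beyond the
    full reward range -> 0 (error signal and time-out in the task).
    """
    e = np.abs(np.asarray(error_in_indices))
    return np.select([e == 0, e == 1, e <= 3], [3, 2, 1], default=0)
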