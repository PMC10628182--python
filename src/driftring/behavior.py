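"""Model-free behavioral measures and significance tests.

Performance matrices over the load x delay grid, circular bias and
chance-corrected precision, normalized per-color response frequency,
uniformity (Hodges-Ajne), factorial (two-way ANOVA with partial omega^2,
Friedman + Kendall's W), binomial performance-vs-chance and Cochran's Q
tests, and the serial-dependence curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .wheel import (
    ACCURACY_WINDOWS,
    TWO_PI,
    ColorWheelSpec,
    index_to_angle,
    signed_angular_error,
    signed_index_error,
)
from .trials import response_errors

#: Order of the three load conditions on the performance-matrix axis.
LOAD_CONDITIONS = (("load1", 1, "none"), ("load2_sim", 2, "simultaneous"), ("load2_retro", 2, "retro"))
DELAY_ORDER = ("simultaneous", "short", "long")

#: The "diagonal" of increasing memory demand: load 1 at the shortest delay,
#: load 2 with simultaneous cue at the short delay, load 2 with retro cue at
#: the long delay.
DIAGONAL = (("load1", "simultaneous"), ("load2_sim", "short"), ("load2_retro", "long"))

PRECISION_CAP = 1e3


def _condition_labels(table: pd.DataFrame) -> pd.Series:
    lab = pd.Series("", index=table.index)
    for name, load, cue in LOAD_CONDITIONS:
        lab[(table["load"] == load) & (table["cue"] == cue)] = name
    return lab


def performance_by_condition(
    table: pd.DataFrame, wheel: ColorWheelSpec = ColorWheelSpec()
) -> dict:
    """Proportion correct per (load condition x delay class) per accuracy level.

    Returns ``{"matrices": {level: DataFrame 3x3}, "counts": DataFrame,
    "diagonal": {level: [p1, p2, p3]}}``.  Proportions are of trials whose
    index error falls within the level's window; empty cells are NaN
    (flagged missing, not zero).
    """
    err = np.abs(signed_index_error(table["response_idx"].to_numpy(int), table["target_idx"].to_numpy(int), wheel))
    cond = _condition_labels(table)
    rows = [c[0] for c in LOAD_CONDITIONS]
    counts = pd.DataFrame(0, index=rows, columns=list(DELAY_ORDER))
    mats = {lvl: pd.DataFrame(np.nan, index=rows, columns=list(DELAY_ORDER)) for lvl in ACCURACY_WINDOWS}
    for name in rows:
        for delay in DELAY_ORDER:
            sel = (cond == name) & (table["delay_class"] == delay)
            nsel = int(sel.sum())
            counts.loc[name, delay] = nsel
            if nsel:
                for lvl, win in ACCURACY_WINDOWS.items():
                    mats[lvl].loc[name, delay] = float(np.mean(err[sel.to_numpy()] <= win))
    diagonal = {
        lvl: [mats[lvl].loc[r, c] for r, c in DIAGONAL] for lvl in ACCURACY_WINDOWS
    }
    return {"matrices": mats, "counts": counts, "diagonal": diagonal}


# ---------------------------------------------------------------------------
# circular summaries


def circular_mean(angles) -> float:
    angles = np.asarray(angles, dtype=float)
    return float(np.angle(np.mean(np.exp(1j * angles))))


def resultant_length(angles) -> float:
    angles = np.asarray(angles, dtype=float)
    return float(np.abs(np.mean(np.exp(1j * angles))))


def circular_sd(angles) -> float:
    """sqrt(-2 ln Rbar); 0 for identical angles, large for dispersed ones."""
    rbar = resultant_length(angles)
    if rbar >= 1.0:
        return 0.0
    if rbar <= 0.0:
        return np.inf
    return float(np.sqrt(-2.0 * np.log(rbar)))


def _uniform_inverse_sd_expectation(n: int, n_mc: int = 200, seed: int = 12345) -> float:
    """Monte-Carlo E[1/circular SD] for n uniform angles (chance correction)."""
    rng = np.random.default_rng(seed)
    vals = np.empty(n_mc)
    for i in range(n_mc):
        sd = circular_sd(rng.uniform(0, TWO_PI, size=n))
        vals[i] = min(1.0 / sd, PRECISION_CAP) if sd > 0 else PRECISION_CAP
    return float(vals.mean())


def bias_and_precision(
    errors,
    group_by=None,
    n_mc: int = 200,
    seed: int = 12345,
) -> dict:
    """Mean absolute bias and chance-corrected precision of signed errors.

    Bias is |circular mean| of the errors; precision is 1/circular SD minus
    the Monte-Carlo expectation of 1/circular SD for matched-n uniform draws
    (fixed internal seed), so uniform responding scores ~0.  When
    ``group_by`` (e.g. target color per trial) is given, both measures are
    computed per group and averaged, mirroring per-target-color analysis.
    Degenerate all-identical samples are reported at the documented cap with
    ``degenerate=True``.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("need at least 2 errors")
    if group_by is not None:
        group_by = np.asarray(group_by)
        out = [
            bias_and_precision(errors[group_by == g], None, n_mc, seed)
            for g in np.unique(group_by)
            if np.sum(group_by == g) >= 2  # singleton groups carry no dispersion
        ]
        if not out:
            raise ValueError("no group has >= 2 errors")
        return {
            "bias": float(np.mean([o["bias"] for o in out])),
            "precision": float(np.mean([o["precision"] for o in out])),
            "degenerate": any(o["degenerate"] for o in out),
        }
    bias = abs(circular_mean(errors))
    sd = circular_sd(errors)
    degenerate = sd == 0.0
    raw = PRECISION_CAP if degenerate else min(1.0 / sd, PRECISION_CAP)
    return {
        "bias": float(bias),
        "precision": float(raw - _uniform_inverse_sd_expectation(len(errors), n_mc, seed)),
        "degenerate": degenerate,
    }


def bias_precision_along_diagonal(table: pd.DataFrame, wheel: ColorWheelSpec = ColorWheelSpec(), **kw) -> pd.DataFrame:
    """Per-target-color-averaged bias and precision for the demand diagonal."""
    cond = _condition_labels(table)
    err = response_errors(table, wheel)
    rows = []
    for name, delay in DIAGONAL:
        sel = ((cond == name) & (table["delay_class"] == delay)).to_numpy()
        bp = bias_and_precision(err[sel], group_by=table["target_idx"].to_numpy(int)[sel], **kw)
        rows.append({"condition": name, "delay_class": delay, "n": int(sel.sum()), **bp})
    return pd.DataFrame(rows)


def normalized_response_frequency(table: pd.DataFrame, wheel: ColorWheelSpec = ColorWheelSpec()) -> pd.DataFrame:
    """Per-color response count divided by target incidence (Fig.-4a-style ratio).

    Values > 1 mark colors reported more often than they occurred as target.
    Raises if some color never occurred as a target.
    """
    n = wheel.n_colors
    tcount = np.bincount(table["target_idx"].to_numpy(int), minlength=n + 1)[1:]
    rcount = np.bincount(table["response_idx"].to_numpy(int), minlength=n + 1)[1:]
    if np.any(tcount == 0):
        missing = np.nonzero(tcount == 0)[0][:5] + 1
        raise ValueError(f"colors never used as target: {missing.tolist()}")
    return pd.DataFrame(
        {"color": np.arange(1, n + 1), "target_count": tcount, "response_count": rcount,
         "ratio": rcount / tcount}
    )


# ---------------------------------------------------------------------------
# significance tests


def hodges_ajne_test(angles, exact_limit_ratio: float = 1 / 3, n_perm: int = 10000, seed: int = 0) -> dict:
    """Hodges-Ajne test for non-uniformity of circular data.

    The statistic m is the minimum number of points in any closed
    half-circle.  For m < n/3 the exact tail ``p = (n - 2m) C(n, m) / 2^(n-1)``
    applies; otherwise a permutation (uniform resampling) estimate is used.
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if n < 4:
        raise ValueError("need at least 4 angles")
    m = _half_circle_min(angles)
    if m < n * exact_limit_ratio:
        # log-space evaluation of (n - 2m) C(n, m) / 2^(n-1) to survive large n
        logp = (
            np.log(n - 2 * m)
            + special.gammaln(n + 1) - special.gammaln(m + 1) - special.gammaln(n - m + 1)
            - (n - 1) * np.log(2.0)
        )
        p = float(min(np.exp(logp), 1.0))
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        stats_null = np.array(
            [_half_circle_min(rng.uniform(0, TWO_PI, n)) for _ in range(n_perm)]
        )
        p = float((np.sum(stats_null <= m) + 1) / (n_perm + 1))
        method = "permutation"
    return {"m": int(m), "p": p, "n": n, "method": method}


def _half_circle_min(angles: np.ndarray) -> int:
    """Minimum count in a closed half-circle, by scanning all data boundaries."""
    a = np.sort(np.mod(angles, TWO_PI))
    n = len(a)
    # counts in [b, b+pi) for boundaries just at/after each point and antipode
    bounds = np.concatenate([a, np.mod(a + np.pi, TWO_PI)])
    ext = np.concatenate([a, a + TWO_PI])
    best = n
    for b in bounds:
        lo = np.searchsorted(ext, b, side="left")
        hi = np.searchsorted(ext, b + np.pi, side="right")
        inside = hi - lo  # closed half-circle [b, b+pi]
        best = min(best, n - inside)
    return int(best)


def cochrans_q_test(outcomes) -> dict:
    """Cochran's Q for matched binary outcomes (blocks x groups).

    Q = k(k-1) sum_j (G_j - N/k)^2 / (k sum_i L_i - sum_i L_i^2), chi-square
    with k-1 df.  Rows with zero variance contribute nothing; if the
    denominator vanishes the result is flagged degenerate.
    """
    x = np.asarray(outcomes, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a blocks x groups matrix with >= 2 of each")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary")
    b, k = x.shape
    G = x.sum(axis=0)
    L = x.sum(axis=1)
    N = x.sum()
    denom = k * L.sum() - np.sum(L**2)
    if denom == 0:
        # every block constant: the numerator is also 0, no evidence of a
        # group difference; flagged so callers can tell it apart from Q ~ 0
        return {"Q": 0.0, "df": k - 1, "p": 1.0, "degenerate": True}
    Q = k * (k - 1) * np.sum((G - N / k) ** 2) / denom
    return {"Q": float(Q), "df": k - 1, "p": float(stats.chi2.sf(Q, k - 1)), "degenerate": False}


def binomial_chance_test(k: int, n: int, p0: float) -> float:
    """One-sided exact binomial tail P(X >= k) under chance rate p0."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("require 0 < p0 < 1")
    return float(stats.binom.sf(k - 1, n, p0))


def variance_partitioning(cell_table: pd.DataFrame, response: str = "performance") -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (load x delay) with partial omega^2.

    ``cell_table`` holds one row per session x load x delay cell with the
    cell's performance proportion.  Partial omega^2 per term is
    ``(SS - df * MS_err) / (SS + (N - df) * MS_err)``, the effect size the
    analysis reports as percent explained variance.  Balanced designs are
    assumed; unbalanced empty cells are rejected.
    """
    required = {"session_id", "load_condition", "delay_class", response}
    if not required.issubset(cell_table.columns):
        raise ValueError(f"cell table needs columns {sorted(required)}")
    counts = cell_table.groupby(["load_condition", "delay_class"]).size()
    n_cells = cell_table["load_condition"].nunique() * cell_table["delay_class"].nunique()
    if len(counts) != n_cells or counts.nunique() != 1:
        raise ValueError("unbalanced design: every load x delay cell needs the same session count")
    if counts.iloc[0] < 2:
        raise ValueError("need >= 2 sessions per cell")
    df = cell_table.rename(columns={response: "y"})
    model = ols("y ~ C(load_condition) * C(delay_class)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ms_err = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    N = len(df)
    rows = []
    names = {"C(load_condition)": "load", "C(delay_class)": "delay",
             "C(load_condition):C(delay_class)": "interaction"}
    for term, label in names.items():
        ss, dfe = table.loc[term, "sum_sq"], table.loc[term, "df"]
        omega = (ss - dfe * ms_err) / (ss + (N - dfe) * ms_err)
        rows.append({
            "factor": label, "F": float(table.loc[term, "F"]),
            "p": float(table.loc[term, "PR(>F)"]), "omega_sq_partial": float(omega),
            "omega_sq_partial_clipped": float(max(omega, 0.0)),
        })
    return pd.DataFrame(rows)


def friedman_test(matrix) -> dict:
    """Friedman rank test across conditions with Kendall's W effect size.

    ``matrix`` is blocks x conditions.  Average-rank tie correction applies;
    a fully constant matrix returns chi2 = 0, p = 1, W = 0.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a blocks x conditions matrix with >= 2 of each")
    nb, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    col = ranks.sum(axis=0)
    ss = np.sum((col - nb * (k + 1) / 2.0) ** 2)
    # tie correction per block
    tiecorr = 0.0
    for row in x:
        _, c = np.unique(row, return_counts=True)
        tiecorr += np.sum(c**3 - c)
    denom = nb * k * (k * k - 1) - tiecorr
    if denom <= 0:
        return {"chi2": 0.0, "df": k - 1, "p": 1.0, "kendalls_w": 0.0}
    chi2 = 12.0 * (k - 1) * ss / denom
    return {
        "chi2": float(chi2),
        "df": k - 1,
        "p": float(stats.chi2.sf(chi2, k - 1)),
        "kendalls_w": float(chi2 / (nb * (k - 1))),
    }


# ---------------------------------------------------------------------------
# serial dependence


@dataclass
class SerialBiasCurve:
    """Smoothed signed error as a function of previous-target offset."""

    grid_rad: np.ndarray
    mean_error: np.ndarray
    peak_magnitude_rad: float
    peak_location_deg: float
    n_trials: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_rad": self.grid_rad, "mean_error_rad": self.mean_error})


def serial_dependence_curve(
    table: pd.DataFrame,
    wheel: ColorWheelSpec = ColorWheelSpec(),
    kernel_kappa: float = 16.0,
    n_grid: int = 180,
    min_trials: int = 50,
) -> SerialBiasCurve:
    """Response bias as a function of previous-minus-current target offset.

    Errors are smoothed over the offset axis with a von Mises kernel (default
    concentration ~ 20 degree half-width).  A positive peak at positive
    offsets means attraction toward the previous target.  The curve is
    antisymmetrized before peak extraction so the reported peak reflects the
    odd (directional) component.
    """
    has_prev = table["prev_target_idx"].notna()
    sub = table.loc[has_prev]
    if len(sub) < min_trials:
        raise ValueError(f"need >= {min_trials} trials with a previous target, got {len(sub)}")
    delta = signed_angular_error(
        index_to_angle(sub["prev_target_idx"].to_numpy(int), wheel),
        index_to_angle(sub["target_idx"].to_numpy(int), wheel),
    )
    err = response_errors(sub, wheel)
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False) + np.pi / n_grid
    w = np.exp(kernel_kappa * (np.cos(grid[:, None] - delta[None, :]) - 1.0))
    mean_err = (w @ err) / np.maximum(w.sum(axis=1), 1e-12)
    odd = 0.5 * (mean_err - mean_err[::-1])  # grid is symmetric about 0
    i = int(np.argmax(np.abs(odd)))
    peak_mag = float(odd[i]) if grid[i] > 0 else float(-odd[i])
    peak_loc = float(np.degrees(abs(grid[i])))
    return SerialBiasCurve(grid, mean_err, peak_mag, peak_loc, len(sub))


def session_cell_performance(
    table: pd.DataFrame, window: int = 3, wheel: ColorWheelSpec = ColorWheelSpec()
) -> pd.DataFrame:
    """Per-session x load-condition x delay performance proportions (ANOVA input)."""
    err = np.abs(signed_index_error(table["response_idx"].to_numpy(int), table["target_idx"].to_numpy(int), wheel))
    df = table.assign(correct=(err <= window), load_condition=_condition_labels(table))
    out = (
        df.groupby(["session_id", "load_condition", "delay_class"], observed=True)["correct"]
        .mean()
        .rename("performance")
        .reset_index()
    )
    return out
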