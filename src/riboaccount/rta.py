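"""Ribosome transit assay (RTA) kinetics.

Summarizes flow-cytometric RPM signal into background-subtracted
time-course points, fits a one-phase exponential decay to harringtonine
run-off curves, and converts the fitted half-life into a stalled-ribosome
fraction and a relative elongation rate.

The decay model is empirical: after initiation is blocked, the RPM
signal of run-off-competent ribosomes decays as span * exp(-lambda * t)
toward a plateau contributed by stalled ribosomes,

    S(t) = span * exp(-lambda * t) + plateau,      t_half = ln(2)/lambda.

Elongation rates are anchored to the reference condition of a 70 s RPM
half-life corresponding to ~6 residues/s, with rate inversely
proportional to half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gmean

REFERENCE_T_HALF_S = 70.0
REFERENCE_RATE_AA_PER_S = 6.0


class FitError(RuntimeError):
    """Raised when the decay fit cannot be performed or does not converge."""


@dataclass
class DecayFit:
    """One-phase exponential decay fit result."""

    span: float
    plateau: float
    lambda_per_s: float
    residual_sse: float
    n_points: int
    ci_t_half: tuple[float, float] | None = None

    @property
    def s0(self) -> float:
        return self.span + self.plateau

    @property
    def t_half_s(self) -> float:
        return math.log(2.0) / self.lambda_per_s


@dataclass
class ElongationEstimate:
    """Elongation rate inferred from an RPM run-off half-life."""

    rate_aa_per_s: float
    t_half_s: float
    reference_t_half_s: float = REFERENCE_T_HALF_S
    reference_rate_aa_per_s: float = REFERENCE_RATE_AA_PER_S

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.reference_t_half_s / self.t_half_s - 1.0)


def summarize_rpm(
    events: pd.DataFrame,
    statistic: Literal["median", "geomean"] = "median",
    floor_at_zero: bool = True,
    background_label: str | None = "background",
    treatment: str | None = None,
) -> pd.DataFrame:
    """Collapse per-cell events into background-subtracted time-course points.

    Parameters
    ----------
    events
        Flow-event table with columns ``condition``, ``treatment``,
        ``chase_time_s``, ``signal``.
    statistic
        Population summary: ``"median"`` (default, robust to lognormal
        tails) or ``"geomean"``.
    floor_at_zero
        Floor negative background-subtracted values at 0.
    background_label
        Treatment label of the autofluorescence control population; pass
        ``None`` to skip background subtraction.
    treatment
        Restrict the sample population to this treatment label; default
        is every non-background row.

    Returns
    -------
    DataFrame with one row per (condition, chase_time_s): columns
    ``mfi`` (background-subtracted summary), ``n`` cells and ``se``.
    """
    if events.empty:
        raise ValueError("events table is empty")
    stat_fn = {"median": np.median, "geomean": gmean}[statistic]
    is_bg = (
        events["treatment"].eq(background_label)
        if background_label is not None
        else pd.Series(False, index=events.index)
    )
    sample = events[~is_bg]
    if treatment is not None:
        sample = sample[sample["treatment"].eq(treatment)]
    if sample.empty:
        raise ValueError("no sample events after treatment filtering")
    out = []
    for (cond, t), grp in sample.groupby(["condition", "chase_time_s"], sort=True):
        x = grp["signal"].to_numpy(dtype=float)
        bg_val = 0.0
        if background_label is not None:
            bg = events[is_bg & events["condition"].eq(cond) & events["chase_time_s"].eq(t)]
            if bg.empty:
                raise ValueError(
                    f"no '{background_label}' events for condition={cond!r}, "
                    f"chase_time_s={t}"
                )
            bg_val = float(stat_fn(bg["signal"].to_numpy(dtype=float)))
        mfi = float(stat_fn(x)) - bg_val
        if floor_at_zero and mfi < 0:
            mfi = 0.0
        out.append(
            {
                "condition": cond,
                "chase_time_s": float(t),
                "mfi": mfi,
                "n": len(x),
                "se": float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0,
            }
        )
    return pd.DataFrame(out)


def normalize_to_max(points: pd.DataFrame, column: str = "mfi") -> pd.DataFrame:
    """Rescale a time course so its maximum summary value is 100."""
    top = points[column].max()
    if not top > 0:
        raise ValueError("cannot normalize: no point with positive signal")
    out = points.copy()
    out[column] = out[column] * (100.0 / top)
    if "se" in out.columns:
        out["se"] = out["se"] * (100.0 / top)
    return out


def _decay(t: np.ndarray, span: float, lam: float, plateau: float) -> np.ndarray:
    return span * np.exp(-lam * t) + plateau


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    plateau0 = float(y.min())
    span0 = float(y.max() - y.min())
    resid = y - plateau0
    mask = resid > max(1e-12, 1e-6 * span0)
    if mask.sum() >= 2 and span0 > 0:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        lam0 = max(-float(slope), 1e-6)
    else:
        lam0 = math.log(2.0) / max(t.max(), 1.0)
    return max(span0, 1e-12), lam0, plateau0


def fit_one_phase_decay(
    points: pd.DataFrame,
    fix_plateau: float | None = None,
    n_restarts: int = 5,
    seed: int | None = None,
) -> DecayFit:
    """Least-squares fit of S(t) = span*exp(-lambda t) + plateau.

    Requires at least 3 distinct chase times (4 when the plateau is
    free). Initialization takes the plateau from the smallest summary
    value, the span from the range, and lambda from a log-linear
    regression of the plateau-subtracted signal; up to ``n_restarts``
    jittered restarts are attempted before declaring failure.
    """
    t = points["chase_time_s"].to_numpy(dtype=float)
    y = points["mfi"].to_numpy(dtype=float)
    n_distinct = np.unique(t).size
    need = 3 if fix_plateau is not None else 4
    if n_distinct < need:
        raise FitError(
            f"need >= {need} distinct chase times "
            f"({'fixed' if fix_plateau is not None else 'free'} plateau); got {n_distinct}"
        )
    if np.ptp(y) <= 1e-12 * max(abs(y.max()), 1.0):
        raise FitError(
            "signal is flat across chase times; decay rate is unidentifiable "
            "(consistent with a fully stalled ribosome population)"
        )
    span0, lam0, plateau0 = _initial_guess(t, y)
    if fix_plateau is not None:
        plateau0 = fix_plateau
        span0 = max(float(y.max()) - fix_plateau, 1e-12)
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        jitter = 1.0 if attempt == 0 else float(rng.lognormal(0, 0.5))
        try:
            if fix_plateau is not None:
                popt, _ = curve_fit(
                    lambda tt, sp, la: _decay(tt, sp, la, fix_plateau),
                    t,
                    y,
                    p0=[span0 * jitter, lam0 * jitter],
                    bounds=([0.0, 1e-12], [np.inf, np.inf]),
                    maxfev=10000,
                )
                span, lam, plateau = float(popt[0]), float(popt[1]), float(fix_plateau)
            else:
                popt, _ = curve_fit(
                    _decay,
                    t,
                    y,
                    p0=[span0 * jitter, lam0 * jitter, max(plateau0, 0.0)],
                    bounds=([0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
                    maxfev=10000,
                )
                span, lam, plateau = map(float, popt)
            sse = float(np.sum((_decay(t, span, lam, plateau) - y) ** 2))
            return DecayFit(
                span=span, plateau=plateau, lambda_per_s=lam, residual_sse=sse, n_points=len(t)
            )
        except (RuntimeError, ValueError) as err:  # non-convergence
            last_err = err
    raise FitError(
        f"one-phase decay fit failed after {n_restarts + 1} attempts: {last_err}"
    )


def bootstrap_t_half_from_events(
    events: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    statistic: Literal["median", "geomean"] = "median",
    background_label: str | None = "background",
    fix_plateau: float | None = None,
    ci_level: float = 0.95,
) -> tuple[DecayFit, np.ndarray]:
    """Fit the run-off decay and bootstrap its half-life CI.

    Cells are resampled with replacement within each chase timepoint
    (sample and background populations independently), the summary curve
    is recomputed, and the fit repeated; the percentile interval of the
    bootstrap half-lives at ``ci_level`` is attached to the point fit.
    Returns ``(fit, bootstrap_t_half_draws)``; non-converging replicates
    are dropped.
    """
    rng = np.random.default_rng(seed)
    points = summarize_rpm(events, statistic=statistic, background_label=background_label)
    fit = fit_one_phase_decay(points, fix_plateau=fix_plateau)
    stat_fn = {"median": np.median, "geomean": gmean}[statistic]

    is_bg = (
        events["treatment"].eq(background_label)
        if background_label is not None
        else pd.Series(False, index=events.index)
    )
    times = np.sort(events["chase_time_s"].unique())
    sample_arrays = [
        events.loc[~is_bg & events["chase_time_s"].eq(t), "signal"].to_numpy(dtype=float)
        for t in times
    ]
    bg_arrays = [
        events.loc[is_bg & events["chase_time_s"].eq(t), "signal"].to_numpy(dtype=float)
        for t in times
    ]
    draws = []
    for _ in range(n_boot):
        mfi = np.empty(times.size)
        for i, (xs, xb) in enumerate(zip(sample_arrays, bg_arrays)):
            s = float(stat_fn(rng.choice(xs, size=xs.size, replace=True)))
            b = float(stat_fn(rng.choice(xb, size=xb.size, replace=True))) if xb.size else 0.0
            mfi[i] = max(s - b, 0.0)
        pts = pd.DataFrame({"chase_time_s": times, "mfi": mfi})
        try:
            draws.append(fit_one_phase_decay(pts, fix_plateau=fix_plateau, n_restarts=2).t_half_s)
        except FitError:
            continue
    draws_arr = np.asarray(draws)
    if draws_arr.size:
        alpha = (1.0 - ci_level) / 2.0
        fit.ci_t_half = (
            float(np.quantile(draws_arr, alpha)),
            float(np.quantile(draws_arr, 1.0 - alpha)),
        )
    return fit, draws_arr


def stalled_fraction(fit: DecayFit) -> float:
    """Fraction of puromycylated ribosomes that do not run off: plateau/(span+plateau)."""
    total = fit.span + fit.plateau
    if total <= 0:
        raise ValueError("span + plateau must be positive")
    return fit.plateau / total


def stalled_fraction_from_points(
    points: pd.DataFrame, late_time_s: float = 900.0
) -> float:
    """Model-free stalled fraction: residual signal at a late chase time over t=0 signal.

    Mirrors subtracting the signal remaining after a long (15 min)
    harringtonine pretreatment, by which time all run-off-competent
    ribosomes have cleared even long transcripts.
    """
    t = points["chase_time_s"].to_numpy(dtype=float)
    y = points["mfi"].to_numpy(dtype=float)
    y0 = float(y[np.argmin(t)])
    ylate = float(y[np.argmin(np.abs(t - late_time_s))])
    if y0 <= 0:
        raise ValueError("signal at t=0 must be positive")
    return min(max(ylate / y0, 0.0), 1.0)


def estimate_stalled_fraction(points: pd.DataFrame) -> float:
    """Stalled fraction from the decay fit, falling back to the late/initial signal ratio.

    A fully stalled population gives a flat time course on which the
    decay rate is unidentifiable; the model-free ratio handles that case.
    """
    try:
        return stalled_fraction(fit_one_phase_decay(points))
    except FitError:
        return stalled_fraction_from_points(points, late_time_s=float(points["chase_time_s"].max()))


def elongation_rate_from_half_life(
    t_half_s: float,
    ref_t_half_s: float = REFERENCE_T_HALF_S,
    ref_rate_aa_per_s: float = REFERENCE_RATE_AA_PER_S,
) -> ElongationEstimate:
    """Scale the reference elongation rate by inverse proportionality of half-lives.

    rate = ref_rate * ref_t_half / t_half, so rate * t_half is invariant
    (420 aa at the 6 aa/s / 70 s anchor).
    """
    if t_half_s <= 0:
        raise ValueError("t_half_s must be positive")
    rate = ref_rate_aa_per_s * ref_t_half_s / t_half_s
    return ElongationEstimate(
        rate_aa_per_s=rate,
        t_half_s=t_half_s,
        reference_t_half_s=ref_t_half_s,
        reference_rate_aa_per_s=ref_rate_aa_per_s,
    )


def max_orf_cleared(rate_aa_per_s: float, duration_s: float) -> float:
    """Longest open reading frame (residues) a ribosome clears in ``duration_s``."""
    if rate_aa_per_s < 0 or duration_s < 0:
        raise ValueError("rate and duration must be non-negative")
    return rate_aa_per_s * duration_s
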