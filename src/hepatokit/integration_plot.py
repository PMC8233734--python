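"""Integration-plot (graphical) estimation of tissue uptake rate constants.

For an irreversibly-trapping tissue at early times, the amount of tracer per
mL tissue X_t divided by the blood concentration C_t is linear in the
normalized blood exposure AUC_blood(0-t)/C_t:

    X_t / C_t = k_uptake * AUC_blood(0-t) / C_t + V_E

so the slope of the early linear part of the plot estimates the uptake rate
constant k_uptake (mL/min/mL tissue) and the intercept the initial
distribution volume V_E (mL/mL).  Backflux from the tissue bends the plot
downward at later times, so only an early window is regressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tac import TimeActivityCurve, curve_from_tac

__all__ = ["IntegrationPlotResult", "integration_plot"]


@dataclass
class IntegrationPlotResult:
    """OLS estimates from the integration plot."""

    k_uptake: float  # mL/min/mL tissue
    v_e: float  # mL/mL
    r_squared: float
    window: tuple[int, int]  # (first, last) frame index used, inclusive
    n_points: int

    def __post_init__(self):
        if not 0 <= self.window[0] <= self.window[1]:
            raise ValueError("invalid window")


def _plot_coordinates(tissue, blood, idx):
    c_blood = blood.values[idx]
    if np.any(c_blood <= 0):
        raise ValueError("blood concentration must be positive on the window")
    blood_curve = curve_from_tac(blood)
    auc = blood_curve.integral(blood.midtimes[idx])
    x = auc / c_blood
    y = tissue.values[idx] / c_blood
    return x, y


def _ols(x, y):
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def integration_plot(
    tissue: TimeActivityCurve,
    blood: TimeActivityCurve,
    window: str | tuple[float, float] = "0:5",
    policy: str = "fixed",
    min_points: int = 4,
    r2_threshold: float = 0.95,
) -> IntegrationPlotResult:
    """Estimate k_uptake and V_E by OLS on the integration plot.

    ``policy="fixed"`` (default) regresses all frames whose midtime falls in
    the ``window`` interval (minutes, "start:end" string or tuple).
    ``policy="adaptive"`` instead takes the longest initial run of frames
    (at least ``min_points``) whose regression keeps r^2 >= ``r2_threshold``.
    """
    if tissue.schedule != blood.schedule:
        raise ValueError("tissue and blood must share one schedule")
    mid = blood.midtimes

    if policy == "fixed":
        if isinstance(window, str):
            a, b = (float(s) for s in window.split(":"))
        else:
            a, b = window
        idx = np.flatnonzero((mid >= a) & (mid <= b))
        if idx.size < 3:
            raise ValueError(
                f"window {a}:{b} min covers {idx.size} frames; need >= 3"
            )
        x, y = _plot_coordinates(tissue, blood, idx)
        slope, intercept, r2 = _ols(x, y)
        win = (int(idx[0]), int(idx[-1]))
        n = idx.size
    elif policy == "adaptive":
        if mid.size < min_points:
            raise ValueError("fewer frames than min_points")
        best = None
        for last in range(min_points - 1, mid.size):
            idx = np.arange(0, last + 1)
            x, y = _plot_coordinates(tissue, blood, idx)
            slope, intercept, r2 = _ols(x, y)
            if r2 >= r2_threshold:
                best = (slope, intercept, r2, (0, last), idx.size)
            elif best is not None:
                break
        if best is None:
            raise ValueError(
                f"no initial window of >= {min_points} frames reaches "
                f"r^2 >= {r2_threshold}"
            )
        slope, intercept, r2, win, n = best
    else:
        raise ValueError(f"unknown window policy {policy!r}")

    return IntegrationPlotResult(
        k_uptake=slope, v_e=intercept, r_squared=r2, window=win, n_points=n
    )
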