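"""Flow-weighted dual-input function for the liver.

The liver receives tracer from the hepatic artery (concentration taken equal
to the image-derived arterial blood curve) and the portal vein.  The portal
concentration is not measured; it is modelled as the arterial curve passed
through a single-compartment gut-transit system with impulse response
``k_pv * exp(-k_pv t)`` — a unit-gain kernel, so the portal curve is a
smoothed, delayed copy of the arterial one preserving total exposure.  The
dual input mixes the two with the hepatic arterial flow fraction f_HA
(default 0.17 of total hepatic blood flow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .curves import PiecewiseLinearCurve

__all__ = [
    "HEPATIC_ARTERIAL_FLOW_FRACTION",
    "DualInputConfig",
    "portal_curve",
    "dual_input",
    "ArterialModel",
    "synthesize_arterial",
]

HEPATIC_ARTERIAL_FLOW_FRACTION = 0.17


@dataclass(frozen=True)
class DualInputConfig:
    """Dual-input settings: arterial flow fraction and portal transit rate."""

    f_ha: float = HEPATIC_ARTERIAL_FLOW_FRACTION
    k_pv_mode: str = "fitted"  # "fitted" | "fixed"
    k_pv_init: float = 2.0  # min^-1
    k_pv_bounds: tuple[float, float] = (0.5, 20.0)

    def __post_init__(self):
        if not 0.0 <= self.f_ha <= 1.0:
            raise ValueError("f_ha must lie in [0, 1]")
        if self.k_pv_mode not in ("fitted", "fixed"):
            raise ValueError("k_pv_mode must be 'fitted' or 'fixed'")
        lo, hi = self.k_pv_bounds
        if not (0 < lo < hi):
            raise ValueError("k_pv_bounds must satisfy 0 < lo < hi")
        if self.k_pv_init <= 0:
            raise ValueError("k_pv_init must be positive")


def portal_curve(arterial, k_pv: float, t):
    """Portal-vein concentration C_PV(t) = k_pv * (C_A * exp(-k_pv .))(t).

    ``arterial`` may be a :class:`PiecewiseLinearCurve` (evaluated exactly by
    segment recursion) or any callable (evaluated by adaptive quadrature).
    """
    if k_pv <= 0:
        raise ValueError("k_pv must be positive")
    if isinstance(arterial, PiecewiseLinearCurve):
        return k_pv * arterial.exp_conv(k_pv, t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        if ti == 0:
            out[i] = 0.0
            continue
        val, _ = quad(
            lambda s: arterial(s) * np.exp(-k_pv * (ti - s)),
            0.0, ti, epsabs=1e-12, epsrel=1e-10, limit=400,
        )
        out[i] = k_pv * val
    return out if np.ndim(t) else float(out[0])


def dual_input(arterial, portal, cfg: DualInputConfig, t):
    """C_in(t) = f_HA * C_A(t) + (1 - f_HA) * C_PV(t).

    Curve arguments may be callables or precomputed values at ``t``.
    """
    c_a = arterial(t) if callable(arterial) else np.asarray(arterial, dtype=float)
    c_pv = portal(t) if callable(portal) else np.asarray(portal, dtype=float)
    return cfg.f_ha * c_a + (1.0 - cfg.f_ha) * c_pv


class ArterialModel:
    """Bolus-shaped arterial blood curve: a sum of decaying exponentials
    minus a fast rise term forcing C_A(0) = 0 and a single early peak.

    C_A(t) = sum_i A_i exp(-lambda_i t) - (sum_i A_i) exp(-lambda_0 t)
    """

    def __init__(self, amplitudes, rates, rise_rate: float = 20.0):
        a = np.asarray(amplitudes, dtype=float)
        lam = np.asarray(rates, dtype=float)
        if a.shape != lam.shape or a.ndim != 1:
            raise ValueError("amplitudes and rates must be equal-length 1-D")
        if np.any(a < 0):
            raise ValueError("amplitudes must be nonnegative")
        if np.any(lam <= 0) or rise_rate <= 0:
            raise ValueError("rates must be positive")
        if a.size and rise_rate <= lam.max():
            raise ValueError("rise_rate must exceed every washout rate")
        self.amplitudes = a
        self.rates = lam
        self.rise_rate = float(rise_rate)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for a, lam in zip(self.amplitudes, self.rates):
            out = out + a * np.exp(-lam * t)
        out = out - self.amplitudes.sum() * np.exp(-self.rise_rate * t)
        return out if out.ndim else float(out)

    def sample(self, t_end: float, dt: float = 0.005) -> PiecewiseLinearCurve:
        """Dense piecewise-linear version for exact-convolution arithmetic."""
        t = np.arange(0.0, t_end + dt / 2, dt)
        return PiecewiseLinearCurve(t, np.maximum(self(t), 0.0))


def synthesize_arterial(
    amplitudes=(15.0, 4.0, 1.0),
    rates=(3.0, 0.4, 0.02),
    rise_rate: float = 20.0,
) -> ArterialModel:
    """Build a bolus arterial curve; defaults give a %ID/mL-scale mouse
    blood curve peaking within the first minute and washing out over 40 min.
    """
    model = ArterialModel(amplitudes, rates, rise_rate)
    tt = np.linspace(0, 40, 2001)
    if np.any(model(tt) < -1e-9):
        raise ValueError("parameters yield negative concentrations")
    return model
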