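"""Sigmoid regularization of breakthrough curves and the pulse-response peak.

A discretized pore-bundle breakthrough is a staircase; before the method of
moments can be applied it is smoothed with a shifted/anchored logistic

    s(t) = a / (1 + exp(-b[(t - t_lag) - c])) - a / (1 + exp(b c)),  t > t_lag
    s(t) = 0,                                                        t <= t_lag

whose subtraction term anchors s(t_lag) = 0 exactly. The pulse response is
the analytic derivative of the fitted curve; its maximum a*b/4 sits at
t = t_lag + c. t_lag is not a free parameter: it is the residence time of the
fastest retained pore, known from the bundle, so the least-squares problem
has three unknowns (a, b, c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .core import Signal
from .pore_model import PoreBundle

__all__ = ["SigmoidFit", "SigmoidFitError", "fit_sigmoid", "t_lag_from_bundle", "derivative_peak"]

_RESTART_SEED = 1234


class SigmoidFitError(RuntimeError):
    """Sigmoid fit failed; carries the optimizer diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None) -> None:
        super().__init__(message)
        self.details = details or {}


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted parameters of the anchored logistic breakthrough model."""

    a: float
    b: float
    c: float
    t_lag: float
    ssr: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"sigmoid fit requires a, b > 0, got a={self.a}, b={self.b}")

    @property
    def plateau(self) -> float:
        """Limit of the fitted curve as t -> infinity: a - a/(1 + exp(b c))."""
        return self.a - self.a * expit(-self.b * self.c)

    def value(self, t) -> np.ndarray:
        """Fitted breakthrough, forced to 0 for t <= t_lag."""
        t = np.asarray(t, dtype=float)
        s = self.a * expit(self.b * ((t - self.t_lag) - self.c)) - self.a * expit(
            -self.b * self.c
        )
        return np.where(t > self.t_lag, s, 0.0)

    def derivative(self, t) -> np.ndarray:
        """Analytic time derivative of the fitted breakthrough (the pulse peak)."""
        t = np.asarray(t, dtype=float)
        p = expit(self.b * ((t - self.t_lag) - self.c))
        return np.where(t > self.t_lag, self.a * self.b * p * (1.0 - p), 0.0)


def t_lag_from_bundle(bundle: PoreBundle) -> float:
    """Time before any solute exits: the residence time of the largest retained
    pore, min_k tau(r_k)."""
    return bundle.t_lag


def fit_sigmoid(
    curve: Signal,
    t_lag: float,
    max_restarts: int = 5,
    plateau_rtol: float = 0.05,
) -> SigmoidFit:
    """Least-squares fit of the anchored logistic to a breakthrough curve.

    All samples with t > t_lag enter the (unweighted) residual. Initial
    guesses: a = final value, c = time-to-half-plateau past t_lag,
    b = 4 * (max slope) / a; on failure up to ``max_restarts`` log-normally
    jittered restarts are tried with a fixed seed, keeping results
    bit-reproducible.

    Raises
    ------
    SigmoidFitError
        If the curve is degenerate (flat) or no restart converges to a fit
        whose plateau lies within ``plateau_rtol`` of the curve's final value.
    """
    t = curve.times
    y = curve.values
    mask = t > t_lag
    if mask.sum() < 4:
        raise SigmoidFitError(
            f"only {int(mask.sum())} samples beyond t_lag={t_lag:g}; need >= 4"
        )
    tm, ym = t[mask], y[mask]
    y_final = float(ym[-1])
    if y_final <= 0 or np.ptp(ym) < 1e-12 * max(1.0, abs(y_final)):
        raise SigmoidFitError("degenerate flat curve: nothing to fit")

    a0 = y_final
    i_half = int(np.searchsorted(ym, 0.5 * a0))
    c0 = max(tm[min(i_half, tm.size - 1)] - t_lag, 1e-6)
    slope = float(np.max(np.diff(y) / np.diff(t)))
    b0 = max(4.0 * slope / a0, 1e-6)

    def residual(p):
        a, b, c = p
        return a * expit(b * ((tm - t_lag) - c)) - a * expit(-b * c) - ym

    rng = np.random.default_rng(_RESTART_SEED)
    lower = np.array([1e-12, 1e-12, 1e-12])
    upper = np.array([np.inf, np.inf, np.inf])
    x0 = np.array([a0, b0, c0])
    last_details: dict = {}
    for attempt in range(max_restarts + 1):
        guess = x0 if attempt == 0 else x0 * rng.lognormal(0.0, 0.3, size=3)
        res = least_squares(residual, np.clip(guess, lower, upper), bounds=(lower, upper))
        if res.success:
            fit = SigmoidFit(
                a=float(res.x[0]),
                b=float(res.x[1]),
                c=float(res.x[2]),
                t_lag=float(t_lag),
                ssr=float(2.0 * res.cost),
                n_points=int(tm.size),
            )
            if abs(fit.plateau - y_final) <= plateau_rtol * abs(y_final):
                return fit
            last_details = {"plateau": fit.plateau, "final_value": y_final}
        else:
            last_details = {"status": res.status, "message": res.message}
    raise SigmoidFitError(
        f"sigmoid fit did not converge after {max_restarts} restarts", last_details
    )


def derivative_peak(fit: SigmoidFit, time_grid: np.ndarray) -> Signal:
    """Sample the analytic derivative of the fit on ``time_grid`` as a pulse peak."""
    t = np.asarray(time_grid, dtype=float)
    return Signal(t, fit.derivative(t), kind="pulse_response")
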