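"""Phase resetting curves and the stimulus/recovery interval geometry.

A phase resetting curve (PRC) f(θ) gives the fractional change of an
oscillator's cycle period, (P1 − P0)/P0, caused by a perturbation delivered
at phase θ = ts/P0.  Positive values are delays throughout this package: a
spike arriving at phase θ *decrements* the oscillator's phase by f(θ), so a
delay-only PRC (f ≥ 0) can only lengthen cycles.

The same information can be replotted as an interaction curve in the
(stimulus interval, recovery interval) plane:

    tr(ts) = P · (1 + f(ts / P)) − ts

which preserves time units and is the object whose intersections (for the
two coupled neurons) predict one-to-one phase locking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

logger = logging.getLogger("prcmap")

__all__ = [
    "PRCPoints",
    "PRCFunction",
    "InteractionCurve",
    "eval_prc",
    "fit_prc",
    "scale_prc",
    "interaction_curve",
    "two_pulse_recovery",
    "SpikePrecedesSecondInputError",
]


class SpikePrecedesSecondInputError(ValueError):
    """The neuron would have fired before the second input arrived."""


class PRCDomainError(ValueError):
    """Phase outside [0, 1]; the PRC is only trusted on the measured domain."""


class PRCFitError(ValueError):
    """Least-squares PRC fit could not be computed (rank deficiency)."""


# ---------------------------------------------------------------------------
# measurement records
# ---------------------------------------------------------------------------


class PRCPoints:
    """Table of PRC measurements.

    Each record holds the stimulus interval ``ts_ms``, the unperturbed
    period ``P0_ms`` (average of the cycles preceding the perturbation) and
    the perturbed period ``P1_ms``.  The phase ``theta = ts/P0`` and the
    reset ``(P1 − P0)/P0`` are derived, never stored independently.
    """

    def __init__(self, ts_ms, P0_ms, P1_ms):
        ts = np.asarray(ts_ms, dtype=float)
        p0 = np.asarray(P0_ms, dtype=float)
        p1 = np.asarray(P1_ms, dtype=float)
        if not (ts.shape == p0.shape == p1.shape) or ts.ndim != 1:
            raise ValueError("ts_ms, P0_ms, P1_ms must be 1-d and equally long")
        if np.any(~np.isfinite(ts)) or np.any(~np.isfinite(p0)) or np.any(~np.isfinite(p1)):
            raise ValueError("non-finite PRC measurement")
        if np.any(p0 <= 0):
            raise ValueError("unperturbed period P0 must be positive")
        theta = ts / p0
        if np.any(theta < 0) or np.any(theta >= 1 + 1e-12):
            raise ValueError("stimulus phase ts/P0 must lie in [0, 1)")
        self.ts_ms = ts
        self.P0_ms = p0
        self.P1_ms = p1

    @property
    def theta(self) -> np.ndarray:
        return self.ts_ms / self.P0_ms

    @property
    def reset(self) -> np.ndarray:
        return (self.P1_ms - self.P0_ms) / self.P0_ms

    def __len__(self) -> int:
        return self.ts_ms.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ts_ms": self.ts_ms,
                "P0_ms": self.P0_ms,
                "P1_ms": self.P1_ms,
                "theta": self.theta,
                "reset": self.reset,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PRCPoints(n={len(self)})"


# ---------------------------------------------------------------------------
# smooth resetting functions
# ---------------------------------------------------------------------------


@dataclass
class PRCFunction:
    """Smooth resetting function f(θ) on [0, 1].

    ``base`` is the unscaled representation; evaluation returns
    ``scale_factor * base(θ)``.  The cached extrema (``f_min``, ``peak``,
    ``argmax``) always refer to the *scaled* function.  ``kind`` is one of
    ``"polynomial"``, ``"spline"`` or ``"bump"`` (the analytic synthetic
    family).
    """

    kind: str
    base: Callable[[np.ndarray], np.ndarray]
    scale_factor: float = 1.0
    coefficients: np.ndarray | None = None
    se: float | None = None  # sum of squared residuals of the fit, if fitted
    f_min: float = field(default=np.nan)
    peak: float = field(default=np.nan)
    argmax: float = field(default=np.nan)
    argmin: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale_factor):
            raise ValueError("scale_factor must be finite")
        if np.isnan(self.f_min) or np.isnan(self.peak):
            self._cache_extrema()

    # -- evaluation ---------------------------------------------------------
    def __call__(self, theta):
        th = np.asarray(theta, dtype=float)
        if np.any(th < -1e-12) or np.any(th > 1 + 1e-12):
            raise PRCDomainError(
                f"phase {th} outside [0, 1]; PRCs are not extrapolated"
            )
        th = np.clip(th, 0.0, 1.0)
        out = self.scale_factor * np.asarray(self.base(th), dtype=float)
        if np.any(~np.isfinite(out)):
            raise ValueError("PRC evaluated to a non-finite value")
        return out if out.ndim else float(out)

    # -- extrema cache ------------------------------------------------------
    def _cache_extrema(self, n_grid: int = 4097) -> None:
        grid = np.linspace(0.0, 1.0, n_grid)
        vals = self.scale_factor * np.asarray(self.base(grid), dtype=float)
        i_max = int(np.argmax(vals))
        i_min = int(np.argmin(vals))

        def refine(i, sign):
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, n_grid - 1)]
            if hi - lo <= 0:
                return grid[i], vals[i]
            res = minimize_scalar(
                lambda t: -sign * self.scale_factor * float(self.base(t)),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-12},
            )
            return float(res.x), sign * -res.fun

        self.argmax, self.peak = refine(i_max, +1.0)
        self.argmin, self.f_min = refine(i_min, -1.0)

    # -- scaling ------------------------------------------------------------
    def scaled(self, ratio: float) -> "PRCFunction":
        """Return a copy whose values (not phases) are multiplied by ratio."""
        if not (np.isfinite(ratio) and ratio > 0):
            raise ValueError("scale ratio must be positive and finite")
        return PRCFunction(
            kind=self.kind,
            base=self.base,
            scale_factor=self.scale_factor * ratio,
            coefficients=self.coefficients,
            se=self.se,
            f_min=self.f_min * ratio,
            peak=self.peak * ratio,
            argmax=self.argmax,
            argmin=self.argmin,
        )

    @property
    def delay_only(self) -> bool:
        return self.f_min >= -1e-12

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PRCFunction(kind={self.kind!r}, peak={self.peak:.4g} at "
            f"θ={self.argmax:.3f}, f_min={self.f_min:.4g})"
        )


def eval_prc(prc: PRCFunction, theta) -> float:
    """Evaluate a PRC at phase theta (thin functional wrapper)."""
    return prc(theta)


def scale_prc(prc: PRCFunction, ratio: float) -> PRCFunction:
    """Linearly scale a PRC's amplitude, e.g. to emulate a weaker conductance."""
    return prc.scaled(ratio)


def fit_prc(points: PRCPoints, order: int = 3) -> PRCFunction:
    """Least-squares polynomial fit of reset versus phase.

    Parameters
    ----------
    points : PRCPoints
        Measurement table; needs at least ``order + 2`` records whose
        phases span at least half of [0, 1].
    order : int
        Polynomial order, 3 or 4.

    Returns
    -------
    PRCFunction
        kind ``"polynomial"`` with the residual sum of squares in ``se``.
    """
    if order not in (3, 4):
        raise ValueError("polynomial order must be 3 or 4")
    th = points.theta
    y = points.reset
    if len(points) < order + 2:
        raise PRCFitError(f"need at least {order + 2} points for order {order}")
    if th.max() - th.min() < 0.5:
        raise PRCFitError("measured phases must span at least half of [0, 1]")
    if np.unique(th).size < order + 1:
        raise PRCFitError("duplicated phases only: design matrix is rank deficient")
    coeffs = np.polynomial.polynomial.polyfit(th, y, deg=order)
    poly = np.polynomial.Polynomial(coeffs)
    se = float(np.sum((y - poly(th)) ** 2))
    return PRCFunction(kind="polynomial", base=poly, coefficients=coeffs, se=se)


def spline_prc(theta: Sequence[float], values: Sequence[float]) -> PRCFunction:
    """Cubic-spline representation (used for noiseless model-neuron PRCs)."""
    th = np.asarray(theta, dtype=float)
    v = np.asarray(values, dtype=float)
    order = np.argsort(th)
    cs = CubicSpline(th[order], v[order])
    return PRCFunction(kind="spline", base=cs)


# ---------------------------------------------------------------------------
# interaction curves
# ---------------------------------------------------------------------------


@dataclass
class InteractionCurve:
    """Samples of the stimulus→recovery map tr(ts) = P(1 + f(ts/P)) − ts."""

    role: str  # "B" or "M"
    ts_ms: np.ndarray
    tr_ms: np.ndarray
    prc: PRCFunction
    P_ms: float
    orientation: str = "ts_on_x"
    two_pulse: bool = False

    def __call__(self, ts):
        """Continuous evaluation of the recovery interval."""
        ts = np.asarray(ts, dtype=float)
        out = self.P_ms * (1.0 + np.asarray(self.prc(ts / self.P_ms))) - ts
        return out if out.ndim else float(out)


def interaction_curve(
    prc: PRCFunction, P: float, n_samples: int = 512, role: str = "B"
) -> InteractionCurve:
    """Tabulate the interaction curve of one oscillator on ts ∈ [0, P]."""
    if not (np.isfinite(P) and P > 0):
        raise ValueError("period P must be positive")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    ts = np.linspace(0.0, P, int(n_samples))
    tr = P * (1.0 + np.asarray(prc(ts / P))) - ts
    return InteractionCurve(role=role, ts_ms=ts, tr_ms=tr, prc=prc, P_ms=float(P))


def two_pulse_recovery(prc: PRCFunction, P: float, P_partner: float, ts: float) -> float:
    """Recovery interval after two inputs separated by the partner's period.

    The first input arrives at θ1 = ts/P and decrements the phase by f(θ1);
    the second input arrives one partner period later, at
    θ2 = θ1 − f(θ1) + P_partner/P, and the returned interval tr* runs from
    the *second* input to the next spike:

        tr* = P · (1 − θ2 + f(θ2))

    Used to reinject map trajectories across a phase slip (when one neuron
    spikes twice within a single cycle of the other).
    """
    if not (np.isfinite(P) and P > 0 and np.isfinite(P_partner) and P_partner > 0):
        raise ValueError("periods must be positive")
    if not (0.0 <= ts <= P):
        raise ValueError("stimulus interval must lie in [0, P]")
    theta1 = ts / P
    theta1p = theta1 - float(prc(theta1))
    if theta1p < 0.0:
        logger.warning("two_pulse_recovery: phase %.4g clamped to 0", theta1p)
        theta1p = 0.0
    theta2 = theta1p + P_partner / P
    if theta2 >= 1.0:
        raise SpikePrecedesSecondInputError(
            f"neuron fires (θ={theta2:.4f} ≥ 1) before the second input arrives"
        )
    return P * (1.0 - theta2 + float(prc(theta2)))
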