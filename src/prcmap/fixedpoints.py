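"""Fixed points of the coupled interval map and the locking period range.

One network cycle maps the model neuron's stimulus interval through both
interaction curves:

    ts_M  →  tr_M = T_M(ts_M) = ts_B  →  tr_B = T_B(ts_B) = next ts_M

so 1:1 phase-locked modes are the roots of F(ts) = T_B(T_M(ts)) − ts, i.e.
the intersections of the two interaction curves in the ts-tr plane, and a
root is stable iff the one-cycle return map g = T_B ∘ T_M has |g′| < 1
there (equivalent to the graphical slope criterion for the two curves).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .prc import PRCFunction

__all__ = [
    "FixedPoint",
    "FixedPointSet",
    "LockingRange",
    "OverlapReport",
    "find_fixed_points",
    "locking_period_range",
    "confidence_overlap",
]

_NEUTRAL_TOL = 1e-6  # |g'| within this of 1 → neutral


@dataclass
class FixedPoint:
    """A 1:1 phase-locked mode candidate: ts_M* = tr_B*, ts_B* = tr_M*."""

    ts_M: float
    tr_M: float  # equals ts_B*
    tr_B: float  # equals ts_M* at a true fixed point
    stability: str  # "stable" | "unstable" | "neutral"
    return_map_derivative: float

    def to_dict(self) -> dict:
        return {
            "ts_M_ms": self.ts_M,
            "tr_M_ms": self.tr_M,
            "tr_B_ms": self.tr_B,
            "stability": self.stability,
            "return_map_derivative": self.return_map_derivative,
        }


@dataclass
class FixedPointSet:
    """All isolated fixed points, plus a neutral continuum if one exists.

    When the two interaction curves coincide over an interval (degenerate,
    e.g. two flat PRCs with matched effective periods), no point list is
    meaningful; ``neutral_interval`` carries the ts_M interval instead.
    """

    points: List[FixedPoint] = field(default_factory=list)
    neutral_interval: Optional[Tuple[float, float]] = None

    @property
    def stable(self) -> List[FixedPoint]:
        return [p for p in self.points if p.stability == "stable"]

    @property
    def unstable(self) -> List[FixedPoint]:
        return [p for p in self.points if p.stability == "unstable"]

    def __len__(self) -> int:
        return len(self.points)


def _interval_maps(
    prc_B: PRCFunction, P_B: float, prc_M: PRCFunction, P_M: float
) -> Tuple[Callable, Callable]:
    def T_M(ts):
        return P_M * (1.0 + np.asarray(prc_M(np.asarray(ts) / P_M))) - ts

    def T_B(ts):
        return P_B * (1.0 + np.asarray(prc_B(np.asarray(ts) / P_B))) - ts

    return T_B, T_M


def find_fixed_points(
    prc_B: PRCFunction,
    P_B: float,
    prc_M: PRCFunction,
    P_M: float,
    n_grid: int = 2048,
) -> FixedPointSet:
    """Locate and classify all intersections of the two interaction curves.

    Roots of F(ts_M) = T_B(T_M(ts_M)) − ts_M are bracketed on a uniform
    grid over the admissible domain (both PRCs evaluated inside [0, 1], so
    ts_M ≤ P_M and T_M(ts_M) ≤ P_B) and refined by Brent's method to
    1e-9·P_M.  Stability comes from the central-difference derivative of
    the return map g (|g′| < 1 ⇔ stable; a derivative within 1e-6 of ±1 is
    reported neutral).
    """
    if not (P_B > 0 and P_M > 0):
        raise ValueError("periods must be positive")
    T_B, T_M = _interval_maps(prc_B, P_B, prc_M, P_M)

    ts = np.linspace(0.0, P_M, int(n_grid))
    tr_m = T_M(ts)
    valid = (tr_m >= 0.0) & (tr_m <= P_B)
    F = np.full_like(ts, np.nan)
    F[valid] = T_B(tr_m[valid]) - ts[valid]

    def Ffun(x: float) -> float:
        return float(T_B(float(T_M(x))) - x)

    # degenerate continuum: F vanishes along a stretch of the grid
    tol_cont = 1e-9 * max(P_B, P_M)
    near_zero = valid & (np.abs(F) < tol_cont)
    if near_zero.sum() >= max(8, int(0.03 * n_grid)):
        idx = np.flatnonzero(near_zero)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        longest = max(runs, key=len)
        if len(longest) >= max(8, int(0.03 * n_grid)):
            return FixedPointSet(
                points=[], neutral_interval=(float(ts[longest[0]]), float(ts[longest[-1]]))
            )

    roots: List[float] = []
    for i in range(len(ts) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        f0, f1 = F[i], F[i + 1]
        if f0 == 0.0:
            roots.append(float(ts[i]))
        elif f0 * f1 < 0.0:
            roots.append(float(brentq(Ffun, ts[i], ts[i + 1], xtol=1e-9 * P_M)))
    if valid[-1] and F[-1] == 0.0:
        roots.append(float(ts[-1]))

    # dedupe near-identical roots
    uniq: List[float] = []
    for r in sorted(roots):
        if not uniq or r - uniq[-1] > 1e-7 * P_M:
            uniq.append(r)

    points = []
    h = 1e-6 * P_M
    for r in uniq:
        lo = max(r - h, 0.0)
        hi = min(r + h, P_M)
        g = lambda x: Ffun(x) + x
        try:
            gprime = (g(hi) - g(lo)) / (hi - lo)
        except ValueError:  # derivative stencil left the admissible domain
            gprime = np.nan
        if np.isnan(gprime) or abs(abs(gprime) - 1.0) < _NEUTRAL_TOL:
            stability = "neutral"
        elif abs(gprime) < 1.0:
            stability = "stable"
        else:
            stability = "unstable"
        tr_m_star = float(T_M(r))
        points.append(
            FixedPoint(
                ts_M=r,
                tr_M=tr_m_star,
                tr_B=float(T_B(tr_m_star)),
                stability=stability,
                return_map_derivative=float(gprime),
            )
        )
    return FixedPointSet(points=points)


@dataclass
class LockingRange:
    """Contiguous range of biological periods with a stable fixed point."""

    P_lo: float
    P_hi: float
    grid: np.ndarray
    stable_mask: np.ndarray
    empty: bool = False

    @property
    def width(self) -> float:
        return 0.0 if self.empty else self.P_hi - self.P_lo

    def contains(self, P: float) -> bool:
        return (not self.empty) and self.P_lo <= P <= self.P_hi

    def to_dict(self) -> dict:
        return {
            "P_lo_ms": None if self.empty else self.P_lo,
            "P_hi_ms": None if self.empty else self.P_hi,
            "empty": self.empty,
            "grid_resolution_ms": float(np.diff(self.grid).mean()) if len(self.grid) > 1 else 0.0,
        }


def locking_period_range(
    prc_B: PRCFunction,
    prc_M: PRCFunction,
    P_M: float,
    P_B_grid: np.ndarray,
    mu: Optional[float] = None,
) -> LockingRange:
    """Sweep the biological period and mark where a stable fixed point exists.

    Shifting the biological interaction curve along the diagonal (longer
    period → up and right) moves, creates or destroys intersections; the
    returned range is the contiguous stable block containing ``mu`` (or the
    widest block when ``mu`` is not supplied).  An empty range is a valid
    outcome meaning locking is impossible anywhere on the grid.
    """
    grid = np.asarray(P_B_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("P_B_grid must be monotone increasing with ≥2 points")
    mask = np.zeros(len(grid), dtype=bool)
    for i, pb in enumerate(grid):
        fps = find_fixed_points(prc_B, pb, prc_M, P_M)
        mask[i] = len(fps.stable) > 0

    if not mask.any():
        return LockingRange(np.nan, np.nan, grid, mask, empty=True)

    idx = np.flatnonzero(mask)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    chosen = None
    if mu is not None:
        for run in runs:
            if grid[run[0]] <= mu <= grid[run[-1]]:
                chosen = run
                break
    if chosen is None:
        chosen = max(runs, key=lambda r: grid[r[-1]] - grid[r[0]])
    return LockingRange(float(grid[chosen[0]]), float(grid[chosen[-1]]), grid, mask)


@dataclass
class OverlapReport:
    """Overlap of the period's 95% band (μ ± 2σ_eff) with the locking range."""

    verdict: str  # "contained" | "partial" | "disjoint" | "no_locking_regime"
    escaping_fraction: float
    band: Tuple[float, float]
    range_: Optional[Tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "escaping_fraction": self.escaping_fraction,
            "band_ms": list(self.band),
            "locking_range_ms": None if self.range_ is None else list(self.range_),
        }


def confidence_overlap(rng: LockingRange, mu: float, sigma_eff: float) -> OverlapReport:
    """Report whether μ ± 2σ_eff stays inside the phase-locking regime."""
    if sigma_eff < 0:
        raise ValueError("sigma_eff must be non-negative")
    lo, hi = mu - 2.0 * sigma_eff, mu + 2.0 * sigma_eff
    if rng.empty:
        return OverlapReport("no_locking_regime", 1.0, (lo, hi), None)
    if sigma_eff == 0.0:
        inside = rng.contains(mu)
        return OverlapReport(
            "contained" if inside else "disjoint",
            0.0 if inside else 1.0,
            (lo, hi),
            (rng.P_lo, rng.P_hi),
        )
    overlap = max(0.0, min(hi, rng.P_hi) - max(lo, rng.P_lo))
    frac_out = 1.0 - overlap / (hi - lo)
    if overlap == 0.0:
        verdict = "disjoint"
    elif frac_out <= 1e-12:
        verdict = "contained"
        frac_out = 0.0
    else:
        verdict = "partial"
    return OverlapReport(verdict, frac_out, (lo, hi), (rng.P_lo, rng.P_hi))
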