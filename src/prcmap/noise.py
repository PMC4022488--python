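"""Intrinsic-noise models for the biological oscillator.

Three stochastic descriptions of cycle-to-cycle variability are supported,
plus a noiseless reference:

``prc_gaussian``
    A zero-mean Gaussian of standard deviation σ (phase units) is added to
    the phase resetting each time an input is received.  No history
    dependence; the implied standard deviation of the perturbed period is
    μσ/(1 + f_min).

``period_gaussian``
    The period of each cycle is drawn independently as P·(1 + σX); one draw
    per biological cycle, reused for both the phase and the recovery
    interval within that cycle.  σ_eff = μσ.

``ou_period``
    The period itself performs an Ornstein-Uhlenbeck random walk: Gaussian
    kicks scaled by √dt accumulate and are pulled back to the mean μ with
    time constant τ (Euler–Maruyama update):

        P[k+1] = P[k] + (μ − P[k])·dt/τ + σ·√dt·X

    The accumulation from sample to sample is what gives this model its
    history dependence; the long-run standard deviation is σ·√(τ/2).
    ``tau=inf`` disables mean reversion (pure Brownian period).

σ units differ by kind: phase fraction (prc_gaussian), fraction of period
(period_gaussian) and ms·ms^{-1/2} (ou_period).  All times are ms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .prc import PRCFunction

logger = logging.getLogger("prcmap")

__all__ = [
    "NoiseSpec",
    "PeriodProcessState",
    "ou_step",
    "sample_period",
    "sample_reset",
    "effective_sd",
    "PERIOD_FLOOR_FRACTION",
]

KINDS = ("none", "prc_gaussian", "period_gaussian", "ou_period")

# sampled/updated periods below this fraction of μ are clamped (a delay PRC
# cannot produce a negative or vanishing cycle; the regime is unphysical)
PERIOD_FLOOR_FRACTION = 0.1


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one intrinsic-noise process."""

    kind: str = "none"
    sigma: float = 0.0
    tau_ms: Optional[float] = None
    mu_ms: float = 1000.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; choose from {KINDS}")
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError("sigma must be finite and non-negative")
        if not (np.isfinite(self.mu_ms) and self.mu_ms > 0):
            raise ValueError("mean period mu_ms must be positive")
        if self.kind == "ou_period":
            if self.tau_ms is None or not self.tau_ms > 0:
                raise ValueError("ou_period requires tau_ms > 0 (inf allowed)")

    def with_(self, **kw) -> "NoiseSpec":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "sigma": self.sigma,
            "tau_ms": self.tau_ms,
            "mu_ms": self.mu_ms,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(
            kind=d.get("kind", "none"),
            sigma=float(d.get("sigma", 0.0)),
            tau_ms=(None if d.get("tau_ms") is None else float(d["tau_ms"])),
            mu_ms=float(d.get("mu_ms", 1000.0)),
            seed=d.get("seed"),
        )


@dataclass
class PeriodProcessState:
    """Mutable state of the period process of one oscillator."""

    current_period: float
    last_sample_time: float
    rng: np.random.Generator

    @classmethod
    def init(cls, spec: NoiseSpec, rng: np.random.Generator, t0: float = 0.0):
        return cls(current_period=spec.mu_ms, last_sample_time=t0, rng=rng)


def _clamp_period(p: float, mu: float) -> float:
    floor = PERIOD_FLOOR_FRACTION * mu
    if p < floor:
        logger.warning("period %.3f ms clamped to %.3f ms (10%% of mean)", p, floor)
        return floor
    return p


def ou_step(state: PeriodProcessState, spec: NoiseSpec, dt: float) -> PeriodProcessState:
    """Advance the OU period process by dt (Euler–Maruyama update, in place).

    Raises on non-positive dt; warns when dt exceeds τ (the explicit update
    is only a faithful discretization for dt ≲ τ).
    """
    if spec.kind != "ou_period":
        raise ValueError("ou_step requires an ou_period noise spec")
    if not dt > 0:
        raise ValueError("dt must be positive")
    tau = spec.tau_ms
    if math.isfinite(tau) and dt > tau:
        logger.warning("OU step dt=%.3g ms exceeds tau=%.3g ms", dt, tau)
    p = state.current_period
    drift = 0.0 if not math.isfinite(tau) else (spec.mu_ms - p) * dt / tau
    kick = spec.sigma * math.sqrt(dt) * state.rng.standard_normal()
    state.current_period = _clamp_period(p + drift + kick, spec.mu_ms)
    state.last_sample_time += dt
    return state


def sample_period(state: PeriodProcessState, spec: NoiseSpec) -> float:
    """Period to use for the oscillator's next cycle.

    ``period_gaussian`` draws P·(1 + σX) once per biological cycle (the
    caller invokes this at the biological neuron's spike and reuses the
    value for both θ and tr within the cycle); ``ou_period`` returns the
    current OU estimate; the others return μ.
    """
    if spec.kind == "period_gaussian":
        p = spec.mu_ms * (1.0 + spec.sigma * state.rng.standard_normal())
        state.current_period = _clamp_period(p, spec.mu_ms)
    elif spec.kind == "ou_period":
        pass  # current_period is advanced by ou_step at sampling events
    else:
        state.current_period = spec.mu_ms
    return state.current_period


def sample_reset(
    prc: PRCFunction, theta: float, spec: NoiseSpec, rng: np.random.Generator
) -> float:
    """Phase resetting applied for one received input, f(θ) (+ σX if noisy)."""
    f = float(prc(theta))
    if spec.kind == "prc_gaussian" and spec.sigma > 0:
        f += spec.sigma * rng.standard_normal()
    return f


def effective_sd(spec: NoiseSpec, prc: Optional[PRCFunction] = None) -> float:
    """Long-run standard deviation of the intrinsic period, in ms.

    prc_gaussian  → μσ/(1 + f_min)   (needs the PRC for its minimum)
    period_gaussian → μσ
    ou_period     → σ·√(τ/2)   (stationary sd of the discretized process)
    none          → 0
    """
    if spec.kind == "none":
        return 0.0
    if spec.kind == "period_gaussian":
        return spec.mu_ms * spec.sigma
    if spec.kind == "prc_gaussian":
        if prc is None:
            raise ValueError("prc_gaussian effective sd requires the PRC (f_min)")
        return spec.mu_ms * spec.sigma / (1.0 + prc.f_min)
    # ou_period
    if not math.isfinite(spec.tau_ms):
        return math.inf
    return spec.sigma * math.sqrt(spec.tau_ms / 2.0)
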