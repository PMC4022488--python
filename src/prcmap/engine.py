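"""Event-driven simulation of the two-oscillator pulse-coupled map.

Between firing events each oscillator's phase advances at constant velocity
1/P; when a neuron fires, its own phase resets from 1 to 0 and the partner's
phase is decremented by the (possibly noisy) phase resetting evaluated at
the partner's current phase.  The next event is always the neuron with the
shortest recovery interval tr = P·(1 − θ).

The biological oscillator ("B") carries one of the intrinsic-noise models of
:mod:`prcmap.noise`; the model oscillator ("M") is noiseless with a constant
intrinsic period.  For the Ornstein-Uhlenbeck period process, a new period
estimate is sampled at every event involving B (its own spike or a received
input) with dt equal to the time elapsed since the previous sample.  Because
each interval's length is itself generated from the estimate in effect at
the interval's start, this elapsed time coincides with the deterministic
approximations used when the interval is not known in advance (the recovery
interval computed from the pre-update estimate, or the previous period for
an unperturbed cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .noise import NoiseSpec, PeriodProcessState, ou_step, sample_period, sample_reset
from .prc import PRCFunction, PRCPoints

logger = logging.getLogger("prcmap")

__all__ = [
    "OscillatorSpec",
    "SpikeRecord",
    "UnsupportedFiringPatternError",
    "simulate_circuit",
    "simulate_prc_protocol",
]

_TIE_EPS = 1e-12


class UnsupportedFiringPatternError(RuntimeError):
    """A neuron fired three or more times within one partner cycle."""


@dataclass
class OscillatorSpec:
    """Immutable description of one oscillator: PRC, mean period and noise."""

    name: str
    prc: PRCFunction
    period_ms: float
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if not self.period_ms > 0:
            raise ValueError("period_ms must be positive")
        if abs(self.noise.mu_ms - self.period_ms) > 1e-9:
            # keep the noise-model mean and the oscillator period consistent
            self.noise = self.noise.with_(mu_ms=self.period_ms)


@dataclass
class SpikeRecord:
    """Spike times, per-event log, and the hidden intrinsic-period trace.

    ``events`` has one row per spike with the receiving partner's stimulus
    interval, its scheduled recovery interval, and the reset applied to it.
    The truth channel (``truth_t_ms``, ``truth_P_ms``) logs every resample
    of the biological neuron's intrinsic period and is never consumed by the
    analysis operations — it exists for testing and diagnostics only.
    """

    spikes_B: np.ndarray
    spikes_M: np.ndarray
    events: pd.DataFrame
    truth_t_ms: np.ndarray
    truth_P_ms: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def duration_ms(self) -> float:
        return float(self.meta.get("duration_ms", max(self.spikes_B[-1], self.spikes_M[-1])))


class _OscState:
    __slots__ = ("spec", "theta", "pstate", "last_spike")

    def __init__(self, spec: OscillatorSpec, theta0: float, rng: np.random.Generator):
        self.spec = spec
        self.theta = float(theta0)
        self.pstate = PeriodProcessState.init(spec.noise, rng)
        self.last_spike = -theta0 * spec.period_ms  # nominal previous spike
        if spec.noise.kind == "period_gaussian":
            sample_period(self.pstate, spec.noise)

    @property
    def period(self) -> float:
        return self.pstate.current_period


def _resample_at_B_event(st: _OscState, t: float) -> bool:
    """Resample B's period process at a sampling event; True if changed."""
    spec = st.spec.noise
    if spec.kind == "ou_period":
        dt = t - st.pstate.last_sample_time
        if dt > 0:
            ou_step(st.pstate, spec, dt)
            return True
        return False
    return False


def simulate_circuit(
    oscillators: Sequence[OscillatorSpec],
    duration_s: float,
    seed: int,
    theta_B0: float = 0.0,
    theta_M0: Optional[float] = None,
) -> SpikeRecord:
    """Simulate the coupled circuit for ``duration_s`` seconds.

    Parameters
    ----------
    oscillators : (OscillatorSpec, OscillatorSpec)
        The biological-side oscillator first, the model oscillator second.
        Only the first may carry a noise model.
    duration_s : float
        Simulated time in seconds.
    seed : int
        Seeds every random draw (noise and, unless pinned, the model
        neuron's initial phase).
    theta_B0, theta_M0 : float
        Initial phases; ``theta_M0=None`` draws uniformly per seed.
    """
    if hasattr(oscillators, "oscillators"):
        oscillators = oscillators.oscillators()  # ScenarioPreset duck-typing
    osc_B, osc_M = oscillators
    if osc_M.noise.kind != "none":
        raise ValueError("the model oscillator is noiseless by construction")
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    duration_ms = 1000.0 * duration_s
    rng = np.random.default_rng(seed)
    if theta_M0 is None:
        theta_M0 = float(rng.uniform(0.0, 1.0))

    B = _OscState(osc_B, theta_B0, rng)
    M = _OscState(osc_M, theta_M0, rng)
    B.pstate.last_sample_time = 0.0

    t = 0.0
    spikes = {"B": [], "M": []}
    ev_time, ev_neuron, ev_ts, ev_tr, ev_reset = [], [], [], [], []
    truth_t, truth_P = [0.0], [B.period]
    last_winner, streak = None, 0

    def clamp_phase(theta: float, who: str) -> float:
        if theta < 0.0:
            logger.warning("%s phase %.4g clamped to 0 after reset", who, theta)
            return 0.0
        if theta >= 1.0:
            logger.debug("%s phase %.4g clamped below 1 after reset", who, theta)
            return 1.0 - 1e-12
        return theta

    while t < duration_ms:
        tr_B = B.period * (1.0 - B.theta)
        tr_M = M.period * (1.0 - M.theta)
        # tie: the biological neuron fires first (fixed, measure-zero order)
        winner, loser = ("B", "M") if tr_B <= tr_M + _TIE_EPS else ("M", "B")
        dt = tr_B if winner == "B" else tr_M
        t += dt
        B.theta += dt / B.period
        M.theta += dt / M.period

        w = B if winner == "B" else M
        l = M if winner == "B" else B

        # --- the winner spikes -------------------------------------------
        spikes[winner].append(t)
        if winner == last_winner:
            streak += 1
            if streak >= 3:
                raise UnsupportedFiringPatternError(
                    f"neuron {winner} fired {streak} times in a row; the map "
                    "supports at most two consecutive spikes per neuron"
                )
        else:
            last_winner, streak = winner, 1
        w.theta = 0.0
        w.last_spike = t
        if winner == "B":
            if osc_B.noise.kind == "period_gaussian":
                sample_period(B.pstate, osc_B.noise)  # one draw per cycle
                truth_t.append(t)
                truth_P.append(B.period)
            elif _resample_at_B_event(B, t):
                truth_t.append(t)
                truth_P.append(B.period)

        # --- the loser receives the input --------------------------------
        ts_phys = t - l.last_spike
        theta_pre = min(l.theta, 1.0 - 1e-12)
        if loser == "B":
            if _resample_at_B_event(B, t):  # OU case 1: dt = ts exactly
                truth_t.append(t)
                truth_P.append(B.period)
            delta = sample_reset(l.spec.prc, theta_pre, osc_B.noise, rng)
        else:
            delta = float(l.spec.prc(theta_pre))
        l.theta = clamp_phase(theta_pre - delta, loser)

        ev_time.append(t)
        ev_neuron.append(winner)
        ev_ts.append(ts_phys)
        ev_tr.append(l.period * (1.0 - l.theta))
        ev_reset.append(delta)

    events = pd.DataFrame(
        {
            "time_ms": ev_time,
            "neuron": ev_neuron,
            "ts_ms": ev_ts,
            "tr_ms": ev_tr,
            "reset_applied": ev_reset,
        }
    )
    return SpikeRecord(
        spikes_B=np.asarray(spikes["B"]),
        spikes_M=np.asarray(spikes["M"]),
        events=events,
        truth_t_ms=np.asarray(truth_t),
        truth_P_ms=np.asarray(truth_P),
        meta={
            "seed": seed,
            "duration_ms": duration_ms,
            "theta_B0": theta_B0,
            "theta_M0": theta_M0,
            "noise": osc_B.noise.to_dict(),
            "P_B_ms": osc_B.period_ms,
            "P_M_ms": osc_M.period_ms,
        },
    )


def simulate_prc_protocol(
    oscillator: OscillatorSpec,
    n_points: int = 20,
    seed: int = 0,
    n_unperturbed: int = 5,
) -> PRCPoints:
    """Simulate the PRC measurement protocol on a single noisy oscillator.

    For each of ``n_points`` stimulus phases evenly spaced in (0, 1):
    ``n_unperturbed`` cycles elapse (the period process evolving freely),
    their mean gives the unperturbed period P0, then one perturbation is
    applied at ts = θ·P0 and the perturbed period P1 = ts + tr is recorded.
    The period process is carried continuously across the whole protocol,
    as in the experiment.
    """
    if n_points < n_unperturbed:
        raise ValueError(f"need at least {n_unperturbed} points")
    spec = oscillator.noise
    rng = np.random.default_rng(seed)
    pstate = PeriodProcessState.init(spec, rng)
    prc = oscillator.prc

    thetas = (np.arange(n_points) + 0.5) / n_points
    t = 0.0
    pstate.last_sample_time = 0.0
    rec_ts, rec_p0, rec_p1 = [], [], []

    def spike_update(t_now: float) -> None:
        # a new period estimate is sampled at every spike
        if spec.kind == "ou_period":
            dt = t_now - pstate.last_sample_time
            if dt > 0:
                ou_step(pstate, spec, dt)
        else:
            sample_period(pstate, spec)

    for theta_target in thetas:
        observed = []
        for _ in range(n_unperturbed):
            spike_update(t)
            cycle = pstate.current_period
            observed.append(cycle)
            t += cycle
        spike_update(t)  # spike that starts the perturbed cycle
        p_start = pstate.current_period
        P0 = float(np.mean(observed))
        ts = theta_target * P0
        t_input = t + ts
        if spec.kind == "ou_period":
            ou_step(pstate, spec, ts)  # case 1: elapsed interval known
        p_rec = pstate.current_period
        theta_dyn = ts / p_start
        if theta_dyn > 1.0:
            logger.warning(
                "protocol: stimulus at θ=%.3f beyond the noisy cycle; clamped", theta_dyn
            )
            theta_dyn = 1.0
        delta = sample_reset(prc, theta_dyn, spec, rng)
        theta_p = theta_dyn - delta
        if theta_p < 0.0:
            theta_p = 0.0
        elif theta_p > 1.0:
            theta_p = 1.0
        tr = p_rec * (1.0 - theta_p)
        rec_ts.append(ts)
        rec_p0.append(P0)
        rec_p1.append(ts + tr)
        t = t_input + tr

    return PRCPoints(rec_ts, rec_p0, rec_p1)
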