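"""Network phases, motif segmentation, bifurcation counts, circular statistics.

The network phase φ_net of one model-neuron cycle is the position of the
biological spike within it, ts_M/(ts_M + tr_M).  Records are segmented into
phase-locked episodes (phase confined to a ±0.1 band for ≥20 cycles),
phase-slipping episodes (monotone circular progression, one neuron lapping
the other) and "other"; a bifurcation is a transition between locking and
slipping.  The first 10 network phases of a record are always discarded as
transient by the downstream operations (the raw series keeps everything).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .engine import SpikeRecord, simulate_circuit

__all__ = [
    "NetworkPhaseSeries",
    "MotifSegmentation",
    "CircularStats",
    "InsufficientDataError",
    "network_phases",
    "classify_motifs",
    "circular_stats",
    "metrics_report",
    "multiseed_metrics",
    "DISCARD_CYCLES",
    "LOCK_WINDOW",
    "LOCK_BAND",
    "SLIP_RUN",
]

DISCARD_CYCLES = 10  # transient cycles removed before any metric
LOCK_WINDOW = 20  # cycles a phase must stay confined to count as locked
LOCK_BAND = 0.2  # total width of the ±0.1 confinement band
SLIP_RUN = 5  # consecutive same-sign increments that mark progression


class InsufficientDataError(ValueError):
    """Too few usable network phases to compute metrics."""


@dataclass
class NetworkPhaseSeries:
    """Cycle-indexed network phase series (raw; nothing discarded)."""

    cycle: np.ndarray  # model-neuron cycle index
    ts_M: np.ndarray
    tr_M: np.ndarray
    phi: np.ndarray  # ts_M / (ts_M + tr_M), in [0, 1)
    P_net: np.ndarray  # network period ts_M + tr_M
    slip_marker_cycles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __len__(self) -> int:
        return len(self.phi)

    def retained(self) -> "NetworkPhaseSeries":
        """Drop the first DISCARD_CYCLES phases (transient)."""
        k = DISCARD_CYCLES
        if len(self.cycle) > k:
            kept_markers = self.slip_marker_cycles[self.slip_marker_cycles >= self.cycle[k]]
        else:
            kept_markers = self.slip_marker_cycles[:0]
        return NetworkPhaseSeries(
            cycle=self.cycle[k:],
            ts_M=self.ts_M[k:],
            tr_M=self.tr_M[k:],
            phi=self.phi[k:],
            P_net=self.P_net[k:],
            slip_marker_cycles=kept_markers,
        )


def network_phases(record: SpikeRecord) -> NetworkPhaseSeries:
    """Compute one network phase per model-neuron cycle containing a
    biological spike.

    Cycles containing zero or two biological spikes cannot yield a phase;
    they are logged as slip markers (one neuron lapped the other there).
    """
    tM = np.asarray(record.spikes_M, dtype=float)
    tB = np.asarray(record.spikes_B, dtype=float)
    if len(tM) < 2 or len(tB) < 1:
        raise InsufficientDataError("need at least two model spikes and one biological spike")

    cycles, ts_l, tr_l, phi_l, pn_l = [], [], [], [], []
    # biological spikes inside each model cycle [tM[i], tM[i+1])
    counts, _ = np.histogram(tB, bins=tM)
    markers = np.flatnonzero(counts != 1)
    pos = np.searchsorted(tM, tB, side="right") - 1
    in_cycle = (pos >= 0) & (pos < len(tM) - 1)
    tB_in = tB[in_cycle]
    pos_in = pos[in_cycle]
    for i in np.flatnonzero(counts == 1):
        b = tB_in[pos_in == i][0]
        ts = b - tM[i]
        tr = tM[i + 1] - b
        cycles.append(i)
        ts_l.append(ts)
        tr_l.append(tr)
        phi_l.append(ts / (ts + tr))
        pn_l.append(ts + tr)

    if len(phi_l) < 12:
        raise InsufficientDataError(
            f"only {len(phi_l)} network phases; at least 12 model-neuron cycles "
            "containing a biological spike are required"
        )
    return NetworkPhaseSeries(
        cycle=np.asarray(cycles, dtype=int),
        ts_M=np.asarray(ts_l),
        tr_M=np.asarray(tr_l),
        phi=np.asarray(phi_l),
        P_net=np.asarray(pn_l),
        slip_marker_cycles=np.asarray(markers, dtype=int),
    )


# ---------------------------------------------------------------------------
# motif segmentation
# ---------------------------------------------------------------------------


@dataclass
class MotifSegmentation:
    """Episode labels partitioning the retained cycles, plus the NB count."""

    episodes: List[Tuple[int, int, str]]  # (start, end inclusive, label) in retained index
    labels: np.ndarray  # per retained cycle: "locked" | "slipping" | "other"
    nb: int  # number of locked ↔ slipping transitions

    def fraction(self, label: str) -> float:
        return float(np.mean(self.labels == label)) if len(self.labels) else 0.0


def _circular_increments(phi: np.ndarray) -> np.ndarray:
    """Per-cycle phase increments mapped to (−0.5, 0.5]."""
    d = np.diff(phi)
    d = np.mod(d + 0.5, 1.0) - 0.5
    d[d == -0.5] = 0.5
    return d


def classify_motifs(series: NetworkPhaseSeries) -> MotifSegmentation:
    """Segment a network-phase series into locked / slipping / other episodes.

    Locked: every cycle covered by some 20-cycle window whose circularly
    unwrapped phase range is ≤ 0.2 (the ±0.1 band without assuming an
    anchor value); maximal such stretches form locked episodes.  A maximal
    non-locked segment is labelled slipping when it shows monotone circular
    progression — a wrap event (including model cycles with 0 or 2
    biological spikes) or ≥5 consecutive same-sign increments — and
    "other" otherwise.  NB counts adjacencies between locked and slipping
    episodes.
    """
    retained = series.retained()
    phi = retained.phi
    n = len(phi)
    if n == 0:
        return MotifSegmentation([], np.array([], dtype=object), 0)
    d = _circular_increments(phi)
    u = np.concatenate([[phi[0]], phi[0] + np.cumsum(d)])  # unwrapped

    labels = np.array(["other"] * n, dtype=object)
    locked = np.zeros(n, dtype=bool)
    w = LOCK_WINDOW
    if n >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        win = sliding_window_view(u, w)
        ok = (win.max(axis=1) - win.min(axis=1)) <= LOCK_BAND
        for i in np.flatnonzero(ok):
            locked[i : i + w] = True
    labels[locked] = "locked"

    # wrap evidence: large raw jumps, and cycles where one neuron lapped the
    # other (no computable phase)
    raw_jump = np.abs(np.diff(phi)) > 0.5
    lap_after = np.zeros(n - 1 if n > 1 else 0, dtype=bool)
    if len(retained.slip_marker_cycles) and n > 1:
        for mc in retained.slip_marker_cycles:
            j = int(np.searchsorted(retained.cycle, mc)) - 1
            if 0 <= j < len(lap_after):
                lap_after[j] = True
    wrap = raw_jump | lap_after if n > 1 else raw_jump

    # label non-locked segments
    i = 0
    while i < n:
        if locked[i]:
            i += 1
            continue
        j = i
        while j < n and not locked[j]:
            j += 1
        seg = slice(i, j)  # maximal non-locked segment [i, j)
        slipping = False
        if j - i >= 2:
            dseg = d[i : j - 1]
            if np.any(wrap[i : j - 1]):
                slipping = True
            else:
                signs = np.sign(dseg)
                run = best = 0
                prev = 0.0
                for s in signs:
                    if s != 0 and s == prev:
                        run += 1
                    elif s != 0:
                        run = 1
                        prev = s
                    else:
                        run = 0
                        prev = 0.0
                    best = max(best, run)
                if best >= SLIP_RUN:
                    slipping = True
        labels[seg] = "slipping" if slipping else "other"
        i = j

    # episodes and NB
    episodes: List[Tuple[int, int, str]] = []
    start = 0
    for k in range(1, n + 1):
        if k == n or labels[k] != labels[start]:
            episodes.append((start, k - 1, str(labels[start])))
            start = k
    nb = 0
    for (a, b) in zip(episodes, episodes[1:]):
        if {a[2], b[2]} == {"locked", "slipping"}:
            nb += 1
    return MotifSegmentation(episodes=episodes, labels=labels, nb=nb)


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------


@dataclass
class CircularStats:
    X: float
    Y: float
    R2: float
    phi_ave: float  # radians in (−π, π]

    def to_dict(self) -> dict:
        return {"X": self.X, "Y": self.Y, "R2": self.R2, "phi_ave": self.phi_ave}


def circular_stats(series: NetworkPhaseSeries) -> CircularStats:
    """Vector strength of the spike-timing angles 2π·ts_M,n/P_n.

    R² = X² + Y² with X, Y the mean cosine and sine; 1 means a perfectly
    consistent phasic relationship, 0 a uniform one.  The mean angle comes
    from atan2 so the quadrant is preserved.
    """
    retained = series.retained()
    if len(retained) < 1:
        raise InsufficientDataError("no retained cycles for circular statistics")
    ang = 2.0 * np.pi * retained.ts_M / retained.P_net
    X = float(np.mean(np.cos(ang)))
    Y = float(np.mean(np.sin(ang)))
    return CircularStats(X=X, Y=Y, R2=X * X + Y * Y, phi_ave=float(np.arctan2(Y, X)))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def metrics_report(record: SpikeRecord) -> dict:
    """The three per-record metrics: NB, fraction locked, and R²."""
    series = network_phases(record)
    seg = classify_motifs(series)
    stats = circular_stats(series)
    return {
        "NB": seg.nb,
        "fraction_locked": seg.fraction("locked"),
        "fraction_slipping": seg.fraction("slipping"),
        "fraction_other": seg.fraction("other"),
        "R2": stats.R2,
        "phi_ave": stats.phi_ave,
        "n_retained_cycles": int(len(series.retained())),
    }


def multiseed_metrics(
    oscillators, duration_s: float, seeds: Sequence[int]
) -> dict:
    """Run the circuit for several seeds and aggregate per-seed metric ranges."""
    per_seed = []
    for s in seeds:
        rec = simulate_circuit(oscillators, duration_s, int(s))
        per_seed.append({"seed": int(s), **metrics_report(rec)})
    nbs = [m["NB"] for m in per_seed]
    return {
        "per_seed": per_seed,
        "NB_range": [int(min(nbs)), int(max(nbs))],
        "fraction_locked_range": [
            min(m["fraction_locked"] for m in per_seed),
            max(m["fraction_locked"] for m in per_seed),
        ],
        "R2_range": [min(m["R2"] for m in per_seed), max(m["R2"] for m in per_seed)],
    }
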