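"""Ground-truth generators: PRC families, scenario presets, full experiments.

Every downstream stage is testable against data whose generating parameters
are known exactly.  The default PRC family is a normalized beta-like bump

    f(θ) = a · θ^m (1−θ)^k / [p^m (1−p)^k],   m = s·p,  k = s·(1−p)

which is smooth, vanishes at θ = 0 and θ = 1, is non-negative (delay-only,
as for this class of neurons under inhibition) and attains its maximum a at
θ = p.  ``s = m + k`` controls sharpness.  The peak phase of the
experimental PRCs is never published, so ``peak_phase`` is a configuration
choice (default 0.6, a broad late-cycle bump as typical of delay PRCs under
inhibition); peak amplitudes and periods come from the experiment tables.

Scenario presets ``"exp1"``…``"exp35"`` carry the published per-experiment
values (periods, PRC peaks, calibrated noise parameters, bifurcation
counts) from a packaged JSON table; times are milliseconds after loading
(the OU time constant is published in seconds and converted on load).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Tuple

import numpy as np

from .engine import OscillatorSpec, SpikeRecord, simulate_circuit, simulate_prc_protocol
from .noise import NoiseSpec
from .prc import PRCFunction, PRCPoints

__all__ = [
    "PRCFamilySpec",
    "ScenarioPreset",
    "SyntheticExperiment",
    "make_prc",
    "make_scenario",
    "make_experiment",
    "list_presets",
    "load_preset_table",
    "near_boundary_scenario",
]

DEFAULT_PEAK_PHASE = 0.6
DEFAULT_SHAPE = (2.0, 2.0)
DEFAULT_DURATION_S = 600.0


@dataclass(frozen=True)
class PRCFamilySpec:
    """Parameters of one synthetic delay-only PRC bump."""

    peak_amplitude: float
    peak_phase: float = DEFAULT_PEAK_PHASE
    shape_exponents: Tuple[float, float] = DEFAULT_SHAPE
    delay_only: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.peak_amplitude) and self.peak_amplitude >= 0):
            raise ValueError("peak_amplitude must be finite and non-negative")
        if not (0.0 < self.peak_phase < 1.0):
            raise ValueError("peak_phase must lie strictly inside (0, 1)")
        m, k = self.shape_exponents
        if not (m > 0 and k > 0):
            raise ValueError("shape_exponents must both be positive")


def make_prc(spec: PRCFamilySpec) -> PRCFunction:
    """Build the smooth bump PRC described by ``spec``.

    The exponent pair is re-balanced as (s·p, s·(1−p)) with s the supplied
    exponent sum, which pins the maximum exactly at ``peak_phase`` while
    preserving the requested sharpness.  ``f(0) = f(1) = 0`` and
    ``max f = peak_amplitude`` exactly.
    """
    a = spec.peak_amplitude
    p = spec.peak_phase
    s = float(sum(spec.shape_exponents))
    m, k = s * p, s * (1.0 - p)
    norm = p ** m * (1.0 - p) ** k

    if a == 0.0:
        base = lambda th: np.zeros_like(np.asarray(th, dtype=float))
        return PRCFunction(kind="bump", base=base, f_min=0.0, peak=0.0, argmax=p, argmin=0.0)

    def base(th):
        th = np.asarray(th, dtype=float)
        return th ** m * (1.0 - th) ** k / norm

    return PRCFunction(
        kind="bump", base=base, scale_factor=a, f_min=0.0, peak=a, argmax=p, argmin=0.0
    )


@dataclass(frozen=True)
class ScenarioPreset:
    """One coupled-circuit scenario: periods, PRC peaks, truth noise."""

    id: str
    P_B_ms: float
    P_M_ms: float
    peak_B: float
    peak_M: float
    duration_s: float = DEFAULT_DURATION_S
    truth_noise: NoiseSpec = field(default_factory=NoiseSpec)
    peak_phase_B: float = DEFAULT_PEAK_PHASE
    peak_phase_M: float = DEFAULT_PEAK_PHASE
    shape_exponents: Tuple[float, float] = DEFAULT_SHAPE
    table_row: Optional[dict] = None  # published values, when id is exp1..exp35

    def __post_init__(self) -> None:
        if not (self.P_B_ms > 0 and self.P_M_ms > 0):
            raise ValueError("periods must be positive")
        if self.peak_B < 0 or self.peak_M < 0:
            raise ValueError("PRC peaks must be non-negative")

    def prc_B(self) -> PRCFunction:
        return make_prc(
            PRCFamilySpec(self.peak_B, self.peak_phase_B, self.shape_exponents)
        )

    def prc_M(self) -> PRCFunction:
        return make_prc(
            PRCFamilySpec(self.peak_M, self.peak_phase_M, self.shape_exponents)
        )

    def oscillators(self) -> Tuple[OscillatorSpec, OscillatorSpec]:
        noise = self.truth_noise.with_(mu_ms=self.P_B_ms)
        return (
            OscillatorSpec("B", self.prc_B(), self.P_B_ms, noise),
            OscillatorSpec("M", self.prc_M(), self.P_M_ms, NoiseSpec()),
        )

    def with_noise(self, noise: NoiseSpec) -> "ScenarioPreset":
        return replace(self, truth_noise=noise.with_(mu_ms=self.P_B_ms))


def load_preset_table() -> list[dict]:
    """The packaged per-experiment summary table (35 rows)."""
    with resources.files("prcmap.data").joinpath("presets.json").open() as fh:
        return json.load(fh)


def list_presets() -> list[str]:
    return [row["id"] for row in load_preset_table()]


def make_scenario(preset_id, duration_s: float = DEFAULT_DURATION_S, **overrides) -> ScenarioPreset:
    """Build a scenario from a published preset id or an inline config dict.

    ``preset_id`` may be ``"exp1"``…``"exp35"`` (published values; the OU
    noise parameters calibrated for that experiment become the truth noise,
    with τ converted from seconds to ms) or a mapping with at least
    ``P_B_ms`` and ``P_M_ms``.
    """
    if isinstance(preset_id, dict):
        cfg = dict(preset_id)
        noise = cfg.pop("truth_noise", None)
        if isinstance(noise, dict):
            noise = NoiseSpec.from_dict(noise)
        preset = ScenarioPreset(
            id=cfg.pop("id", "custom"),
            P_B_ms=float(cfg.pop("P_B_ms")),
            P_M_ms=float(cfg.pop("P_M_ms")),
            peak_B=float(cfg.pop("peak_B", 0.0)),
            peak_M=float(cfg.pop("peak_M", 0.0)),
            duration_s=float(cfg.pop("duration_s", duration_s)),
            truth_noise=(noise or NoiseSpec()),
            **cfg,
        )
        return preset.with_noise(preset.truth_noise)
    rows = {row["id"]: row for row in load_preset_table()}
    if preset_id not in rows:
        raise KeyError(
            f"unknown preset {preset_id!r}; known ids: {', '.join(rows)}"
        )
    row = rows[preset_id]
    noise = NoiseSpec(
        kind="ou_period",
        sigma=row["ou_sigma"],
        tau_ms=1000.0 * row["ou_tau_s"],
        mu_ms=row["P_B_ms"],
    )
    preset = ScenarioPreset(
        id=preset_id,
        P_B_ms=row["P_B_ms"],
        P_M_ms=row["P_M_ms"],
        peak_B=row["Peak_B"],
        peak_M=row["Peak_M"],
        duration_s=duration_s,
        truth_noise=noise,
        table_row=row,
        **overrides,
    )
    return preset


@dataclass
class SyntheticExperiment:
    """A complete simulated experiment with its generating truth attached."""

    preset: ScenarioPreset
    prc_table: PRCPoints
    record: SpikeRecord
    truth: dict  # exact generator inputs: noise kind, sigma, tau, periods, seed


def make_experiment(
    preset: ScenarioPreset, seed: int, n_prc_points: int = 20
) -> SyntheticExperiment:
    """Simulate the PRC measurement and the coupled circuit for one preset.

    The truth labels are a verbatim pass-through of the generator inputs;
    two different seeds give distinct records with identical truth labels.
    """
    osc_B, osc_M = preset.oscillators()
    # independent substreams for the two protocols, both derived from seed
    prc_table = simulate_prc_protocol(osc_B, n_points=n_prc_points, seed=seed)
    record = simulate_circuit((osc_B, osc_M), preset.duration_s, seed=seed + 1)
    truth = {
        "noise": osc_B.noise.to_dict(),
        "P_B_ms": preset.P_B_ms,
        "P_M_ms": preset.P_M_ms,
        "peak_B": preset.peak_B,
        "peak_M": preset.peak_M,
        "seed": seed,
    }
    return SyntheticExperiment(preset=preset, prc_table=prc_table, record=record, truth=truth)


def near_boundary_scenario(
    base: Optional[ScenarioPreset] = None,
    margin_ms: float = 10.0,
    sigma: float = 0.05,
    tau_cycles: float = 100.0,
    grid_points: int = 161,
) -> ScenarioPreset:
    """Place the biological period a fixed margin inside the locking range.

    Computes the locking period range of the (bump-PRC) scenario and sets
    μ = P_hi − margin_ms, so the upper existence boundary of the stable
    fixed point sits ``margin_ms`` above the mean period.  The truth noise
    is an OU process with the given σ and τ = tau_cycles·μ.  This is the
    regime where slow history-dependent period noise can carry the system
    across the boundary (phase slips) while fast per-cycle jitter of
    comparable PRC variability cannot.
    """
    from .fixedpoints import locking_period_range  # local import, no cycle

    if base is None:
        base = make_scenario("exp19")
    grid = np.linspace(0.75 * base.P_M_ms, 1.35 * base.P_M_ms, grid_points)
    rng = locking_period_range(base.prc_B(), base.prc_M(), base.P_M_ms, grid)
    if rng.empty:
        raise ValueError("scenario family has no locking regime to sit near")
    mu = rng.P_hi - margin_ms
    noise = NoiseSpec(kind="ou_period", sigma=sigma, tau_ms=tau_cycles * mu, mu_ms=mu)
    return replace(
        base, id=f"{base.id}-near-boundary", P_B_ms=mu, truth_noise=noise
    )
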