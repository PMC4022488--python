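"""File formats, run configuration and the end-to-end pipeline.

Tabular data travels as comma-separated text with a header row ('.'
decimal, UTF-8); configs and reports are JSON.  Every stochastic stage of a
run derives its seed from the single master seed in the config, so a bundle
is reproducible from its logged config alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import calibrate_ou, calibrate_sigma, se_ratio
from .engine import SpikeRecord, simulate_circuit, simulate_prc_protocol
from .fixedpoints import confidence_overlap, find_fixed_points, locking_period_range
from .metrics import classify_motifs, metrics_report, multiseed_metrics, network_phases
from .noise import NoiseSpec, effective_sd
from .prc import PRCPoints, fit_prc
from .synth import ScenarioPreset, make_scenario

logger = logging.getLogger("prcmap")

__all__ = [
    "read_prc_table",
    "write_prc_table",
    "write_spike_record",
    "read_spike_times",
    "RunConfig",
    "run_pipeline",
]

PRC_COLUMNS = ("ts_ms", "P0_ms", "P1_ms")


class FormatError(ValueError):
    pass


def read_prc_table(path) -> PRCPoints:
    """Load a PRC measurement table (columns ts_ms, P0_ms, P1_ms).

    Malformed rows (non-numeric, non-positive P0, phase outside [0, 1)) are
    rejected with their line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in PRC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    bad_lines = []
    vals = {}
    for c in PRC_COLUMNS:
        vals[c] = pd.to_numeric(df[c], errors="coerce")
    ok = np.ones(len(df), dtype=bool)
    for c in PRC_COLUMNS:
        ok &= vals[c].notna().to_numpy()
    ok &= (vals["P0_ms"] > 0).to_numpy(na_value=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = vals["ts_ms"] / vals["P0_ms"]
    ok &= ((theta >= 0) & (theta < 1)).to_numpy(na_value=False)
    if not ok.all():
        bad_lines = [int(i) + 2 for i in np.flatnonzero(~ok)]  # header is line 1
        raise FormatError(f"{path}: malformed rows at lines {bad_lines}")
    return PRCPoints(vals["ts_ms"].to_numpy(), vals["P0_ms"].to_numpy(), vals["P1_ms"].to_numpy())


def write_prc_table(points: PRCPoints, path) -> None:
    pd.DataFrame(
        {c: getattr(points, c) for c in PRC_COLUMNS}
    ).to_csv(path, index=False)


def write_spike_record(record: SpikeRecord, path, truth_path=None) -> None:
    """Write the event log as CSV; optionally the truth period trace as a
    sidecar (time_ms, P_true_ms)."""
    record.events.to_csv(path, index=False)
    if truth_path is not None:
        pd.DataFrame(
            {"time_ms": record.truth_t_ms, "P_true_ms": record.truth_P_ms}
        ).to_csv(truth_path, index=False)


def read_spike_times(path) -> SpikeRecord:
    """Rebuild a (metrics-sufficient) SpikeRecord from an event-log CSV."""
    df = pd.read_csv(path)
    for c in ("time_ms", "neuron"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    tB = df.loc[df["neuron"] == "B", "time_ms"].to_numpy(dtype=float)
    tM = df.loc[df["neuron"] == "M", "time_ms"].to_numpy(dtype=float)
    return SpikeRecord(
        spikes_B=tB,
        spikes_M=tM,
        events=df,
        truth_t_ms=np.array([]),
        truth_P_ms=np.array([]),
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    scenario: object  # preset id or inline dict
    noise: Optional[dict] = None  # overrides the preset truth noise
    duration_s: float = 600.0
    n_prc_points: int = 20
    replicates: int = 20
    n_seeds: int = 10
    master_seed: int = 0
    calibrate: bool = False
    outdir: Optional[str] = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        return d

    def seeds(self) -> dict:
        """Deterministic per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.master_seed).generate_state(4) % (2**31)
        return {
            "prc_protocol": int(ss[0]),
            "circuit": int(ss[1]),
            "multiseed": int(ss[2]),
            "calibration": int(ss[3]),
        }


def _resolve_scenario(config: RunConfig) -> ScenarioPreset:
    sc = make_scenario(config.scenario, duration_s=config.duration_s)
    if config.noise is not None:
        sc = sc.with_noise(NoiseSpec.from_dict(config.noise))
    return sc


def run_pipeline(config: RunConfig) -> dict:
    """synth → PRC fit → fixed points → circuit → metrics (→ calibration).

    Returns the artifact bundle as a dict and, when ``config.outdir`` is
    set, writes each piece (CSV tables, JSON reports, run log).
    """
    seeds = config.seeds()
    scenario = _resolve_scenario(config)
    osc_B, osc_M = scenario.oscillators()

    stage = "prc_protocol"
    try:
        prc_table = simulate_prc_protocol(
            osc_B, n_points=config.n_prc_points, seed=seeds["prc_protocol"]
        )
        stage = "prc_fit"
        reference_fit = fit_prc(prc_table, order=4)
        stage = "fixed_points"
        fps = find_fixed_points(scenario.prc_B(), scenario.P_B_ms, scenario.prc_M(), scenario.P_M_ms)
        grid = np.linspace(0.75 * scenario.P_M_ms, 1.35 * scenario.P_M_ms, 121)
        lrange = locking_period_range(
            scenario.prc_B(), scenario.prc_M(), scenario.P_M_ms, grid, mu=scenario.P_B_ms
        )
        sd_eff = effective_sd(osc_B.noise, prc=scenario.prc_B())
        overlap = confidence_overlap(lrange, scenario.P_B_ms, sd_eff if np.isfinite(sd_eff) else 0.0)
        stage = "circuit"
        record = simulate_circuit((osc_B, osc_M), config.duration_s, seeds["circuit"])
        stage = "metrics"
        metrics = metrics_report(record)
        bundle = {
            "config": config.to_dict(),
            "version": __version__,
            "seeds": seeds,
            "scenario": {
                "id": scenario.id,
                "P_B_ms": scenario.P_B_ms,
                "P_M_ms": scenario.P_M_ms,
                "peak_B": scenario.peak_B,
                "peak_M": scenario.peak_M,
                "noise": osc_B.noise.to_dict(),
            },
            "prc_fit": {
                "order": 4,
                "se": reference_fit.se,
                "coefficients": list(map(float, reference_fit.coefficients)),
            },
            "fixed_points": [p.to_dict() for p in fps.points],
            "locking_range": lrange.to_dict(),
            "sigma_eff_ms": sd_eff,
            "confidence_overlap": overlap.to_dict(),
            "metrics": metrics,
        }
        if config.calibrate:
            stage = "calibration"
            result = calibrate_ou(
                scenario,
                reference_fit,
                reference_fit.se,
                NB_observed=metrics["NB"],
                duration_s=config.duration_s,
                seed=seeds["calibration"],
                n_seeds=config.n_seeds,
                replicates=config.replicates,
            )
            bundle["calibration"] = result.to_dict()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_prc_table(prc_table, out / "prc_table.csv")
        write_spike_record(record, out / "spikes.csv", out / "spikes_truth.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=1, default=float)
        logger.info("bundle written to %s", out)
    return bundle
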