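# prcmap

Phase-resetting-curve (PRC) map analysis of two reciprocally inhibitory
neural oscillators, with intrinsic-noise models and calibration.

## The problem

A hybrid circuit couples one biological oscillator (an invertebrate
pacemaker-like neuron, period P_B) to one noiseless computational model
neuron (period P_M) through mutual pulsatile inhibition.  Such circuits
show two dominant dynamical motifs: **phase locking** (the biological
spike sits at a fixed position within the model neuron's cycle) and
**phase slipping** (one neuron laps the other, the phase progressing every
cycle), with abrupt, seemingly random transitions between them.  `prcmap`
is for researchers who want to predict these motifs from measurable
single-neuron properties and to ask *what kind of intrinsic noise* the
biological neuron must carry for the observed transitions to occur.

## The model

Each oscillator is a phase θ ∈ [0, 1) advancing at rate 1/P and reset to
0 at a spike; an input arriving at phase θ decrements the phase by the
PRC f(θ) = (P1 − P0)/P0 (positive = delay).  In the stimulus/recovery
interval plane the neuron is the interaction curve

    tr(ts) = P · (1 + f(ts/P)) − ts,

and a 1:1 locked mode is an intersection of the two neurons' curves — a
fixed point of the return map g = T_B ∘ T_M, stable iff |g′| < 1.  The
range of biological periods with a stable intersection (the locking range)
is compared against the 95% band μ ± 2σ_eff of the intrinsic period under
three noise models:

| model | update | σ_eff |
|---|---|---|
| resetting jitter | f(θ) + σX per input | μσ/(1 + f_min) |
| period jitter | P(1 + σX) per cycle | μσ |
| Ornstein–Uhlenbeck period | P += (μ−P)dt/τ + σ√dt·X | σ√(τ/2) |

Only the OU process is history-dependent: its kicks accumulate over
~τ/μ cycles, so at a noise level consistent with the measured PRC scatter
it can carry the period across the locking boundary and back, producing
locked↔slipping bifurcations that per-cycle Gaussian jitter cannot.

The package ships an event-driven simulator of the coupled map (including
the two-pulse branch that reinjects trajectories across slips), the PRC
measurement protocol, fixed-point and locking-range analysis, a motif
classifier (locked / slipping / other, bifurcation count NB, vector
strength R²), a calibration engine that fits σ to the PRC scatter and τ to
the observed bifurcation counts, and a synthetic-data generator with the
35 published experiment presets (`exp1`…`exp35`).

## Worked example

Experiment 19's preset: P_B = 838.82 ms, P_M = 799.3 ms, PRC peaks
0.0431/0.1007, published OU parameters σ = 0.0453, τ = 83.882 s.

```python
import numpy as np
import prcmap as pm

sc = pm.make_scenario("exp19")
fps = pm.find_fixed_points(sc.prc_B(), sc.P_B_ms, sc.prc_M(), sc.P_M_ms)
for p in fps.points:
    print(f"{p.stability:9s} ts_M*={p.ts_M:7.2f} ms  g'={p.return_map_derivative:+.3f}")

grid = np.linspace(0.9 * sc.P_M_ms, 1.15 * sc.P_M_ms, 101)
rng = pm.locking_period_range(sc.prc_B(), sc.prc_M(), sc.P_M_ms, grid, mu=sc.P_B_ms)
sd = pm.effective_sd(sc.truth_noise, prc=sc.prc_B())
rep = pm.confidence_overlap(rng, sc.P_B_ms, sd)
print(f"locking range: [{rng.P_lo:.1f}, {rng.P_hi:.1f}] ms, mu = {sc.P_B_ms} ms")
print(f"sigma_eff(OU) = {sd:.2f} ms, overlap: {rep.verdict}")

nbs = [pm.metrics_report(pm.simulate_circuit(sc.oscillators(), 600.0, seed=s))["NB"]
       for s in range(10)]
print("NB per seed:", nbs)
```

prints

```
stable    ts_M*= 405.97 ms  g'=+0.837
unstable  ts_M*= 644.72 ms  g'=+1.197
locking range: [795.3, 849.3] ms, mu = 838.82 ms
sigma_eff(OU) = 9.28 ms, overlap: partial
NB per seed: [0, 0, 0, 4, 2, 4, 0, 0, 0, 0]
```

Read: the interaction curves intersect twice, one stable mode (the circuit
locks with the biological spike 406 ms into the model cycle) and one
unstable.  The mean period sits 10 ms below the upper edge of the locking
range, while the OU period process wanders with σ_eff ≈ 9.3 ms — its 95%
band partially escapes the locking regime, so some seeds of a 600 s run
show bifurcations (locked↔slipping transitions) and others none.  Under
the two Gaussian models calibrated to the same PRC scatter, σ_eff is ~2 ms,
the band stays inside the range, and every seed stays locked (NB = 0).

The same operations are exposed on the command line:

```
prcmap fixed-points --preset exp19 --sweep
prcmap simulate --preset exp34 --noise ou_period --sigma 0.1047 --tau-ms 80630 --seeds 10
prcmap calibrate --preset exp19 --duration 300
```

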