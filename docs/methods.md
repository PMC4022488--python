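# Methods

`prcmap` analyses a two-neuron hybrid circuit — one noisy biological
oscillator (B) reciprocally coupled to one noiseless model oscillator (M)
through pulsatile inhibition — at the level of phase resetting curves
(PRCs) and interval maps, not membrane equations.  This note records the
model, the numerical choices, and the limits of what the synthetic data
can show.

## The pulse-coupled map

Each oscillator carries a phase θ ∈ [0, 1) advancing at constant velocity
1/P between events and resetting from 1 to 0 at a spike.  A spike in one
neuron perturbs the other instantaneously: the receiver at phase θ has its
phase decremented by its PRC value f(θ), where f = (P1 − P0)/P0 is measured
with the same inhibitory conductance waveform used for coupling, and
positive f is a delay.  The pulsatile assumption is that each input's
effect is complete before the next event.  The simulator is event-driven:
at every step the neuron with the shortest recovery interval
tr = P(1 − θ) fires next; phases are only updated at firing times.  A
neuron may fire twice within one partner cycle (a phase slip); the second
input is then handled by the same phase-decrement rule, which is
algebraically identical to the two-pulse recovery interval
tr\* = P(1 − θ2 + f(θ2)) with θ2 = θ1 − f(θ1) + P_partner/P
(`prcmap.prc.two_pulse_recovery`; the engine and the closed form are
cross-checked in the test suite).  Three consecutive spikes in one neuron
without an intervening partner spike are outside the map's validity and
raise an error.

Interval-map analysis works in the (ts, tr) plane: each neuron's
interaction curve is tr(ts) = P(1 + f(ts/P)) − ts, and a 1:1 locked mode is
an intersection of the two curves, i.e. a fixed point of the one-cycle
return map g = T_B ∘ T_M on the model neuron's stimulus interval.
Stability is |g′| < 1, computed by central differences with step 1e-6·P —
equivalent to the graphical slope criterion for the two curves.  Roots are
bracketed on a 2048-point grid and refined by Brent's method to 1e-9·P;
doubling the grid does not change the result (tested).  The admissible
domain keeps both PRCs inside their measured domain [0, 1]
(ts_M ≤ P_M and tr_M(ts_M) ≤ P_B); fixed points beyond it would involve
the two-pulse branch and are out of scope.  If the two curves coincide
along a stretch of the grid (degenerate flat/flat case) a neutral
continuum is reported instead of a point list.  A derivative within 1e-6
of ±1 is reported "neutral" rather than forced into a stable/unstable
call.

Sweeping the biological period shifts its interaction curve along the
diagonal; the contiguous block of periods with a stable intersection is the
locking range, and comparing it with the 95% band μ ± 2σ_eff of the
intrinsic-period distribution predicts whether a noise model can carry the
circuit out of locking.

## Noise models

All noise lives in the biological oscillator; the model neuron is
noiseless with constant period, so every bit of variability in a record is
attributable to the modelled intrinsic noise.

1. **Resetting jitter** (`prc_gaussian`): each received input decrements
   the phase by f(θ) + σX, X ~ N(0,1), σ in phase units.  Maximum effective
   period sd: σ_eff = μσ/(1 + f_min); for delay-only PRCs f_min = 0.
2. **Period jitter** (`period_gaussian`): each biological cycle draws its
   period once as P(1 + σX), used for both θ = ts/P and tr = P(1 − θ)
   within the cycle; σ is a fraction of the period.  σ_eff = μσ.
   Draws are serially independent (lag-1 autocorrelation ≈ 0).
3. **Ornstein–Uhlenbeck period process** (`ou_period`): the period itself
   diffuses with √dt-scaled kicks and linear mean reversion,

       P[k+1] = P[k] + (μ − P[k])·dt/τ + σ·√dt·X,

   an Euler–Maruyama update with σ in ms·ms^(−1/2) and τ in ms (published
   values are in seconds and converted on load).  Stationary sd of the
   discretized chain: σ_eff = σ·√(τ/2); this closed form is validated
   against a 1e5-step simulation (within 5%) rather than quoted.  Lag-1
   autocorrelation at regular sampling dt is exp(−dt/τ) — the history
   dependence that distinguishes this model.  τ = ∞ disables reversion
   (pure Brownian period).  Updates with dt > τ emit a warning (the
   explicit scheme leaves its stable regime).

A new period estimate is sampled at every event involving B (own spike or
received input), with dt equal to the elapsed time since the previous
sample.  Because every interval's length is generated from the estimate in
effect at its start, this elapsed time coincides exactly with the three
interval cases of the sampling scheme (stimulus interval known; recovery
interval approximated by its deterministic value from the pre-update
estimate; unperturbed cycle approximated by the previous period).  Sampled
or updated periods below 10% of μ are clamped there with a logged warning;
negative periods are unphysical and the delay-only regime never
approaches them in practice.  Phases pushed below 0 by a large reset are
clamped to 0 (a delayed neuron cannot fire before its own spike), also
logged.

## PRC measurement protocol and fitting

The simulated protocol mirrors the experimental one: for each of ~20
stimulus phases evenly spaced in (0, 1), five unperturbed cycles elapse
(the period process evolving freely), their mean is the unperturbed period
P0, one perturbation is applied at ts = θ·P0, and the perturbed period
P1 = ts + tr is recorded.  The period process is carried continuously
across the whole protocol.  Biological-style PRCs are fitted with 3rd or
4th order polynomials by least squares; order 4 is used for synthetic bump
data because order 3 leaves systematic lack-of-fit (~40% of the noise-level
squared error for the default bump, versus ~5% at order 4) — the same
"choose the order that leaves residuals random" rule used for the
experimental fits.  Fitted PRCs are evaluated only on [0, 1]; there is no
extrapolation.

## Calibration

σ is calibrated so that the simulated protocol's scatter matches a
measured squared error (SE): bisection on σ against the expected SE ratio,
averaged over ≥20 protocol replicates with common random numbers, stopping
in [0.9, 1.0] ("close to one without exceeding one").  Two estimator
details matter:

- Each simulated replicate's SE is measured about its **own** polynomial
  refit, because the experimental SE is defined about the experimental
  data's own fit; using the fixed reference fit instead leaves the
  simulated slow-period trend unabsorbed and biases σ low by ~15% for OU
  noise (the literal fixed-reference ratio remains available as
  `se_ratio` and via `se_mode="reference"`).
- A held-out validation replicate set guards the hard upper bound: if the
  calibrated σ's ratio on fresh replicates exceeds 1, σ is shrunk toward
  the bound.  Without this, a 20-replicate calibration set can be
  "overfit" by 10–15%.

The OU model's τ is found by alternation: starting at τ = 1000·P_B,
(a) calibrate σ at the current τ, (b) simulate the circuit for 10 seeds
and count motif bifurcations per seed; τ moves by factors of 2 (up when
the simulations under-produce bifurcations, down when every seed
over-produces) until the 10-seed range brackets the observed count while
the SE criterion holds, or an iteration cap (12) is hit, in which case the
best attempt is returned flagged as a failure.  Fits are not unique — a
wide band of (σ, τ) passes both criteria — so the result records the full
search path.  Parameter recovery on synthetic OU truth (σ = 0.05,
τ = 100·μ) is mean-unbiased with a per-experiment spread of ~15%,
dominated by the χ²-like variance of a single 20-point protocol's SE;
recovery checks therefore average a few synthetic experiments.

## Motif metrics

The network phase of a model-neuron cycle containing exactly one
biological spike is φ = ts_M/(ts_M + tr_M); cycles containing zero or two
biological spikes mark laps (slips) and yield no phase.  The first 10
phases of every record are discarded as transient by all downstream
operations (the raw series is kept intact).  Segmentation:

- **Locked**: every cycle covered by some 20-cycle window whose circularly
  unwrapped phase range is ≤ 0.2 (the ±0.1 criterion without assuming an
  anchor value); increments are unwrapped to (−0.5, 0.5].
- **Slipping**: a maximal non-locked segment showing monotone circular
  progression — a wrap event (including lap markers) or ≥5 consecutive
  same-sign increments.  The whole segment is labelled, because a slip
  episode physically includes the slow drift into and out of the fast
  sweep past the ghost of the lost fixed point; fragmenting it would
  undercount locked↔slipping transitions.
- **Other**: the remainder (short wobbles, undefined activity).

The bifurcation count NB is the number of adjacent locked↔slipping episode
pairs.  Circular statistics use angles 2π·ts_M,n/P_n:
R² = X² + Y² (vector strength) and φ_ave = atan2(Y, X).

## Synthetic data and what it does not show

The default PRC family is the normalized bump a·θ^m(1−θ)^k/max with
exponents rebalanced to put the maximum exactly at the requested peak
phase.  It is smooth, delay-only and vanishes at both ends — qualitatively
the shape of this neuron class under inhibition — but it is **not** the
unpublished experimental PRC of any given circuit.  Peak amplitudes,
periods and calibrated noise parameters come from the shipped 35-row
experiment table; the peak phase is never published, so the default (0.6,
a broad late-cycle bump, exponent sum 4) is a configuration choice.
Consequences: per-experiment quantities that depend on PRC shape (locking
boundaries, bifurcation counts under the published noise parameters) are
qualitative surrogates, not reproductions — e.g. the always-locked
experiments' surrogates can show occasional bifurcations that the real
circuits did not.  What passing tests do show: the map/fixed-point
machinery, the noise processes and their statistics, the calibration
procedure, and the central mechanism — at matched PRC scatter only the
history-dependent period process widens the period's 95% band beyond the
locking boundary and produces locked↔slipping bifurcations.

Scenario durations are not published per experiment; the default is 600 s.
Initial phases default to θ_B = 0 with θ_M drawn uniformly per seed
(transients are discarded rather than controlled).  Simultaneous-firing
ties (equal recovery intervals to machine precision) are resolved
biological-first; ties are measure-zero and any fixed order preserves
determinism.

## Problem sizes and tolerances

Stationary-OU checks use 1e5 steps (sd within 5%); autocorrelation checks
use ≥5e4 steps (±0.02).  Fixed-point/iteration equivalence uses 24
randomized bump scenarios, 1e4 map iterations, tolerance 1e-6·P.
Calibration runs 20 protocol replicates of 20 points and 10 circuit seeds
of 600 s (~750 cycles each).  Monte-Carlo tolerances in tests are set at
roughly 3 standard errors of the corresponding estimator.  All analysis
code is pure numpy/scipy/pandas; a full test run takes well under a
minute of compute plus the stochastic acceptance suite (~30 s total).
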