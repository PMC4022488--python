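"""Event-driven coupled-map simulation and the PRC measurement protocol."""

import numpy as np
import pytest

from prcmap.engine import (
    OscillatorSpec,
    UnsupportedFiringPatternError,
    simulate_circuit,
    simulate_prc_protocol,
)
from prcmap.fixedpoints import find_fixed_points
from prcmap.metrics import network_phases
from prcmap.noise import NoiseSpec
from prcmap.prc import fit_prc, two_pulse_recovery
from prcmap.synth import PRCFamilySpec, make_prc, make_scenario


def _osc(name, prc, P, noise=None):
    return OscillatorSpec(name, prc, P, noise or NoiseSpec())


class TestStepSemantics:
    def test_uncoupled_identical_clocks_alternate_forever(self, zero_prc):
        rec = simulate_circuit(
            (_osc("B", zero_prc, 100.0), _osc("M", zero_prc, 100.0)),
            2.0,
            seed=0,
            theta_M0=0.5,
        )
        assert np.allclose(rec.spikes_B, 100.0 * np.arange(1, len(rec.spikes_B) + 1))
        assert np.allclose(rec.spikes_M, 100.0 * np.arange(1, len(rec.spikes_M) + 1) - 50.0)

    def test_detuned_clocks_lap_at_the_beat_frequency(self, zero_prc):
        # P_B=100, P_M=90: M gains 10 ms per M-cycle, lapping B every 900 ms
        rec = simulate_circuit(
            (_osc("B", zero_prc, 100.0), _osc("M", zero_prc, 90.0)),
            18.0,
            seed=0,
            theta_M0=0.25,
        )
        series = network_phases(rec)
        # cycles without a computable phase are exactly the lap events
        n_laps = len(series.slip_marker_cycles)
        assert n_laps == pytest.approx(18_000 / 900, abs=1)

    def test_noiseless_convergence_to_stable_fixed_point(self):
        sc = make_scenario("exp19").with_noise(NoiseSpec(kind="none"))
        fps = find_fixed_points(sc.prc_B(), sc.P_B_ms, sc.prc_M(), sc.P_M_ms)
        (stable,) = [p for p in fps.points if p.stability == "stable"]
        rec = simulate_circuit(sc.oscillators(), 600.0, seed=0, theta_M0=0.3)
        b_events = rec.events[rec.events.neuron == "B"]
        # ts recorded at a B spike is the model neuron's stimulus interval
        late = b_events.ts_ms.tail(5).to_numpy()
        assert np.allclose(late, stable.ts_M, atol=1e-6 * sc.P_M_ms)

    def test_spike_times_strictly_increasing_and_time_conserved(self):
        sc = make_scenario("exp19")
        rec = simulate_circuit(sc.oscillators(), 120.0, seed=5)
        assert np.all(np.diff(rec.spikes_B) > 0)
        assert np.all(np.diff(rec.spikes_M) > 0)
        ev = rec.events.time_ms.to_numpy()
        assert np.all(np.diff(ev) >= 0)
        assert ev[-1] >= rec.meta["duration_ms"]

    def test_three_consecutive_spikes_unsupported(self, zero_prc):
        with pytest.raises(UnsupportedFiringPatternError):
            simulate_circuit(
                (_osc("B", zero_prc, 1000.0), _osc("M", zero_prc, 100.0)),
                10.0,
                seed=0,
                theta_M0=0.5,
            )

    def test_second_input_in_one_cycle_follows_two_pulse_recovery(self):
        # periods detuned beyond the locking range → slips occur, and some
        # biological cycles receive two model-neuron inputs
        prc_B = make_prc(PRCFamilySpec(0.05, 0.6))
        prc_M = make_prc(PRCFamilySpec(0.08, 0.6))
        P_B, P_M = 460.0, 400.0
        rec = simulate_circuit(
            (_osc("B", prc_B, P_B), _osc("M", prc_M, P_M)), 120.0, seed=1, theta_M0=0.4
        )
        ev = rec.events
        m_rows = np.flatnonzero((ev.neuron == "M").to_numpy())
        checked = 0
        for i, j in zip(m_rows, m_rows[1:]):
            if j != i + 1:
                continue  # a B spike intervened
            # two consecutive M spikes: B received two inputs in one cycle
            ts1 = ev.ts_ms.iloc[i]
            gap = ev.time_ms.iloc[j] - ev.time_ms.iloc[i]
            if not np.isclose(gap, P_M, atol=1e-9):
                continue  # M was perturbed between its spikes
            expected = two_pulse_recovery(prc_B, P_B, P_M, ts1)
            assert ev.tr_ms.iloc[j] == pytest.approx(expected, abs=1e-9 * P_B)
            checked += 1
        assert checked >= 3

    def test_reproducible_and_seed_sensitive(self):
        sc = make_scenario("exp19")
        a = simulate_circuit(sc.oscillators(), 60.0, seed=9)
        b = simulate_circuit(sc.oscillators(), 60.0, seed=9)
        c = simulate_circuit(sc.oscillators(), 60.0, seed=10)
        assert np.array_equal(a.spikes_B, b.spikes_B)
        assert np.array_equal(a.spikes_M, b.spikes_M)
        assert not np.array_equal(a.spikes_B, c.spikes_B)

    @pytest.mark.parametrize("kind", ["prc_gaussian", "period_gaussian", "ou_period"])
    def test_zero_sigma_reduces_to_deterministic_map(self, kind):
        sc = make_scenario("exp19")
        tau = 1000.0 if kind == "ou_period" else None
        noisy = sc.with_noise(NoiseSpec(kind=kind, sigma=0.0, tau_ms=tau, mu_ms=sc.P_B_ms))
        clean = sc.with_noise(NoiseSpec(kind="none"))
        a = simulate_circuit(noisy.oscillators(), 60.0, seed=3)
        b = simulate_circuit(clean.oscillators(), 60.0, seed=3)
        assert np.array_equal(a.spikes_B, b.spikes_B)
        assert np.array_equal(a.spikes_M, b.spikes_M)

    def test_model_neuron_period_is_constant_throughout(self):
        sc = make_scenario("exp19")
        rec = simulate_circuit(sc.oscillators(), 120.0, seed=2)
        # every M cycle uninterrupted by a B input would be exactly P_M;
        # perturbed cycles are P_M plus the applied resetting, so all
        # variability in the record is attributable to the biological side
        ev = rec.events
        m_spikes = ev[ev.neuron == "M"]
        resets_to_M = ev[ev.neuron == "B"]  # B firing perturbs M
        assert (rec.truth_P_ms > 0).all()
        # M's scheduled recovery after a B input always uses P_M exactly
        for _, row in resets_to_M.head(20).iterrows():
            assert row.tr_ms <= sc.P_M_ms * (1 + sc.peak_M) + 1e-9


class TestPRCProtocol:
    def test_noiseless_protocol_reproduces_prc_exactly(self, parabola_prc):
        osc = _osc("B", parabola_prc, 100.0)
        pts = simulate_prc_protocol(osc, 20, seed=0)
        assert len(pts) == 20
        assert np.allclose(pts.reset, parabola_prc(pts.theta), atol=1e-12)
        assert np.allclose(pts.P0_ms, 100.0)

    def test_point_count_matches_request(self, parabola_prc):
        osc = _osc("B", parabola_prc, 100.0)
        assert len(simulate_prc_protocol(osc, 37, seed=0)) == 37

    def test_scatter_grows_with_sigma(self, parabola_prc):
        def mean_se(sigma):
            noise = NoiseSpec(kind="period_gaussian", sigma=sigma, mu_ms=100.0)
            osc = _osc("B", parabola_prc, 100.0, noise)
            ses = []
            for s in range(8):
                pts = simulate_prc_protocol(osc, 20, seed=s)
                ses.append(fit_prc(pts, order=3).se)
            return np.mean(ses)

        assert mean_se(0.002) < mean_se(0.01) < mean_se(0.03)

    def test_prc_gaussian_protocol_matches_analytic_scale(self, parabola_prc):
        # resets are f(θ) + σX about a cubic that can absorb 4 dof:
        # E[SE] = (n − 4)σ² for the refit of each table
        sigma, n = 0.01, 20
        noise = NoiseSpec(kind="prc_gaussian", sigma=sigma, mu_ms=100.0)
        osc = _osc("B", parabola_prc, 100.0, noise)
        ses = [fit_prc(simulate_prc_protocol(osc, n, seed=s), order=3).se for s in range(60)]
        assert np.mean(ses) == pytest.approx((n - 4) * sigma**2, rel=0.2)

    def test_ou_protocol_periods_have_memory(self):
        prc = make_prc(PRCFamilySpec(0.05, 0.6))
        noise = NoiseSpec(kind="ou_period", sigma=0.05, tau_ms=50_000.0, mu_ms=500.0)
        osc = _osc("B", prc, 500.0, noise)
        pts = simulate_prc_protocol(osc, 40, seed=2)
        p0 = pts.P0_ms
        r = np.corrcoef(p0[:-1], p0[1:])[0, 1]
        assert r > 0.3  # successive block averages stay correlated
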