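"""Trace and dwell simulation: rate composition, protocols, determinism."""

import numpy as np
import pytest

from stallkin.survival import fit_exponential_mle
from stallkin.synthetic_traces import (
    KineticParams,
    TraceConfig,
    effective_rate,
    event_log_dwells,
    read_trace,
    simulate_dwells,
    simulate_force_cycle_dwells,
    simulate_force_cycle_trace,
    simulate_recycling_trace,
    write_trace,
)


class TestEffectiveRate:
    def test_intrinsic_zero_torque_rate(self):
        """No enzyme, relaxed DNA: residence ~1e6 s (rate ~1/9e5 s^-1)."""
        rate = effective_rate(KineticParams(), torque=0.0, rapa=0.0, atp=0.0)
        assert 1.0 / rate == pytest.approx(9e5, rel=0.20)

    def test_saturating_enzyme_zero_torque_rate(self):
        rate = effective_rate(KineticParams(), torque=0.0, rapa=1e5, atp=1e6)
        assert 1.0 / rate == pytest.approx(2800.0, rel=0.15)

    def test_negative_torque_gives_zero_rate(self):
        assert effective_rate(KineticParams(), -12.0, rapa=100.0, atp=1000.0) == 0.0
        assert effective_rate(KineticParams(), -12.0, rapa=0.0, atp=1000.0) == 0.0

    def test_reference_condition_matches_table_lifetime(self):
        """100 nM RapA, 1 mM ATP at +12 pN·nm: lifetime near 983 s."""
        rate = effective_rate(KineticParams(), 12.0, rapa=100.0, atp=1000.0)
        assert 1.0 / rate == pytest.approx(983.0, rel=0.20)

    def test_rate_increases_with_torque_and_concentration(self):
        p = KineticParams()
        assert effective_rate(p, 30.0, 100, 1000) > effective_rate(p, 12.0, 100, 1000)
        assert effective_rate(p, 12.0, 500, 1000) > effective_rate(p, 12.0, 3, 1000)

    def test_negative_concentration_refused(self):
        with pytest.raises(ValueError):
            effective_rate(KineticParams(), 12.0, rapa=-1.0, atp=1000.0)


class TestSimulateDwells:
    def test_sample_mean_converges_to_inverse_rate(self):
        p = KineticParams()
        rate = effective_rate(p, 12.0, 100.0, 1000.0)
        dwells = simulate_dwells(p, 12.0, 100.0, 1000.0, n=10_000, seed=1)
        se = (1.0 / rate) / np.sqrt(10_000)
        assert abs(dwells.durations.mean() - 1.0 / rate) < 3 * se

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_dwells(KineticParams(), 12.0, 100.0, 1000.0, n=50, seed=9)
        b = simulate_dwells(KineticParams(), 12.0, 100.0, 1000.0, n=50, seed=9)
        assert np.array_equal(a.durations, b.durations)

    def test_tiny_censor_time_censors_everything(self):
        dwells = simulate_dwells(
            KineticParams(), 12.0, 100.0, 1000.0, n=20, censor_time=1e-9, seed=2
        )
        assert dwells.censored_mask.all()

    def test_zero_rate_warns_and_returns_all_censored(self):
        with pytest.warns(UserWarning, match="zero"):
            dwells = simulate_dwells(
                KineticParams(), -12.0, 100.0, 1000.0, n=5, censor_time=100.0, seed=3
            )
        assert dwells.censored_mask.all()

    def test_round_trip_through_mle_within_3_se(self):
        p = KineticParams()
        for torque in (12.0, 22.0, 30.0):
            rate = effective_rate(p, torque, 100.0, 1000.0)
            dwells = simulate_dwells(p, torque, 100.0, 1000.0, n=100, seed=int(torque))
            fit = fit_exponential_mle(dwells)
            assert abs(fit.mean_lifetime - 1.0 / rate) < 3 * fit.standard_error


class TestRecyclingTrace:
    def test_noiseless_trace_has_three_levels(self):
        cfg = TraceConfig(noise_sd=0.0, seed=4)
        trace = simulate_recycling_trace(
            KineticParams(), cfg, 30.0, 100.0, 1000.0, duration=3000.0
        )
        assert set(np.unique(trace.extensions)) <= set(cfg.levels.values())
        assert len(set(np.unique(trace.extensions))) == 3

    def test_event_log_alternates_states(self):
        cfg = TraceConfig(noise_sd=0.0, seed=5)
        trace = simulate_recycling_trace(
            KineticParams(), cfg, 30.0, 100.0, 1000.0, duration=3000.0
        )
        order = {"initiation": 0, "stall": 1, "removal": 2}
        phases = [order[ev] for _, ev in trace.event_log if ev in order]
        for prev, nxt in zip(phases, phases[1:]):
            assert nxt == (prev + 1) % 3

    def test_no_enzyme_low_torque_trace_has_no_removal(self):
        """At +12 pN·nm without enzyme p(removal in 1e4 s) ~ 1e4/9e5."""
        cfg = TraceConfig(noise_sd=0.0, seed=6, sampling_rate=5.0)
        trace = simulate_recycling_trace(
            KineticParams(), cfg, 12.0, 0.0, 0.0, duration=10_000.0
        )
        assert not any(ev == "removal" for _, ev in trace.event_log)

    def test_rescue_rate_increases_never_terminated_fraction(self):
        """A competing anti-backtracking rescue locks more cycles in place
        the faster it is, mirroring the inhibitor's halving of removal."""
        fractions = []
        for rescue in (0.0, 0.005, 0.05):
            censored = total = 0
            for seed in range(40):
                cfg = TraceConfig(noise_sd=0.0, seed=seed, sampling_rate=1.0)
                trace = simulate_recycling_trace(
                    KineticParams(greb_rescue_rate=rescue),
                    cfg, 30.0, 100.0, 1000.0, duration=2000.0,
                )
                dwells = event_log_dwells(trace)
                total += len(dwells)
                censored += sum(c for _, _, c in dwells)
            fractions.append(censored / max(total, 1))
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[2] > fractions[0]

    def test_nonpositive_duration_refused(self):
        with pytest.raises(ValueError):
            simulate_recycling_trace(
                KineticParams(), TraceConfig(), 12.0, 100.0, 1000.0, duration=0.0
            )


class TestForceCycling:
    def test_high_window_dwell_mean_matches_52_pnnm_condition(self):
        """64 enzyme-free cycles at 6 pN: mean dwell within 3 SE of 2500 s."""
        dwells = simulate_force_cycle_dwells(
            KineticParams(),
            low_force=0.3,
            high_force=6.0,
            hold_low=400.0,
            n_cycles=64,
            seed=12,
        )
        assert len(dwells) == 64
        se = 2500.0 / np.sqrt(64)
        assert abs(dwells.durations.mean() - 2500.0) < 3 * se

    def test_removal_essentially_confined_to_high_window_without_enzyme(self):
        """The low-force intrinsic clock is ~2000x slower, so removals at
        low force are at most a rare exception among 64 cycles."""
        dwells = simulate_force_cycle_dwells(
            KineticParams(), 0.3, 6.0, 400.0, n_cycles=64, seed=12
        )
        windows = dwells.condition["removal_window"]
        assert windows.count("high") >= 62

    def test_trace_removal_events_occur_at_high_force_without_enzyme(self):
        cfg = TraceConfig(noise_sd=0.0, seed=15, sampling_rate=2.0)
        trace = simulate_force_cycle_trace(
            KineticParams(), cfg, 0.3, 6.0, hold_low=400.0, duration=20_000.0
        )
        removals = [t for t, ev in trace.event_log if ev == "removal"]
        assert removals, "expected at least one removal event"
        for t in removals:
            idx = np.searchsorted(trace.times, t) - 1
            assert trace.force_schedule[idx] == 6.0

    def test_zero_initiation_rate_gives_flat_baseline_trace(self):
        cfg = TraceConfig(noise_sd=0.0, seed=8)
        trace = simulate_force_cycle_trace(
            KineticParams(initiation_rate=0.0),
            cfg, 0.3, 6.0, hold_low=100.0, duration=500.0,
        )
        levels = set(np.unique(trace.extensions))
        assert levels <= {
            cfg.baseline_extension,
            cfg.baseline_extension * 0.75,
        }
        assert not any(ev == "initiation" for _, ev in trace.event_log)

    def test_force_schedule_alternates(self):
        cfg = TraceConfig(noise_sd=0.0, seed=9)
        trace = simulate_force_cycle_trace(
            KineticParams(), cfg, 0.3, 6.0, hold_low=200.0, duration=2000.0,
            rapa=100.0, atp=1000.0,
        )
        assert set(np.unique(trace.force_schedule)) <= {0.3, 6.0}
        assert (trace.force_schedule == 6.0).any()

    def test_bad_force_ordering_refused(self):
        with pytest.raises(ValueError):
            simulate_force_cycle_dwells(KineticParams(), 6.0, 0.3, 400.0, 10)

    def test_nonpositive_hold_refused(self):
        with pytest.raises(ValueError):
            simulate_force_cycle_dwells(KineticParams(), 0.3, 6.0, 0.0, 10)


class TestFullChainRecovery:
    def test_bell_parameters_recovered_from_simulated_dwell_sets(self):
        """Simulate at 5 torques from a known law; refit recovers
        theta/kBT within 15% and k0 within a factor of 1.5."""
        truth = KineticParams(k0=3e-4, theta0_over_kBT=0.1)
        points = []
        for i, torque in enumerate((12.0, 18.0, 22.0, 27.0, 30.0)):
            dwells = simulate_dwells(truth, torque, 0.0, 0.0, n=200, seed=100 + i)
            points.append((torque, fit_exponential_mle(dwells)))
        from stallkin.inference import fit_bell

        fit = fit_bell(points)
        assert fit.slope == pytest.approx(0.1, rel=0.15)
        assert 1 / 1.5 < fit.k0 / 3e-4 < 1.5


class TestTraceIO:
    def test_write_read_round_trip(self, tmp_path):
        cfg = TraceConfig(noise_sd=5.0, seed=10, sampling_rate=10.0)
        trace = simulate_recycling_trace(
            KineticParams(), cfg, 30.0, 100.0, 1000.0, duration=500.0
        )
        path = tmp_path / "trace.tsv"
        write_trace(trace, str(path))
        back = read_trace(str(path))
        assert np.allclose(back.times, trace.times)
        assert np.allclose(back.extensions, trace.extensions, atol=1e-3)
        assert back.event_log == [(pytest.approx(t), e) for t, e in trace.event_log]
        assert back.meta["protocol"] == "recycling"
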