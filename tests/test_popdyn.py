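"""Culture, reporter and segregation dynamics; synthetic event sampling."""

from dataclasses import replace

import numpy as np
import pytest

from segflow.fcs_io import EventTable
from segflow.gating import Gate, GateSet, assign_gates, gate_fractions
from segflow.popdyn import (
    CultureState,
    GrowthParams,
    IntegrationFailureError,
    Phase,
    ReactorConfig,
    ReporterParams,
    Scenario,
    SegregationParams,
    kill_culture,
    limitation_signal,
    run_culture,
    sample_events,
    scenario,
    step_culture,
    step_reporter,
    update_segregation,
)


GROWTH = GrowthParams()
REPORTER = ReporterParams()


def _chemostat_config(d_rate, s_feed=5.0, x0=0.5, s0=1.0):
    return ReactorConfig(
        phases=(Phase(0.0, "chemostat", dilution_rate=d_rate),),
        s_feed=s_feed, x0=x0, s0=s0,
    )


def _integrate(config, state, hours, dt=0.01, reporter=REPORTER, growth=GROWTH):
    for _ in range(int(round(hours / dt))):
        state = step_culture(state, config, growth, dt, reporter)
    return state


class TestStepCulture:
    def test_chemostat_steady_state_matches_closed_form(self):
        d = 0.14
        config = _chemostat_config(d)
        state = CultureState(biomass=0.5, glucose=1.0)
        state = _integrate(config, state, 120.0)
        s_star = GROWTH.k_s * d / (GROWTH.mu_max - d)
        x_star = GROWTH.y_xs * (config.s_feed - s_star)
        assert state.glucose == pytest.approx(s_star, rel=0.01)
        assert state.biomass == pytest.approx(x_star, rel=0.01)
        assert state.mu == pytest.approx(d, rel=0.01)

    def test_starvation_fixed_point(self):
        config = ReactorConfig(phases=(Phase(0.0, "batch"),), x0=1.0, s0=0.0)
        state = CultureState(biomass=1.0, glucose=0.0)
        state = _integrate(config, state, 5.0)
        assert state.biomass == pytest.approx(1.0)
        assert state.mu == 0.0

    def test_washout_when_dilution_exceeds_mu_max(self):
        config = _chemostat_config(0.9, x0=1.0, s0=5.0)  # D > mu_max
        state = CultureState(biomass=1.0, glucose=5.0)
        biomasses = []
        for _ in range(3000):
            state = step_culture(state, config, GROWTH, 0.01)
            biomasses.append(state.biomass)
        # monotone decay after an initial transient, heading to zero
        tail = biomasses[500:]
        assert all(b2 <= b1 for b1, b2 in zip(tail, tail[1:]))
        assert tail[-1] < 0.01

    def test_batch_mass_balance(self):
        config = ReactorConfig(phases=(Phase(0.0, "batch"),), x0=0.1, s0=5.0)
        state = CultureState(biomass=0.1, glucose=5.0)
        end = _integrate(config, state, 10.0, dt=0.002)
        consumed = 5.0 - end.glucose
        produced = end.biomass - 0.1
        assert produced == pytest.approx(GROWTH.y_xs * consumed, rel=1e-3)

    def test_pulse_adds_glucose_mass(self):
        config = ReactorConfig(
            phases=(Phase(0.0, "chemostat_pulses", dilution_rate=0.0,
                          pulse_amount_g=0.24, pulse_period_min=15.0),),
            volume_l=1.0, x0=1e-9, s0=0.0,
        )
        state = CultureState(biomass=1e-9, glucose=0.0)
        state = _integrate(config, state, 1.0)
        # pulses at t in {0.25, 0.5, 0.75, 1.0} h (t=0 excluded: window is half-open)
        assert state.glucose == pytest.approx(4 * 0.24, rel=1e-6)

    def test_dt_bounds_enforced(self):
        state = CultureState()
        with pytest.raises(ValueError):
            step_culture(state, _chemostat_config(0.1), GROWTH, 0.5)

    def test_negative_state_raises_integration_failure(self):
        # huge biomass burns substrate in one step -> negative glucose
        state = CultureState(biomass=500.0, glucose=0.05)
        with pytest.raises(IntegrationFailureError):
            step_culture(state, _chemostat_config(0.0, s0=0.05), GROWTH, 0.01)

    def test_temperature_scales_growth(self):
        cold = GROWTH.mu(5.0, 30.0)
        warm = GROWTH.mu(5.0, 37.0)
        hot = GROWTH.mu(5.0, 42.0)
        assert cold < warm < hot


class TestStepReporter:
    def test_steady_state_matches_closed_form(self):
        params = REPORTER
        mu = 0.3
        state = CultureState(mu=mu, atp=params.atp_replete, gfp=0.0)
        for _ in range(4000):
            state = step_reporter(state, params, 30.0, 0.01)
        delta = params.degradation_rate(params.atp_replete, 30.0)
        g_star = params.alpha * mu**2 / (delta + mu)
        assert state.gfp == pytest.approx(g_star, rel=0.01)

    def test_pure_exponential_decay_halving(self):
        # mu = 0 and delta = ln2 / 0.8h: G halves every 0.8 h
        params = replace(REPORTER, delta_0=np.log(2) / 0.8, delta_max=0.0)
        state = CultureState(mu=0.0, atp=0.0, gfp=1000.0)
        for _ in range(int(0.8 / 0.001)):
            state = step_reporter(state, params, 30.0, 0.001)
        assert state.gfp == pytest.approx(500.0, rel=0.01)

    def test_default_half_life_below_one_hour_when_atp_replete(self):
        delta = REPORTER.degradation_rate(REPORTER.atp_replete, 30.0)
        assert np.log(2) / delta <= 1.0

    def test_heat_shock_factor_spike_and_relaxation(self):
        h0 = REPORTER.heat_shock_factor(42.0, 0.0)
        h5min = REPORTER.heat_shock_factor(42.0, 5.0 / 60.0)
        h_late = REPORTER.heat_shock_factor(42.0, 1.0)
        assert 15.0 <= h0 <= 20.0
        assert h5min < h0 / 3
        assert h_late == pytest.approx(REPORTER.shock_relaxed, rel=0.01)
        assert REPORTER.heat_shock_factor(30.0, None) == 1.0

    def test_upshift_starts_and_cooling_resets_the_clock(self):
        state = CultureState(time_h=2.0, gfp=100.0)
        hot = step_reporter(state, REPORTER, 42.0, 0.01)
        assert hot.shock_time_h == pytest.approx(2.0)
        cooled = step_reporter(hot, REPORTER, 30.0, 0.01)
        assert cooled.shock_time_h is None

    def test_glucose_pulse_after_heat_shock_degrades_gfp(self):
        """ATP from a post-shock substrate pulse fuels the proteases: the
        pulsed reactor's GFP falls below the unpulsed one's."""
        base = scenario("heatshock_pulse")
        no_pulse = replace(
            base,
            reactor=replace(
                base.reactor,
                phases=(Phase(0.0, "batch"), Phase(4.5, "chemostat", dilution_rate=0.0)),
            ),
        )
        shock_gfp = run_culture(base, t_end=4.5, dt=0.005)[-1].gfp
        end_pulse = run_culture(base, t_end=6.5, dt=0.005)[-1]
        end_ref = run_culture(no_pulse, t_end=6.5, dt=0.005)[-1]
        assert end_pulse.gfp < end_ref.gfp
        # pulsed reactor loses most of its GFP; the starved reference holds on
        assert end_pulse.gfp < 0.5 * shock_gfp
        assert end_ref.gfp > 0.6 * shock_gfp


class TestUpdateSegregation:
    def test_zero_limitation_relaxes_to_minimum(self):
        params = SegregationParams()
        state = CultureState(f_r1=0.6, f_r2=0.4, f_r3=0.0)
        for _ in range(2000):
            state = update_segregation(state, 0.0, params, 0.01)
        assert state.f_r2 == pytest.approx(params.f2_min, abs=1e-6)
        assert state.f_r2 < 0.05  # below the initial-culture ceiling

    def test_full_limitation_reaches_maximum_equal_partition(self):
        from segflow.segmetrics import degree_of_segregation

        params = SegregationParams(f2_max=0.5)
        state = CultureState()
        for _ in range(3000):
            state = update_segregation(state, 1.0, params, 0.01)
        assert state.f_r2 == pytest.approx(0.5, abs=1e-4)
        assert degree_of_segregation(state.f_r1, state.f_r2) == pytest.approx(1.0, abs=1e-3)

    def test_alternating_limitation_matches_recurrence(self):
        params = SegregationParams()
        state = CultureState()
        f2 = state.f_r2
        dt = 0.01
        for i in range(500):
            lim = 1.0 if (i // 50) % 2 == 0 else 0.0
            state = update_segregation(state, lim, params, dt)
            target = params.f2_min + (params.f2_max - params.f2_min) * lim
            f2 = f2 + params.rate * (target - f2) * dt
            assert state.f_r2 == pytest.approx(f2, rel=1e-12)

    def test_fractions_stay_normalized(self):
        state = CultureState(f_r1=0.5, f_r2=0.3, f_r3=0.2)
        out = update_segregation(state, 0.9, SegregationParams(), 0.01)
        assert out.f_r1 + out.f_r2 + out.f_r3 == pytest.approx(1.0)
        assert out.f_r3 == 0.2  # only a kill event moves R3

    def test_invalid_limitation_rejected(self):
        with pytest.raises(ValueError):
            update_segregation(CultureState(), 1.5, SegregationParams(), 0.01)

    def test_kill_event_moves_cells_to_r3(self):
        state = kill_culture(CultureState(f_r1=0.9, f_r2=0.1, f_r3=0.0), 1.0)
        assert state.f_r3 == pytest.approx(1.0)
        assert state.f_r1 == pytest.approx(0.0)


class TestSampleEvents:
    def test_degenerate_mixture_lands_in_band_gate(self):
        state = CultureState(f_r1=1.0, f_r2=0.0, f_r3=0.0)
        table = sample_events(state, 5000, seed=1)
        loc, sd = state.fl3_bands[0]
        gate = Gate("band1", {"FL3": (10 ** (loc - 5 * sd), 10 ** (loc + 5 * sd))}, 1)
        gs = GateSet(gates=(gate,), fsc_threshold=0)
        fr = gate_fractions(assign_gates(table, gs))
        assert fr.get("band1", 0.0) > 0.999

    def test_fraction_recovery_within_binomial_error(self):
        state = CultureState(f_r1=0.7, f_r2=0.3, f_r3=0.0)
        n = 40_000
        table = sample_events(state, n, seed=5)
        fl3 = table.events["FL3"].to_numpy()
        # split halfway between the R1 and R2 bands (log10 2.0 vs 3.0)
        observed = float(np.mean(fl3 >= 10 ** 2.5))
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(observed - 0.3) < 3 * se

    def test_same_seed_identical_tables(self):
        state = scenario("chemostat_pulses").initial_state()
        a = sample_events(state, 1000, seed=42)
        b = sample_events(state, 1000, seed=42)
        assert a.events.equals(b.events)

    def test_different_seed_differs(self):
        state = CultureState()
        assert not sample_events(state, 100, seed=1).events.equals(
            sample_events(state, 100, seed=2).events
        )

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            sample_events(CultureState(), 0, seed=1)

    def test_heat_shock_widens_fl1_distribution(self):
        calm = CultureState(gfp=500.0)
        shocked = replace(calm, shock_time_h=4.5, time_h=5.0)
        sd_calm = np.std(np.log10(sample_events(calm, 20_000, seed=9).events["FL1"]))
        sd_shock = np.std(np.log10(sample_events(shocked, 20_000, seed=9).events["FL1"]))
        assert sd_shock > 1.5 * sd_calm

    def test_channels_and_nonnegativity(self):
        table = sample_events(CultureState(), 500, seed=3)
        assert set(table.channels) == {"FSC", "SSC", "FL1", "FL3"}
        assert (table.events.to_numpy() >= 0).all()


class TestScenarios:
    def test_named_scenarios_exist_and_run(self):
        for name in ("chemostat_pulses", "three_temperatures", "heatshock_pulse", "unimodal_control"):
            scn = scenario(name)
            states = run_culture(scn, t_end=0.5, dt=0.01)
            assert states[-1].time_h == pytest.approx(0.5)

    def test_unknown_scenario(self):
        with pytest.raises(KeyError):
            scenario("nope")

    def test_run_culture_is_deterministic(self):
        scn = scenario("chemostat_pulses")
        a = run_culture(scn, t_end=2.0, dt=0.01)[-1]
        b = run_culture(scn, t_end=2.0, dt=0.01)[-1]
        assert a == b
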