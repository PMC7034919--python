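"""Oscillatory steering law and closed-loop runs."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oppnav as on


class TestTurnAmplitude:
    @pytest.mark.parametrize("baseline,gain,drive,expected", [
        (90.0, 100.0, 0.3, 60.0),       # plain arithmetic
        (90.0, 100.0, -1.5, 180.0),     # clipped above
        (90.0, 100.0, 1.5, 0.0),        # clipped below
        (45.0, 0.0, -0.9, 45.0),        # zero gain pins the baseline
        (45.0, 0.0, 0.9, 45.0),
    ])
    def test_finite_gain(self, baseline, gain, drive, expected):
        p = on.AgentParams(baseline=baseline, gain=gain)
        assert on.turn_amplitude(drive, p) == expected

    @pytest.mark.parametrize("drive,expected", [
        (0.01, 0.0), (1.0, 0.0), (-0.01, 180.0), (-1.0, 180.0), (0.0, 77.0),
    ])
    def test_infinite_gain_sign_rule(self, drive, expected):
        p = on.AgentParams(baseline=77.0, gain=math.inf)
        assert on.turn_amplitude(drive, p) == expected

    @settings(deadline=None, max_examples=100)
    @given(
        drive=st.floats(-2, 2, allow_nan=False),
        baseline=st.floats(0, 180),
        gain=st.one_of(st.floats(0, 1e6), st.just(math.inf)),
    )
    def test_bounded_and_monotone(self, drive, baseline, gain):
        p = on.AgentParams(baseline=baseline, gain=gain)
        amp = on.turn_amplitude(drive, p)
        assert 0.0 <= amp <= 180.0
        # non-increasing in drive
        assert on.turn_amplitude(drive + 0.25, p) <= amp + 1e-9


class TestStepRules:
    def _quiet_params(self, **kw):
        defaults = dict(baseline=30.0, gain=0.0, noise_model="none")
        defaults.update(kw)
        return on.AgentParams(**defaults)

    def test_headings_alternate_around_mean(self, open_world, banks, ctx):
        """Zero gain, no noise: headings alternate +b/-b about a fixed
        mean direction."""
        params = self._quiet_params(baseline=30.0)
        rng = np.random.default_rng(0)
        state = on.AgentState(position=np.array([2.0, 0.0]), theta=0.0,
                              oscillator_sign=1)
        thetas = []
        for _ in range(6):
            state, rec = on.step_agent(state, open_world, banks, ctx,
                                       params, rng)
            thetas.append(rec["theta"])
        assert np.allclose(thetas, [30.0, 0.0, 30.0, 0.0, 30.0, 0.0])

    def test_two_step_heading_unrolled(self, open_world, banks, ctx):
        """From theta=0 with amplitudes a then a (signs +, -): theta
        returns to a - a = 0."""
        params = self._quiet_params(baseline=45.0)
        rng = np.random.default_rng(0)
        state = on.AgentState(position=np.array([2.0, 0.0]), theta=0.0,
                              oscillator_sign=1)
        state, r1 = on.step_agent(state, open_world, banks, ctx, params, rng)
        assert r1["theta"] == 45.0
        state, r2 = on.step_agent(state, open_world, banks, ctx, params, rng)
        assert r2["theta"] == 0.0

    def test_oscillator_alternates_regardless_of_drive(self, open_world,
                                                       banks, ctx):
        params = on.AgentParams(max_steps=30, seed=4)
        path = on.run_agent(open_world, banks, ctx, params, (3.0, 1.0))
        signs = path.to_dataframe()["oscillator_sign"].to_numpy()
        assert np.all(signs[1:] == -signs[:-1])

    def test_step_length_exact(self, open_world, banks, ctx):
        params = on.AgentParams(max_steps=25, seed=1)
        path = on.run_agent(open_world, banks, ctx, params, (2.0, -1.0))
        gaps = np.hypot(*np.diff(path.positions, axis=0).T)
        assert np.allclose(gaps, params.step_length, atol=1e-12)


class TestRunAgent:
    def test_deterministic_given_seed(self, open_world, banks, ctx):
        params = on.AgentParams(max_steps=40, seed=9)
        p1 = on.run_agent(open_world, banks, ctx, params, (4.0, 0.0))
        p2 = on.run_agent(open_world, banks, ctx, params, (4.0, 0.0))
        assert np.array_equal(p1.positions, p2.positions)
        assert p1.to_dataframe().equals(p2.to_dataframe())

    def test_zero_steps_empty_path(self, open_world, banks, ctx):
        params = on.AgentParams(max_steps=0)
        path = on.run_agent(open_world, banks, ctx, params, (1.0, 1.0))
        assert path.n_steps == 0
        assert np.allclose(path.final_position, (1.0, 1.0))

    def test_out_of_world_truncation(self, open_world, banks, ctx):
        # a zero-baseline, zero-gain agent walks straight out
        params = on.AgentParams(baseline=0.0, gain=0.0, noise_model="none",
                                max_steps=10_000, seed=2)
        release = (open_world.bounds - 1.0, 0.0)
        path = on.run_agent(open_world, banks, ctx, params, release,
                            initial_heading=0.0)
        assert path.status == "out_of_world"
        assert path.n_steps < 10_000

    def test_release_outside_bounds_rejected(self, open_world, banks, ctx):
        with pytest.raises(ValueError):
            on.run_agent(open_world, banks, ctx, on.AgentParams(),
                         (100.0, 100.0))

    def test_attractive_only_records_no_repulsive(self, open_world, banks,
                                                  ctx):
        params = on.AgentParams(memory_mode="attractive_only", max_steps=5,
                                seed=0)
        path = on.run_agent(open_world, banks, ctx, params, (3.0, 0.0))
        df = path.to_dataframe()
        assert df["repulsive_familiarity"].isna().all()
        assert np.isfinite(df["overall_drive"]).all()

    def test_path_round_trip_files(self, open_world, banks, ctx, tmp_path):
        params = on.AgentParams(max_steps=12, seed=3)
        path = on.run_agent(open_world, banks, ctx, params, (2.0, 2.0))
        path.save(tmp_path / "p.csv", tmp_path / "p.json")
        import pandas as pd
        df = pd.read_csv(tmp_path / "p.csv")
        assert list(df.columns) == [
            "t", "x", "y", "theta", "turn_amplitude", "oscillator_sign",
            "attractive_familiarity", "repulsive_familiarity", "overall_drive"]
        meta = json.loads((tmp_path / "p.json").read_text())
        assert meta["status"] == "completed"
        assert np.isclose(meta["arrival_distance"], path.arrival_distance)


class TestHomingBehaviour:
    def test_opponent_agents_home_from_4m(self, open_world, banks, ctx):
        """Majority of default-parameter agents released at 4 m reach
        the nest's 1 m surround."""
        releases = on.release_points(open_world.nest, 4.0, 10, seed=0)
        succ = sum(
            on.homing_success(
                on.run_agent(open_world, banks, ctx,
                             on.AgentParams(max_steps=320, seed=50 + i),
                             r),
                open_world.nest)
            for i, r in enumerate(releases))
        assert succ >= 6

    def test_opponent_beats_tuned_attractive_only(self, open_world, banks,
                                                  ctx):
        """Opponent defaults outperform attractive-only at its best swept
        operating point (gain 50, baseline 180)."""
        releases = on.release_points(open_world.nest, 4.0, 10, seed=0)
        med = {}
        for mode, gain, baseline in (("opponent", 1250.0, 90.0),
                                     ("attractive_only", 50.0, 180.0)):
            dists = [
                on.run_agent(open_world, banks, ctx,
                             on.AgentParams(gain=gain, baseline=baseline,
                                            memory_mode=mode, max_steps=320,
                                            seed=70 + i),
                             r).arrival_distance
                for i, r in enumerate(releases)]
            med[mode] = np.median(dists)
        assert med["opponent"] < med["attractive_only"]

    @pytest.mark.parametrize("gain_multiplier", [10.0, 100.0])
    def test_graceful_degradation_at_high_gain(self, open_world, banks, ctx,
                                               gain_multiplier):
        """Raising the gain far above its threshold keeps the agent
        homing (no catastrophic failure)."""
        gain = 250.0 * gain_multiplier
        releases = on.release_points(open_world.nest, 4.0, 8, seed=1)
        succ = sum(
            on.homing_success(
                on.run_agent(open_world, banks, ctx,
                             on.AgentParams(gain=gain, max_steps=320,
                                            seed=90 + i),
                             r),
                open_world.nest)
            for i, r in enumerate(releases))
        assert succ >= 5
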