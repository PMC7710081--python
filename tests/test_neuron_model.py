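import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tactilepop.neuron_model import (
    MIXING,
    RESET,
    SUMMATION,
    BranchState,
    NeuronModel,
    ResponsivityParams,
    SpikeTrain,
    edge_drive,
    effective_indentation,
    make_simple_rf_neuron,
    mr_input,
    rate_curve,
    rf_boundary_from_dot_scan,
    simulate_neuron,
    step_branch,
)
from tactilepop.skin_stimulus import (
    EdgeStimulus,
    SimulationClock,
    SkinPatch,
    edge_distance,
    prepare_edge,
    sweep_interval,
)

PARAMS = ResponsivityParams(r1=0.5, r2=0.5, w_mr=100.0)


class TestMrInput:
    def test_beyond_reach_is_zero(self):
        assert mr_input(1.5, 0.5, PARAMS) == 0.0

    def test_half_height_at_r1(self):
        assert mr_input(0.5, 0.5, PARAMS) == pytest.approx(25.0)

    def test_at_zero_distance(self):
        expected = 0.5 * 100.0 * (1.0 - 1.0 / (1.0 + math.exp(5.0)))
        assert expected == pytest.approx(49.6654, abs=1e-3)
        assert mr_input(0.0, 0.5, PARAMS) == pytest.approx(expected, rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            mr_input(-0.1, 0.5, PARAMS)


class TestEffectiveIndentation:
    def test_at_zero_distance(self):
        val = effective_indentation(0.0, 0.5, PARAMS)
        assert val == pytest.approx(0.4967, abs=1e-3)
        assert val >= 0.01

    def test_small_amplitude_below_threshold(self):
        assert effective_indentation(0.0, 0.005, PARAMS) < 0.01

    def test_beyond_reach(self):
        assert effective_indentation(1.2, 0.5, PARAMS) == 0.0


class TestStepBranch:
    def test_constant_input_never_spikes(self):
        state = BranchState()
        spikes = []
        for _ in range(200):
            state, s = step_branch(state, 80.0, 1.0, 100.0, eff_indent=0.4)
            spikes.append(s)
        assert not any(spikes)  # non-increasing input is silent

    def test_zero_input_keeps_phase_zero(self):
        state = BranchState()
        for _ in range(10):
            state, s = step_branch(state, 0.0, 1.0, 100.0)
            assert not s
        assert state.phase == 0.0

    def test_saturated_ramp_isi(self):
        # strictly increasing ramp far above saturation: ISI -> ceil(1000/max_rate)
        max_rate = 250.0
        state = BranchState()
        times = []
        for t in range(100):
            state, s = step_branch(state, 1000.0 + t, 1.0, max_rate, eff_indent=0.4)
            if s:
                times.append(t)
        isis = np.diff(times)
        assert np.all(isis == math.ceil(1000.0 / max_rate))


def _brute_force_simulate(neuron, stimulus, clock, scheme):
    """Independent tick-by-tick oracle, scalar arithmetic only."""
    p = neuron.responsivity
    n = neuron.n_mr
    phases = [0.0] * n
    prev = [0.0] * n
    out = []
    for t in clock.times:
        fired = False
        eligible = []
        for i in range(n):
            d = edge_distance(neuron.mr_locations[i], stimulus, t)
            drive = float(mr_input(d, stimulus.amplitude, p))
            eff = float(effective_indentation(d, stimulus.amplitude, p))
            rate = min(drive, neuron.max_rate)
            phases[i] += rate * clock.dt / 1000.0
            if phases[i] >= 1.0 and drive > prev[i] and eff >= 0.01:
                eligible.append(i)
            prev[i] = drive
        if eligible:
            fired = True
            if scheme == RESET:
                phases = [0.0] * n
            else:
                for i in eligible:
                    phases[i] = 0.0
        out.append(fired)
    return np.asarray(out)


class TestSimulateNeuron:
    def _toy(self, locations, scheme=RESET, max_rate=180.0):
        return NeuronModel(
            mr_locations=np.asarray(locations, dtype=float),
            responsivity=ResponsivityParams(r1=0.4, r2=0.6, w_mr=2 * 180.0),
            max_rate=max_rate,
            scheme=scheme,
        )

    @pytest.mark.parametrize("scheme", [RESET, MIXING])
    @pytest.mark.parametrize(
        "locations",
        [[(5.0, 6.0)], [(4.5, 6.0), (5.5, 6.5)], [(4.0, 5.0), (5.0, 6.0), (6.0, 7.0)]],
    )
    def test_oracle_equivalence(self, patch, scheme, locations):
        neuron = self._toy(locations, scheme=scheme)
        stim = prepare_edge(EdgeStimulus(10.0), patch)
        clock = sweep_interval(stim, patch)
        train = simulate_neuron(neuron, stim, clock)
        oracle = _brute_force_simulate(neuron, stim, clock, scheme)
        got = np.zeros(clock.n_ticks, dtype=bool)
        got[np.round(train.times / clock.dt).astype(int)] = True
        assert np.array_equal(got, oracle)

    def test_duplicated_mr_invariance_under_reset(self, patch):
        neuron = self._toy([(4.5, 6.0), (5.5, 6.5)])
        doubled = self._toy([(4.5, 6.0), (5.5, 6.5), (4.5, 6.0)])
        stim = prepare_edge(EdgeStimulus(-22.5), patch)
        clock = sweep_interval(stim, patch)
        a = simulate_neuron(neuron, stim, clock)
        b = simulate_neuron(doubled, stim, clock)
        assert np.array_equal(a.times, b.times)

    def test_mr_order_invariance_under_reset(self, patch):
        locs = [(4.0, 5.0), (5.0, 6.0), (6.5, 7.0)]
        stim = prepare_edge(EdgeStimulus(45.0), patch)
        clock = sweep_interval(stim, patch)
        a = simulate_neuron(self._toy(locs), stim, clock)
        b = simulate_neuron(self._toy(locs[::-1]), stim, clock)
        assert np.array_equal(a.times, b.times)

    def test_single_mr_schemes_degenerate(self, patch):
        stim = prepare_edge(EdgeStimulus(0.0), patch)
        clock = sweep_interval(stim, patch)
        trains = [
            simulate_neuron(self._toy([(6.0, 6.0)], scheme=s), stim, clock).times
            for s in (RESET, MIXING, SUMMATION)
        ]
        assert np.array_equal(trains[0], trains[1])
        assert np.array_equal(trains[0], trains[2])

    def test_mixing_fires_at_least_as_much_as_reset(self, patch):
        locs = [(5.0, 5.5), (6.0, 6.5)]
        stim = prepare_edge(EdgeStimulus(20.0), patch)
        clock = sweep_interval(stim, patch)
        n_reset = len(simulate_neuron(self._toy(locs, scheme=RESET), stim, clock))
        n_mix = len(simulate_neuron(self._toy(locs, scheme=MIXING), stim, clock))
        assert n_mix >= n_reset

    def test_min_isi_respects_max_rate(self, patch, truth_neuron):
        floor = math.floor(1000.0 / truth_neuron.max_rate)
        for theta in (-45.0, -10.0, 0.0, 30.0):
            stim = prepare_edge(EdgeStimulus(theta), patch)
            clock = sweep_interval(stim, patch)
            train = simulate_neuron(truth_neuron, stim, clock)
            if len(train) > 1:
                assert np.diff(train.times).min() >= floor

    def test_no_spikes_after_edge_recedes(self, patch, truth_neuron):
        stim = prepare_edge(EdgeStimulus(15.0), patch)
        clock = sweep_interval(stim, patch)
        train = simulate_neuron(truth_neuron, stim, clock)
        # time at which the line has passed every MR
        n = stim.normal
        offsets = (truth_neuron.mr_locations - np.asarray(stim.ref_start)) @ n
        t_pass = offsets.max() / (stim.speed / 1000.0 * n[0])
        assert len(train) > 0
        assert train.times.max() <= t_pass + clock.dt


class TestRateCurve:
    def test_empty_train(self):
        clock = SimulationClock(dt=1.0, t_start=0.0, t_end=100.0)
        rc = rate_curve(SpikeTrain(times=np.array([]), duration=100.0), clock)
        assert np.all(rc.rate == 0.0)

    def test_single_spike_integrates_to_one(self):
        clock = SimulationClock(dt=1.0, t_start=0.0, t_end=200.0)
        rc = rate_curve(SpikeTrain(times=np.array([100.0]), duration=200.0), clock, 5.0)
        assert rc.rate.sum() * clock.dt / 1000.0 == pytest.approx(1.0, abs=1e-6)

    def test_two_close_spikes_match_kernel_sum(self):
        clock = SimulationClock(dt=1.0, t_start=0.0, t_end=200.0)
        sigma = 5.0
        spikes = [98.0, 102.0]
        rc = rate_curve(SpikeTrain(times=np.array(spikes), duration=200.0), clock, sigma)
        t = clock.times
        expected = sum(
            1000.0 * np.exp(-((t - s) ** 2) / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))
            for s in spikes
        )
        assert np.allclose(rc.rate, expected, atol=1e-4)
        assert t[np.argmax(rc.rate)] == pytest.approx(100.0)


class TestSimpleRf:
    def test_paper_defaults(self):
        n = make_simple_rf_neuron((6.0, 6.0), max_rate=120.0)
        assert n.responsivity.reach == pytest.approx(1.5)
        assert n.responsivity.w_mr == pytest.approx(240.0)

    def test_half_drive_at_r1(self):
        n = make_simple_rf_neuron((6.0, 6.0), max_rate=120.0)
        full = 0.5 * n.responsivity.w_mr
        assert mr_input(0.05, 0.5, n.responsivity) == pytest.approx(full / 2.0)

    def test_zero_drive_beyond_reach(self):
        n = make_simple_rf_neuron((6.0, 6.0), max_rate=120.0)
        assert mr_input(2.0, 0.5, n.responsivity) == 0.0


class TestRfBoundary:
    def _single_mr(self, center, r1=0.3, r2=0.5, max_rate=200.0):
        return NeuronModel(
            mr_locations=np.asarray([center]),
            responsivity=ResponsivityParams(r1, r2, 2 * max_rate),
            max_rate=max_rate,
        )

    def test_single_mr_boundary_is_symmetric_disc(self, patch):
        neuron = self._single_mr((6.0, 6.0))
        region = rf_boundary_from_dot_scan(neuron, patch, ramp_ms=100.0)
        minx, miny, maxx, maxy = region.bounds
        cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
        assert (cx, cy) == pytest.approx((6.0, 6.0), abs=0.11)
        # roughly circular and inside the hard reach cutoff
        assert (maxx - minx) == pytest.approx(maxy - miny, abs=0.21)
        assert (maxx - minx) / 2.0 <= neuron.responsivity.reach + 0.2

    def test_two_distant_mrs_give_two_lobes(self, patch):
        neuron = NeuronModel(
            mr_locations=np.asarray([(3.0, 3.0), (9.0, 9.0)]),
            responsivity=ResponsivityParams(0.3, 0.5, 400.0),
            max_rate=200.0,
        )
        region = rf_boundary_from_dot_scan(neuron, patch, ramp_ms=100.0)
        assert region.geom_type == "MultiPolygon"
        assert len(region.geoms) == 2

    def test_zero_amplitude_dot_rejected(self, patch):
        with pytest.raises(ValueError):
            rf_boundary_from_dot_scan(self._single_mr((6, 6)), patch, dot_amplitude=0.0)

    def test_unresponsive_neuron_raises(self, patch):
        quiet = self._single_mr((6.0, 6.0), max_rate=5.0)  # too slow to reach phase 1
        with pytest.raises(ValueError):
            rf_boundary_from_dot_scan(quiet, patch, ramp_ms=20.0)


class TestValidation:
    def test_scheme_checked(self):
        with pytest.raises(ValueError):
            NeuronModel(np.zeros((1, 2)), PARAMS, 100.0, scheme="telepathy")

    def test_positive_max_rate(self):
        with pytest.raises(ValueError):
            NeuronModel(np.zeros((1, 2)), PARAMS, 0.0)

    def test_spike_train_monotone(self):
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([3.0, 2.0]), duration=10.0)
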