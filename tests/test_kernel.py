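"""Kernel: exact integration, ring buffers, event-driven plasticity, drive."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import expm

from spikescale.connection_store import ConnectionRecord
from spikescale.kernel import (
    LIFParams,
    LIFState,
    RingBuffer,
    STDPParams,
    SpikeHistory,
    make_propagator,
    poisson_input,
    poisson_input_array,
    step_neuron,
    stdp_on_presyn_spike,
)


def analytic_state(params, V0, I0, t):
    """Closed-form subthreshold solution for initial (V0, I0), no input."""
    em, es = math.exp(-t / params.tau_m), math.exp(-t / params.tau_syn)
    inv = 1.0 / params.tau_m - 1.0 / params.tau_syn
    V = params.E_L + (V0 - params.E_L) * em + I0 * (es - em) / (inv * params.C_m)
    return V, I0 * es


class TestPropagator:
    def test_zero_input_membrane_decay(self):
        params = LIFParams()
        prop = make_propagator(params)
        assert prop.decay_mem == pytest.approx(math.exp(-params.h / params.tau_m), rel=1e-15)

    def test_short_step_approaches_identity(self):
        prop = make_propagator(LIFParams(h=1e-7))
        assert prop.decay_mem == pytest.approx(1.0, abs=1e-7)
        assert prop.decay_syn == pytest.approx(1.0, abs=1e-7)
        assert prop.mix == pytest.approx(0.0, abs=1e-9)

    @given(
        tau_m=st.floats(1.0, 50.0),
        tau_ratio=st.floats(0.02, 0.9),
        c_m=st.floats(50.0, 500.0),
        h=st.floats(0.01, 1.0),
    )
    def test_entries_match_matrix_exponential_oracle(self, tau_m, tau_ratio, c_m, h):
        tau_syn = tau_m * tau_ratio
        params = LIFParams(tau_m=tau_m, tau_syn=tau_syn, C_m=c_m, h=h, t_ref=0.0)
        prop = make_propagator(params)
        A = np.array([[-1.0 / tau_syn, 0.0], [1.0 / c_m, -1.0 / tau_m]])
        P = expm(A * h)
        assert prop.decay_syn == pytest.approx(P[0, 0], rel=1e-12)
        assert prop.mix == pytest.approx(P[1, 0], rel=1e-12)
        assert prop.decay_mem == pytest.approx(P[1, 1], rel=1e-12)

    def test_degenerate_time_constants_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_propagator(LIFParams(tau_m=10.0, tau_syn=10.0))


class TestStepNeuron:
    def test_suprathreshold_spikes_and_resets(self):
        params = LIFParams()
        state, spiked = step_neuron(LIFState(V=params.V_th + 1.0), 0.0, params)
        assert spiked and state.V == params.V_reset
        assert state.refr_steps_left == params.ref_steps

    def test_refractory_ignores_input_and_counts_down(self):
        params = LIFParams()
        state = LIFState(V=params.V_reset, I=0.0, refr_steps_left=3)
        state, spiked = step_neuron(state, 1e6, params)
        assert not spiked and state.V == params.V_reset and state.refr_steps_left == 2

    def test_exact_trajectory_matches_closed_form(self):
        # "exact integration": grid values equal the analytic solution
        params = LIFParams(V_th=1e9, t_ref=0.0)
        prop = make_propagator(params)
        V0, I0 = -60.0, 300.0
        state = LIFState(V=V0, I=I0)
        for n in range(1, 101):
            state, _ = step_neuron(state, 0.0, params, prop)
            V_ref, I_ref = analytic_state(params, V0, I0, n * params.h)
            assert abs(state.V - V_ref) < 1e-10
            assert abs(state.I - I_ref) < 1e-10

    def test_constant_input_converges_to_linear_fixed_point(self):
        params = LIFParams(V_th=1e9, t_ref=0.0)
        prop = make_propagator(params)
        c = 50.0  # summed weight arriving every step
        # oracle: fixed point of the affine one-step map, solved linearly
        A = np.array([[prop.decay_syn, 0.0], [prop.mix, prop.decay_mem]])
        b = np.array([c, (1 - prop.decay_mem) * params.E_L])
        I_star, V_star = np.linalg.solve(np.eye(2) - A, b)
        state = LIFState(V=params.E_L)
        for _ in range(3000):
            state, _ = step_neuron(state, c, params, prop)
        assert state.I == pytest.approx(I_star, rel=1e-10)
        assert state.V == pytest.approx(V_star, rel=1e-10)

    def test_non_finite_state_rejected(self):
        with pytest.raises(ValueError):
            step_neuron(LIFState(V=float("nan")), 0.0, LIFParams())


class TestRingBuffer:
    def test_spikes_lump_within_a_slot(self):
        buf = RingBuffer(max_delay_steps=5)
        buf.enqueue_spike(1.5, 3, current_step=0)
        buf.enqueue_spike(2.5, 3, current_step=0)
        assert buf.read(1) == 0.0 and buf.read(2) == 0.0
        assert buf.read(3) == 4.0
        assert buf.read(3) == 0.0  # consumed

    def test_delay_bounds_enforced(self):
        buf = RingBuffer(max_delay_steps=5)
        with pytest.raises(ValueError):
            buf.enqueue_spike(1.0, 0, 0)
        with pytest.raises(ValueError):
            buf.enqueue_spike(1.0, 6, 0)

    def test_random_schedule_matches_event_list_oracle(self):
        gen = np.random.default_rng(7)
        max_delay, n_steps = 8, 60
        buf = RingBuffer(max_delay)
        arrivals = {}  # step -> summed weight, the flat oracle
        for step in range(n_steps):
            for _ in range(int(gen.integers(0, 4))):
                delay = int(gen.integers(1, max_delay + 1))
                weight = float(gen.normal())
                buf.enqueue_spike(weight, delay, step)
                arrivals[step + delay] = arrivals.get(step + delay, 0.0) + weight
            got = buf.read(step)
            assert got == pytest.approx(arrivals.pop(step, 0.0), abs=1e-12)

    def test_weight_conservation(self):
        gen = np.random.default_rng(8)
        buf = RingBuffer(10)
        total_in = 0.0
        total_out = 0.0
        for step in range(40):
            w = float(gen.uniform(0, 1))
            buf.enqueue_spike(w, int(gen.integers(1, 11)), step)
            total_in += w
            total_out += buf.read(step)
        for step in range(40, 51):  # drain the tail
            total_out += buf.read(step)
        assert total_out == pytest.approx(total_in, rel=1e-12)


def stdp_oracle(w_init, pre, post, p):
    """Brute-force all-pairs accumulation, applied in time order.

    At each postsynaptic spike: potentiate with the summed exponential trace
    of all earlier presynaptic spikes; at each presynaptic spike: depress with
    the trace of all earlier postsynaptic spikes.  Ties pair neither way and
    the potentiation at a shared time is applied first.
    """
    events = sorted([(t, 1) for t in pre] + [(t, 0) for t in post])
    w = w_init
    for t, kind in events:
        if kind == 0:
            k = sum(math.exp(-(t - s) / p.tau_plus) for s in pre if s < t)
            w += p.lam * p.w0 ** (1 - p.mu) * w**p.mu * k
        else:
            k = sum(math.exp(-(t - s) / p.tau_minus) for s in post if s < t)
            w = max(w - p.lam * p.alpha * w * k, 0.0)
    return w


def run_event_driven(w_init, pre, post, p):
    syn = ConnectionRecord(target=0, weight=w_init, delay_steps=1)
    history = SpikeHistory(post)
    for t in pre:
        stdp_on_presyn_spike(syn, t, history, p)
    return syn.weight


class TestSTDP:
    PARAMS = STDPParams(w0=20.0)

    def test_zero_learning_rate_is_inert(self):
        p = STDPParams(lam=0.0, w0=20.0)
        assert run_event_driven(20.0, [5.0, 9.0], [6.0, 7.5], p) == 20.0

    def test_empty_post_history_leaves_weight(self):
        assert run_event_driven(20.0, [5.0, 9.0], [], self.PARAMS) == 20.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        gen = np.random.default_rng(seed)
        n_pre, n_post = int(gen.integers(1, 26)), int(gen.integers(0, 26))
        pre = sorted(set(np.round(gen.uniform(0.1, 200.0, n_pre), 1)))
        t_last_pre = max(pre)
        # the event-driven path advances only up to the last presynaptic spike
        post = sorted(
            {t for t in np.round(gen.uniform(0.1, 200.0, n_post), 1) if t <= t_last_pre}
        )
        w_oracle = stdp_oracle(20.0, pre, post, self.PARAMS)
        w_event = run_event_driven(20.0, pre, post, self.PARAMS)
        assert w_event == pytest.approx(w_oracle, rel=1e-12)

    def test_simultaneous_pre_post_pairs_neither_way(self):
        # a shared spike time contributes no Delta-t = 0 pairing
        w = run_event_driven(20.0, [10.0], [10.0], self.PARAMS)
        assert w == 20.0

    def test_split_updates_equal_single_time_ordered_pass(self):
        pre = [3.0, 6.0, 9.0, 14.0]
        post = [4.0, 8.0, 13.0]
        assert run_event_driven(20.0, pre, post, self.PARAMS) == pytest.approx(
            stdp_oracle(20.0, pre, post, self.PARAMS), rel=1e-12
        )

    def test_out_of_order_update_rejected(self):
        syn = ConnectionRecord(target=0, weight=1.0, delay_steps=1)
        history = SpikeHistory([1.0])
        stdp_on_presyn_spike(syn, 5.0, history, self.PARAMS)
        with pytest.raises(ValueError):
            stdp_on_presyn_spike(syn, 2.0, history, self.PARAMS)

    def test_history_requires_increasing_times(self):
        with pytest.raises(ValueError):
            SpikeHistory([2.0, 2.0])


class TestPoissonInput:
    def test_zero_rate_is_silent(self):
        assert poisson_input(3, 17, 0.0, seed=1) == 0

    def test_keyed_draws_are_reproducible_and_partition_free(self):
        # value depends only on (seed, gid, step): scalar and vectorized
        # evaluation orders must agree draw for draw
        gids = np.arange(50)
        vec = poisson_input_array(gids, step=12, rate=8000.0, seed=9)
        for gid in (0, 7, 49):
            assert poisson_input(gid, 12, 8000.0, seed=9) == vec[gid]
        assert poisson_input(5, 3, 8000.0, seed=9) == poisson_input(5, 3, 8000.0, seed=9)
        from spikescale.rng import keyed_uniform

        assert keyed_uniform(9, 5, 3) != keyed_uniform(10, 5, 3)

    def test_empirical_mean_within_three_sigma(self):
        rate, h, n = 8000.0, 0.1, 10**6
        mean = rate * h * 1e-3
        counts = poisson_input_array(np.arange(n), step=0, rate=rate, seed=11, h=h)
        sigma_mean = math.sqrt(mean / n)
        assert abs(counts.mean() - mean) < 3 * sigma_mean
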