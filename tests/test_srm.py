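"""Unit and property tests for the SRM neuron and network simulator."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gesnn import (
    HiddenNeuronSpec,
    NetworkTopology,
    SRMParams,
    SynapseSpec,
    first_spike_time,
    membrane_potential,
    psp_kernel,
    simulate_batch,
    simulate_network,
    topology_from_json,
    topology_to_json,
)


def brute_force_first_spike(impinging, params, search_from=0.0, refine=10):
    """Independent oracle: threshold search on a refine-times-finer grid."""
    fine = params.dt / refine
    n = int(round((params.t_end - search_from) / fine))
    for i in range(n + 1):
        t = search_from + i * fine
        pot = sum(
            w * ((max(t - ti - d, 0.0) / params.tau)
                 * math.exp(1 - max(t - ti - d, 0.0) / params.tau)
                 if t - ti - d > 0 else 0.0)
            for ti, w, d in impinging
        )
        if pot >= params.theta:
            return t
    return None


class TestPSPKernel:
    def test_closed_form_values(self):
        assert psp_kernel(0.0, 9.0) == 0.0
        assert psp_kernel(-3.0, 9.0) == 0.0
        assert psp_kernel(9.0, 9.0) == 1.0
        assert psp_kernel(4.5, 9.0) == pytest.approx(0.5 * math.exp(0.5), abs=1e-12)

    def test_unimodal_peak_at_tau(self):
        # strictly increasing before tau, strictly decreasing after, max 1
        t = np.linspace(1e-6, 45.0, 9001)
        v = psp_kernel(t, 9.0)
        assert np.all(np.diff(v[t <= 9.0]) > 0)
        assert np.all(np.diff(v[t >= 9.0]) < 0)
        assert v.max() <= 1.0

    @given(st.floats(0.01, 100.0), st.floats(0.1, 50.0))
    def test_bounded_unit_interval(self, t, tau):
        assert 0.0 <= psp_kernel(t, tau) <= 1.0

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            psp_kernel(1.0, 0.0)


class TestMembranePotential:
    def test_empty_sum_is_zero(self):
        assert membrane_potential([], 5.0, 9.0) == 0.0

    def test_single_synapse_closed_form(self):
        # spike at 1 ms, delay 0.5 ms, weight 2, evaluated at 10 ms
        expected = 2 * (8.5 / 9) * math.exp(1 - 8.5 / 9)
        assert membrane_potential([(1.0, 2.0, 0.5)], 10.0, 9.0) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(1.99680, abs=5e-5)

    def test_duplicate_synapse_doubles(self):
        one = membrane_potential([(1.0, 2.0, 0.5)], 10.0, 9.0)
        two = membrane_potential([(1.0, 2.0, 0.5)] * 2, 10.0, 9.0)
        assert two == pytest.approx(2 * one, abs=1e-12)

    @given(
        st.floats(-5, 5),
        st.floats(-5, 5),
        st.floats(0.1, 3.0),
        st.floats(0.1, 3.0),
    )
    def test_linear_in_weights(self, alpha, beta, w1, w2):
        base = [(0.5, 1.0, 0.2), (1.5, 1.0, 1.0)]
        t, tau = 7.0, 9.0

        def pot(wa, wb):
            return membrane_potential(
                [(base[0][0], wa, base[0][2]), (base[1][0], wb, base[1][2])], t, tau
            )

        mixed = pot(alpha * w1, beta * w2)
        assert mixed == pytest.approx(
            alpha * pot(w1, 0.0) + beta * pot(0.0, w2), rel=1e-9, abs=1e-9
        )


class TestFirstSpike:
    def test_zero_weight_never_fires(self, params):
        assert first_spike_time([(0.0, 0.0, 0.1)], params) is None

    def test_inhibitory_never_fires(self, params):
        assert first_spike_time([(0.0, -5.0, 0.1)], params) is None

    def test_unit_weight_fires_at_tau_peak(self):
        params = SRMParams(tau=9.0, theta=1.0, t_end=20.0, dt=0.01)
        t = first_spike_time([(0.0, 1.0, 0.0)], params, search_from=0.0)
        assert t == pytest.approx(9.00, abs=1e-9)

    def test_matches_fine_grid_oracle_on_random_neurons(self, params):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(120):
            n_syn = int(rng.integers(1, 5))
            imp = [
                (
                    float(rng.uniform(0.01, 9.0)),
                    float(rng.uniform(-10, 10)),
                    float(rng.uniform(0.01, 19.99)),
                )
                for _ in range(n_syn)
            ]
            got = first_spike_time(imp, params)
            want = brute_force_first_spike(imp, params)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert abs(got - want) <= params.dt + 1e-9
            checked += 1
        assert checked == 120

    @given(st.floats(1.01, 50.0), st.floats(1.01, 50.0))
    def test_nonincreasing_in_weight_single_excitatory(self, w_small, w_big):
        params = SRMParams(tau=9.0, theta=1.0, t_end=20.0, dt=0.01)
        lo, hi = sorted([w_small, w_big])
        t_lo = first_spike_time([(0.0, lo, 0.5)], params)
        t_hi = first_spike_time([(0.0, hi, 0.5)], params)
        assert t_lo is not None and t_hi is not None
        assert t_hi <= t_lo


def _chain_topology():
    """1 input -> 1 hidden (w=2, d=0.5) -> output (w=2, d=1.0)."""
    return NetworkTopology(
        n_inputs=1,
        hidden=(
            HiddenNeuronSpec(
                input_synapses=(SynapseSpec(0, 2.0, 0.5),),
                output_synapse=SynapseSpec(0, 2.0, 1.0),
            ),
        ),
    )


class TestSimulateNetwork:
    def test_all_zero_weights_silent(self, params):
        topo = NetworkTopology(
            n_inputs=1,
            hidden=(
                HiddenNeuronSpec(
                    input_synapses=(SynapseSpec(0, 0.0, 0.5),),
                    output_synapse=SynapseSpec(0, 0.0, 1.0),
                ),
            ),
        )
        out, hidden = simulate_network(topo, [0.01], params)
        assert out is None
        assert hidden.times == (None,)

    def test_two_stage_composition_matches_manual(self, params):
        topo = _chain_topology()
        out, hidden = simulate_network(topo, [0.01], params)
        t_h = first_spike_time([(0.01, 2.0, 0.5)], params, search_from=0.0)
        assert hidden.times[0] == t_h
        expected_out = first_spike_time(
            [(t_h, 2.0, 1.0)], params, search_from=params.decision_start
        )
        assert out == expected_out
        assert out is not None and out >= params.decision_start

    def test_dimension_mismatch_raises(self, params):
        with pytest.raises(ValueError):
            simulate_network(_chain_topology(), [0.01, 0.02], params)

    def test_deterministic(self, params):
        topo = _chain_topology()
        a = simulate_network(topo, [3.3], params)
        b = simulate_network(topo, [3.3], params)
        assert a == b

    def test_stronger_chain_never_fires_later(self, params):
        def out_time(scale):
            topo = NetworkTopology(
                n_inputs=1,
                hidden=(
                    HiddenNeuronSpec(
                        input_synapses=(SynapseSpec(0, 2.0 * scale, 0.5),),
                        output_synapse=SynapseSpec(0, 2.0 * scale, 1.0),
                    ),
                ),
            )
            out, _ = simulate_network(topo, [0.01], params)
            return out

        times = [out_time(s) for s in (1.0, 2.0, 5.0, 20.0)]
        assert all(t is not None for t in times)
        assert all(b <= a for a, b in zip(times, times[1:]))

    def test_batch_agrees_with_scalar_path(self, params):
        rng = np.random.default_rng(7)
        n_inputs = 3
        hidden = []
        for _ in range(4):
            syns = tuple(
                SynapseSpec(
                    int(rng.integers(0, n_inputs)),
                    round(float(rng.uniform(-20, 20)), 2),
                    round(float(rng.uniform(0.01, 19.99)), 2),
                )
                for _ in range(int(rng.integers(1, 4)))
            )
            hidden.append(
                HiddenNeuronSpec(
                    input_synapses=syns,
                    output_synapse=SynapseSpec(
                        0,
                        round(float(rng.uniform(-20, 20)), 2),
                        round(float(rng.uniform(0.01, 19.99)), 2),
                    ),
                )
            )
        topo = NetworkTopology(n_inputs=n_inputs, hidden=tuple(hidden))
        spikes = rng.uniform(0.01, 9.0, size=(8, n_inputs))
        out_batch, hid_batch = simulate_batch(topo, spikes, params)
        for p in range(8):
            out, hid = simulate_network(topo, spikes[p], params)
            if out is None:
                assert np.isnan(out_batch[p])
            else:
                assert out_batch[p] == out
            for j, t in enumerate(hid.times):
                if t is None:
                    assert np.isnan(hid_batch[p, j])
                else:
                    assert hid_batch[p, j] == t


class TestTopologyTypesAndJSON:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SynapseSpec(0, 1000.0, 1.0)  # weight out of range
        with pytest.raises(ValueError):
            SynapseSpec(0, 1.0, 0.0)  # delay below minimum
        with pytest.raises(ValueError):
            NetworkTopology(n_inputs=1, hidden=())
        with pytest.raises(ValueError):
            NetworkTopology(
                n_inputs=1,
                hidden=(
                    HiddenNeuronSpec(
                        input_synapses=(SynapseSpec(3, 1.0, 1.0),),
                        output_synapse=SynapseSpec(0, 1.0, 1.0),
                    ),
                ),
            )

    def test_json_round_trip(self):
        topo = _chain_topology()
        assert topology_from_json(topology_to_json(topo)) == topo
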