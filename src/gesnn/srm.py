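"""Spike Response Model (SRM) neurons and three-layer feedforward networks.

The SRM used here is the reduced, single-spike variant common in temporal-coding
work: the membrane potential of a neuron is a weighted, delayed sum of
postsynaptic-potential (PSP) kernels elicited by presynaptic spikes,

    x_j(t) = sum_i  w_ji * eps(t - t_i - d_ji),

and the neuron emits a spike at the first time the potential reaches the firing
threshold ``theta``.  The PSP kernel is the alpha-like form

    eps(t) = (t / tau) * exp(1 - t / tau)   for t > 0,  else 0,

which rises to a maximum of exactly 1 at ``t == tau`` and decays afterwards.
There is no reset or refractory kernel: every neuron fires at most once, which
is all that a time-to-first-spike readout needs.

Potentials are evaluated on a fixed time grid (``dt``, default 0.01 ms — the
same resolution at which synaptic delays are expressed), so spike times are
grid times and simulation is exactly reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SRMParams",
    "SynapseSpec",
    "HiddenNeuronSpec",
    "NetworkTopology",
    "SpikeVector",
    "psp_kernel",
    "membrane_potential",
    "first_spike_time",
    "simulate_network",
    "simulate_batch",
    "topology_to_json",
    "topology_from_json",
]

WEIGHT_MIN, WEIGHT_MAX = -999.99, 999.99
DELAY_MIN, DELAY_MAX = 0.01, 19.99


@dataclass(frozen=True)
class SRMParams:
    """Neuron-model and simulation-window parameters.

    tau
        Membrane time constant (ms); sets the PSP decay time.
    theta
        Firing threshold (mV).
    t_end
        Simulation end time (ms); conventionally the latest class target
        plus 2 ms.
    dt
        Evaluation grid step (ms).
    decision_start
        Earliest admissible spike time (ms) for the *output* neuron.  Hidden
        neurons are always simulated from t = 0 because input spikes arrive
        well before the decision window opens.
    """

    tau: float = 9.0
    theta: float = 1.0
    t_end: float = 20.0
    dt: float = 0.01
    decision_start: float = 10.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not (0 <= self.decision_start < self.t_end):
            raise ValueError(
                f"decision window [{self.decision_start}, {self.t_end}] is empty"
            )

    def time_grid(self) -> np.ndarray:
        """Evaluation grid 0, dt, 2*dt, ..., t_end (inclusive)."""
        n = int(round(self.t_end / self.dt))
        return np.arange(n + 1) * self.dt


@dataclass(frozen=True)
class SynapseSpec:
    """One synaptic connection: presynaptic index, weight, delay (ms)."""

    presyn_id: int
    weight: float
    delay: float

    def __post_init__(self) -> None:
        if self.presyn_id < 0:
            raise ValueError(f"presyn_id must be >= 0, got {self.presyn_id}")
        if not (WEIGHT_MIN <= self.weight <= WEIGHT_MAX):
            raise ValueError(f"weight {self.weight} outside [{WEIGHT_MIN}, {WEIGHT_MAX}]")
        if not (DELAY_MIN <= self.delay <= DELAY_MAX):
            raise ValueError(f"delay {self.delay} outside [{DELAY_MIN}, {DELAY_MAX}]")


@dataclass(frozen=True)
class HiddenNeuronSpec:
    """A hidden neuron: its input synapses and its single output synapse."""

    input_synapses: tuple[SynapseSpec, ...]
    output_synapse: SynapseSpec

    def __post_init__(self) -> None:
        if len(self.input_synapses) < 1:
            raise ValueError("hidden neuron needs at least one input synapse")
        if self.output_synapse.presyn_id != 0:
            raise ValueError("output synapse presyn_id must be 0")


@dataclass(frozen=True)
class NetworkTopology:
    """A designed three-layer feedforward SNN.

    Hidden neurons connect to a (possibly strict) subset of the ``n_inputs``
    input neurons — partial connectivity — and all project onto one output
    neuron.  Weights and delays are fixed by the design; there is no training.
    """

    n_inputs: int
    hidden: tuple[HiddenNeuronSpec, ...]

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if len(self.hidden) < 1:
            raise ValueError("topology needs at least one hidden neuron")
        for h in self.hidden:
            for syn in h.input_synapses:
                if syn.presyn_id >= self.n_inputs:
                    raise ValueError(
                        f"input synapse references neuron {syn.presyn_id} "
                        f"but only {self.n_inputs} inputs exist"
                    )


@dataclass(frozen=True)
class SpikeVector:
    """Per-neuron first-spike times; ``None`` marks a neuron that never fired."""

    times: tuple[Optional[float], ...]

    def fired(self, i: int) -> bool:
        return self.times[i] is not None


def psp_kernel(t, tau: float):
    """PSP kernel eps(t) = (t/tau) e^(1 - t/tau) for t > 0, else 0.

    Accepts scalars or arrays; the result lies in [0, 1] with the maximum 1
    attained exactly at t == tau.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    s = np.asarray(t, dtype=float)
    sc = np.maximum(s, 0.0)  # avoid exp overflow on large negative elapsed times
    out = np.where(s > 0, (sc / tau) * np.exp(1.0 - sc / tau), 0.0)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def membrane_potential(
    impinging: Iterable[tuple[float, float, float]], t, tau: float
):
    """Summed potential sum_i w_i * eps(t - t_i - d_i).

    ``impinging`` is a list of (spike_time, weight, delay) triples; ``t`` may
    be a scalar or an array of evaluation times.  The sum is linear in the
    weights; an empty list yields 0.
    """
    ts = np.asarray(t, dtype=float)
    total = np.zeros_like(ts, dtype=float)
    for spike_time, weight, delay in impinging:
        total += weight * np.asarray(psp_kernel(ts - spike_time - delay, tau))
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(total)
    return total


def first_spike_time(
    impinging: Sequence[tuple[float, float, float]],
    params: SRMParams,
    search_from: float = 0.0,
) -> Optional[float]:
    """Earliest grid time in [search_from, t_end] where the potential >= theta.

    Returns ``None`` (non-firing) when the threshold is never reached.
    """
    if search_from > params.t_end:
        raise ValueError("search_from beyond simulation end")
    grid = params.time_grid()
    grid = grid[grid >= search_from - 1e-12]
    if not impinging:
        return None
    pot = membrane_potential(impinging, grid, params.tau)
    above = pot >= params.theta
    if not above.any():
        return None
    return float(grid[int(np.argmax(above))])


def simulate_network(
    topology: NetworkTopology,
    input_spike_times: Sequence[float],
    params: SRMParams,
) -> tuple[Optional[float], SpikeVector]:
    """Propagate one encoded pattern through the network.

    Hidden neurons receive the input spikes (searched from t = 0); hidden
    neurons that never fire contribute no PSP to the output.  The output
    neuron's first spike is searched from ``params.decision_start``.
    Deterministic: identical inputs give bit-identical outputs.
    """
    if len(input_spike_times) != topology.n_inputs:
        raise ValueError(
            f"pattern has {len(input_spike_times)} features but topology "
            f"expects {topology.n_inputs}"
        )
    hidden_times: list[Optional[float]] = []
    for h in topology.hidden:
        imp = [
            (float(input_spike_times[s.presyn_id]), s.weight, s.delay)
            for s in h.input_synapses
        ]
        hidden_times.append(first_spike_time(imp, params, search_from=0.0))
    out_imp = [
        (t_h, h.output_synapse.weight, h.output_synapse.delay)
        for t_h, h in zip(hidden_times, topology.hidden)
        if t_h is not None
    ]
    output = first_spike_time(out_imp, params, search_from=params.decision_start)
    return output, SpikeVector(times=tuple(hidden_times))


def simulate_batch(
    topology: NetworkTopology,
    spike_matrix: np.ndarray,
    params: SRMParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`simulate_network` over a (P, n_inputs) spike matrix.

    Returns ``(output_times, hidden_times)`` with shapes (P,) and (P, H);
    ``nan`` marks non-firing neurons.  Grid times match the scalar path
    exactly.
    """
    spikes = np.asarray(spike_matrix, dtype=float)
    if spikes.ndim != 2 or spikes.shape[1] != topology.n_inputs:
        raise ValueError(
            f"spike matrix shape {spikes.shape} incompatible with "
            f"{topology.n_inputs} inputs"
        )
    n_patterns = spikes.shape[0]
    grid = params.time_grid()
    tau, theta = params.tau, params.theta

    hidden_times = np.full((n_patterns, len(topology.hidden)), np.nan)
    for j, h in enumerate(topology.hidden):
        pot = np.zeros((n_patterns, grid.size))
        for syn in h.input_synapses:
            s = grid[None, :] - (spikes[:, syn.presyn_id, None] + syn.delay)
            np.maximum(s, 0.0, out=s)
            pot += syn.weight * (s / tau) * np.exp(1.0 - s / tau) * (s > 0)
        above = pot >= theta
        any_fire = above.any(axis=1)
        idx = np.argmax(above, axis=1)
        hidden_times[any_fire, j] = grid[idx[any_fire]]

    out_grid = grid[grid >= params.decision_start - 1e-12]
    pot = np.zeros((n_patterns, out_grid.size))
    for j, h in enumerate(topology.hidden):
        th = hidden_times[:, j]
        fired = ~np.isnan(th)
        if not fired.any():
            continue
        s = out_grid[None, :] - (th[:, None] + h.output_synapse.delay)
        s = np.where(fired[:, None], s, -1.0)
        np.maximum(s, 0.0, out=s)
        pot += h.output_synapse.weight * (s / tau) * np.exp(1.0 - s / tau) * (s > 0)
    above = pot >= theta
    any_fire = above.any(axis=1)
    idx = np.argmax(above, axis=1)
    output_times = np.full(n_patterns, np.nan)
    output_times[any_fire] = out_grid[idx[any_fire]]
    return output_times, hidden_times


def topology_to_json(topology: NetworkTopology) -> str:
    """Serialise a topology to a JSON document (2-decimal weights/delays)."""
    doc = {
        "n_inputs": topology.n_inputs,
        "hidden": [
            {
                "input_synapses": [
                    {
                        "presyn_id": s.presyn_id,
                        "weight": round(s.weight, 2),
                        "delay": round(s.delay, 2),
                    }
                    for s in h.input_synapses
                ],
                "output_synapse": {
                    "weight": round(h.output_synapse.weight, 2),
                    "delay": round(h.output_synapse.delay, 2),
                },
            }
            for h in topology.hidden
        ],
    }
    return json.dumps(doc, indent=2)


def topology_from_json(text: str) -> NetworkTopology:
    """Inverse of :func:`topology_to_json`."""
    doc = json.loads(text)
    hidden = tuple(
        HiddenNeuronSpec(
            input_synapses=tuple(
                SynapseSpec(s["presyn_id"], s["weight"], s["delay"])
                for s in h["input_synapses"]
            ),
            output_synapse=SynapseSpec(
                0, h["output_synapse"]["weight"], h["output_synapse"]["delay"]
            ),
        )
        for h in doc["hidden"]
    )
    return NetworkTopology(n_inputs=doc["n_inputs"], hidden=hidden)
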