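"""Closed-form memory-consumption model and capacity planning.

A distributed spiking-network simulation stores, per MPI process, a base
footprint, the states of its local neurons, and — dominating everything — the
incoming connections of those neurons together with the sparse lookup
infrastructure needed to route presynaptic spikes to them.  With ``N`` neurons
in total, ``K`` incoming connections per neuron, ``M`` processes and ``T``
threads per process, the per-process footprint is modelled as

    M_total(M, T, N, K) = M_0(M) + M_n(M, N) + M_c(M, T, N, K)

with the connection term

    M_c = T*N*m_c0/8  +  T*N_empty*m_c_empty  +  T*(N - N_empty)*m_c_plus
          + (K*N/M)*m_c

where ``m_c0`` (bits) is the per-neuron-per-thread sparse-table overhead,
``m_c_plus``/``m_c_empty`` the per-source infrastructure cost with/without
local targets, and ``m_c`` the bytes of one connection object.  Under random
wiring a neuron has no targets on a given thread with probability
``p_empty = (1 - 1/N)**K_T`` where ``K_T = N*K/(M*T)`` is the per-thread
synapse count, giving the expected ``N_empty = p_empty * N``.

The terms proportional to ``T*N`` are *serial overhead*: they grow with the
total network on every process regardless of how many processes share the
work, and ultimately cap the reachable network size.  The planning helpers
(:func:`max_network_size`, :func:`min_machine_size`, :func:`max_filling_curve`)
invert the model for machine-sizing questions, and the communication-load
helpers estimate the per-interval spike-exchange buffers of the collective
all-gather scheme.

All MB/GB figures in this module are decimal (1e6 / 1e9 bytes).  The planning
formulas treat N/M and N/(M*T) as real numbers (the model is continuous); the
simulator's integer round-robin partition differs by at most one neuron per
virtual process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "NetworkSpec",
    "MachineSpec",
    "MemoryParams",
    "MemoryBreakdown",
    "CommLoadSpec",
    "CapacityError",
    "prob_no_local_targets",
    "memory_breakdown",
    "max_network_size",
    "min_machine_size",
    "events_per_comm_step",
    "spike_buffer_bytes",
    "buffer_memory_fraction",
    "max_filling_curve",
]


class CapacityError(ValueError):
    """A planning request that no machine/network configuration can satisfy."""


@dataclass(frozen=True)
class NetworkSpec:
    """Network size description: ``N`` neurons, each with fixed in-degrees."""

    N: int
    K_E: int = 0
    K_I: int = 0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.K_E < 0 or self.K_I < 0:
            raise ValueError("in-degrees must be nonnegative")

    @property
    def K(self) -> int:
        """Total in-degree per neuron."""
        return self.K_E + self.K_I


@dataclass(frozen=True)
class MachineSpec:
    """Emulated machine: ``M`` processes (one per node) x ``T`` threads."""

    M: int
    T: int
    mem_per_node: float = 0.0  # usable bytes per node; 0 = unspecified

    def __post_init__(self):
        if self.M < 1 or self.T < 1:
            raise ValueError("M and T must be >= 1")
        if self.mem_per_node < 0:
            raise ValueError("mem_per_node must be nonnegative")


@dataclass(frozen=True)
class MemoryParams:
    """Per-object byte/bit costs instantiating the memory model.

    Connection-side defaults (``m_c`` = 48 B, ``m_c_plus`` = 136 B,
    ``m_c0`` = 2.67 bit, ``m_c_empty`` = 0 B) are the published double-precision
    connection-object costs for the modelled production simulator.  ``m_n``
    defaults to 1000 B — the typical per-neuron state storage.  ``m_n0`` and
    ``m_base`` default to 0, measured from this implementation: neuron locality
    here is round-robin arithmetic (no serial per-neuron table) and the
    emulator has no per-process base footprint worth modelling.  Override them
    when planning for a real simulator.

    m_c0 and m_n0 are carried in *bits* and divided by 8 exactly when summed.
    """

    m_c: float = 48.0  # bytes per connection object
    m_c_plus: float = 136.0  # bytes per source with local targets
    m_c_empty: float = 0.0  # bytes per source without local targets
    m_c0: float = 2.67  # bits per neuron per thread (sparse-table entry)
    m_n: float = 1000.0  # bytes per local neuron state
    m_n0: float = 0.0  # bits per neuron, serial neuron infrastructure
    m_base: float = 0.0  # bytes, base footprint per process

    def __post_init__(self):
        for name in ("m_c", "m_c_plus", "m_c_empty", "m_c0", "m_n", "m_n0", "m_base"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class MemoryBreakdown:
    """Per-process memory components, reported separately and summed."""

    N_M: float  # neurons per process
    K_M: float  # synapses per process
    N_T: float  # neurons per thread
    K_T: float  # synapses per thread
    p_empty: float
    N_c_empty: float  # expected sources without local targets, per thread
    bytes_base: float
    bytes_neurons: float
    bytes_connections: float

    @property
    def bytes_total(self) -> float:
        return self.bytes_base + self.bytes_neurons + self.bytes_connections


@dataclass(frozen=True)
class CommLoadSpec:
    """Inputs to the spike-communication-buffer estimate."""

    N_T_core: float  # neurons per core
    rate: float  # mean firing rate per neuron (1/s)
    min_delay: float  # global minimal synaptic delay (s)
    n_cores: int = 0
    bytes_per_gid: float = 4.0

    def __post_init__(self):
        if min(self.N_T_core, self.rate, self.min_delay, self.n_cores, self.bytes_per_gid) < 0:
            raise ValueError("all communication-load fields must be nonnegative")


def prob_no_local_targets(N: float, K_T: float) -> float:
    """Probability that a neuron has no targets on a given thread.

    ``(1 - 1/N)**K_T`` for ``K_T`` independent uniform source draws from ``N``
    neurons; evaluated as ``exp(K_T * log1p(-1/N))`` so it stays accurate for
    N as large as 1e8 and beyond.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if K_T < 0:
        raise ValueError("K_T must be nonnegative")
    if K_T == 0:
        return 1.0
    if N == 1:
        return 0.0  # every draw hits the single neuron
    return math.exp(K_T * math.log1p(-1.0 / N))


def memory_breakdown(
    net: NetworkSpec, machine: MachineSpec, params: MemoryParams = MemoryParams()
) -> MemoryBreakdown:
    """Evaluate the per-process memory model for a network on a machine."""
    N, K = float(net.N), float(net.K)
    M, T = machine.M, machine.T
    N_M = N / M
    K_M = N_M * K
    N_T = N_M / T
    K_T = N_T * K
    p_empty = prob_no_local_targets(N, K_T)
    N_c_empty = p_empty * N
    bytes_connections = (
        T * N * params.m_c0 / 8.0
        + T * N_c_empty * params.m_c_empty
        + T * (N - N_c_empty) * params.m_c_plus
        + K_M * params.m_c
    )
    bytes_neurons = N_M * params.m_n + N * params.m_n0 / 8.0
    return MemoryBreakdown(
        N_M=N_M,
        K_M=K_M,
        N_T=N_T,
        K_T=K_T,
        p_empty=p_empty,
        N_c_empty=N_c_empty,
        bytes_base=params.m_base,
        bytes_neurons=bytes_neurons,
        bytes_connections=bytes_connections,
    )


def _total_bytes(N: int, K: int, machine: MachineSpec, params: MemoryParams) -> float:
    return memory_breakdown(NetworkSpec(N, K_E=K), machine, params).bytes_total


def max_network_size(
    machine: MachineSpec,
    K: int,
    params: MemoryParams = MemoryParams(),
    budget: float | None = None,
) -> int:
    """Largest N whose per-process footprint fits the per-node budget.

    Found by bisection on the (monotonically nondecreasing) total; the result
    satisfies ``bytes_total(N) <= budget < bytes_total(N + 1)``.
    """
    if budget is None:
        budget = machine.mem_per_node
    if budget <= params.m_base:
        raise CapacityError("no capacity: budget does not exceed the base footprint")
    if _total_bytes(1, K, machine, params) > budget:
        raise CapacityError("no capacity: even a single neuron exceeds the budget")
    lo, hi = 1, 2
    while _total_bytes(hi, K, machine, params) <= budget:
        lo = hi
        hi *= 2
    # invariant: lo feasible, hi infeasible
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _total_bytes(mid, K, machine, params) <= budget:
            lo = mid
        else:
            hi = mid
    return lo


def min_machine_size(
    N: int,
    K: int,
    T: int,
    mem_per_node: float,
    params: MemoryParams = MemoryParams(),
) -> int:
    """Smallest number of nodes M on which the network fits.

    Uses the monotone decrease of the per-process total in M.  The serial
    overhead terms (proportional to N on every process) set the M -> infinity
    floor; if that floor alone exceeds the node memory, no machine size helps.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    serial_floor = (
        params.m_base
        + N * params.m_n0 / 8.0
        + T * N * params.m_c0 / 8.0
        + T * N * params.m_c_empty
    )
    if serial_floor >= mem_per_node:
        raise CapacityError("serial overhead exceeds node memory at any machine size")

    def fits(M: int) -> bool:
        return _total_bytes(N, K, MachineSpec(M, T), params) <= mem_per_node

    if fits(1):
        return 1
    lo, hi = 1, 2
    while not fits(hi):
        lo = hi
        hi *= 2
    # invariant: lo infeasible, hi feasible
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fits(mid):
            hi = mid
        else:
            lo = mid
    return hi


def events_per_comm_step(load: CommLoadSpec) -> float:
    """Expected spikes produced per core per communication interval.

    Spikes are exchanged once per global-minimal-delay interval, so each core
    contributes ``N_T_core * rate * min_delay`` events on average.
    """
    return load.N_T_core * load.rate * load.min_delay


def spike_buffer_bytes(load: CommLoadSpec) -> float:
    """Bytes of spike-receive buffer per node and interval.

    Under collective all-gather exchange every node stores every event, at
    ``bytes_per_gid`` bytes per communicated global id.
    """
    return events_per_comm_step(load) * load.n_cores * load.bytes_per_gid


def buffer_memory_fraction(load: CommLoadSpec, node_memory_bytes: float) -> float:
    """Spike buffer as a fraction of a node's working memory."""
    if node_memory_bytes <= 0:
        raise ValueError("node_memory_bytes must be positive")
    return spike_buffer_bytes(load) / node_memory_bytes


def max_filling_curve(
    machine_sizes: list[int],
    T: int,
    K: int,
    params: MemoryParams = MemoryParams(),
    budget: float = 0.0,
) -> pd.DataFrame:
    """Maximum-filling table: for each machine size, the largest fitting network.

    With any serial overhead present the affordable neurons per core decline
    (approximately logarithmically) with machine size; with none, the curve is
    flat (perfect weak scaling).

    Parameters
    ----------
    machine_sizes
        Strictly increasing node counts M.
    budget
        Usable bytes per node.

    Returns
    -------
    DataFrame with one row per machine size: ``nodes``, ``cores``, ``n_max``,
    ``n_per_core``, ``predicted_bytes`` (per-process total at ``n_max``).
    """
    if not machine_sizes:
        raise ValueError("machine_sizes must be nonempty")
    if list(machine_sizes) != sorted(set(machine_sizes)):
        raise ValueError("machine_sizes must be strictly increasing")
    rows = []
    for M in machine_sizes:
        machine = MachineSpec(M, T)
        n_max = max_network_size(machine, K, params, budget)
        rows.append(
            {
                "nodes": M,
                "cores": M * T,
                "n_max": n_max,
                "n_per_core": n_max / (M * T),
                "predicted_bytes": _total_bytes(n_max, K, machine, params),
            }
        )
    return pd.DataFrame(rows)
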