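"""Emulated multi-process / multi-thread execution.

The network is distributed over ``n_vp = M * T`` *virtual processes* (VPs):
process index times threads plus thread index.  Neurons are assigned
round-robin (``vp = gid mod n_vp``), which balances load to within one neuron
per VP.  The VPs are executed sequentially inside one OS process — what is
emulated, and tested, is the ownership contract (who owns which neuron, which
connections, which random draws) rather than actual concurrency.

The simulation advances in communication blocks of the global minimal
synaptic delay: within a block every VP updates its neurons time-driven and
collects the spikes they emit; at the block boundary all emitted global ids
are concatenated and made visible to every VP (the stand-in for a collective
all-gather).  Each VP then filters the stream through its sparse-table
occupancy bits, discards spikes without local targets, applies the
event-driven plasticity update for plastic synapses, and enqueues the
synaptic weights into the targets' ring buffers at emission step plus delay.

Because wiring and Poisson input come from keyed counter-style streams
(:mod:`spikescale.rng`), connectivity, spike records and final weights are
bit-identical for every factorization (M, T) of the same ``n_vp`` — and, by
construction, even across different ``n_vp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from . import rng
from .connection_store import SparseConnectionTable, serialize_edges
from .kernel import (
    LIFParams,
    RingBufferArray,
    STDPParams,
    SpikeHistory,
    make_propagator,
    poisson_input_array,
    stdp_on_presyn_spike,
    update_population,
)
from .memory_model import MemoryParams, NetworkSpec

if TYPE_CHECKING:  # pragma: no cover
    from .benchmark import BenchmarkConfig

__all__ = [
    "VPGrid",
    "SpikeEvent",
    "ExchangeStats",
    "SimResult",
    "vp_of_gid",
    "wire_network",
    "exchange_and_deliver",
    "run_simulation",
]


@dataclass(frozen=True)
class VPGrid:
    """M processes x T threads; VP index = process * T + thread."""

    M: int
    T: int
    seed: int = 0

    def __post_init__(self):
        if self.M < 1 or self.T < 1:
            raise ValueError("M and T must be >= 1")

    @property
    def n_vp(self) -> int:
        return self.M * self.T

    def process_of_vp(self, vp: int) -> int:
        return vp // self.T

    def thread_of_vp(self, vp: int) -> int:
        return vp % self.T


def vp_of_gid(gid: int, grid: VPGrid) -> int:
    """Round-robin owner VP of a neuron; deterministic and stateless."""
    if gid < 0:
        raise ValueError("gid must be nonnegative")
    return gid % grid.n_vp


@dataclass(frozen=True, order=True)
class SpikeEvent:
    """A spike identified by emitting neuron and integer emission step."""

    step: int
    gid: int

    def __post_init__(self):
        if self.gid < 0 or self.step < 0:
            raise ValueError("gid and step must be nonnegative")


@dataclass
class ExchangeStats:
    """Bookkeeping of one (or accumulated) spike-exchange round."""

    received_per_vp: int = 0  # every VP sees every event (all-gather contract)
    discarded: int = 0  # (vp, event) pairs filtered out by the occupancy bit
    deliveries: int = 0  # ring-buffer additions
    delivered_weight: float = 0.0
    comm_bytes_per_vp: float = 0.0  # events * bytes_per_gid

    def accumulate(self, other: "ExchangeStats") -> None:
        self.received_per_vp += other.received_per_vp
        self.discarded += other.discarded
        self.deliveries += other.deliveries
        self.delivered_weight += other.delivered_weight
        self.comm_bytes_per_vp += other.comm_bytes_per_vp


def wire_network(
    net: NetworkSpec,
    grid: VPGrid,
    seed: int,
    *,
    n_excit: int | None = None,
    weight_exc: float = 1.0,
    weight_inh: float = -1.0,
    delay_steps: int = 15,
    stdp_exc_exc: bool = False,
) -> list[SparseConnectionTable]:
    """Wire a random network with fixed in-degrees, one table per process.

    Every target neuron receives exactly ``net.K_E`` sources drawn uniformly
    *with replacement* from the excitatory pool ``[0, n_excit)`` and ``net.K_I``
    from the inhibitory pool ``[n_excit, N)`` (multapses and autapses are
    permitted; the with-replacement choice is what makes the occupancy
    probability ``(1 - 1/N)**K_T`` exact).  Draws are keyed by
    ``(seed, target gid, draw index)``, so the resulting edge multiset does not
    depend on the machine decomposition.  Each connection is stored on the
    process and thread owning its target.
    """
    N = net.N
    if n_excit is None:
        n_excit = N if net.K_I == 0 else int(round(0.8 * N))
    if not 0 <= n_excit <= N:
        raise ValueError("n_excit must lie in [0, N]")
    if net.K_E > 0 and n_excit < 1:
        raise ValueError("excitatory pool is empty but K_E > 0")
    if net.K_I > 0 and N - n_excit < 1:
        raise ValueError("inhibitory pool is empty but K_I > 0")

    n_vp = grid.n_vp
    tables = [
        SparseConnectionTable(
            N,
            grid.T,
            locality=lambda thread, gid, p=p: gid % n_vp == p * grid.T + thread,
        )
        for p in range(grid.M)
    ]
    idx_exc = np.arange(net.K_E)
    idx_inh = np.arange(net.K_E, net.K_E + net.K_I)
    for gid in range(N):
        vp = gid % n_vp
        p, t = vp // grid.T, vp % grid.T
        table = tables[p]
        target_is_exc = gid < n_excit
        if net.K_E:
            sources = rng.keyed_randint(n_excit, seed, rng.PURPOSE_WIRING, gid, idx_exc)
            syn_type = "stdp" if (stdp_exc_exc and target_is_exc) else "static"
            for src in sources:
                table.add_connection(
                    t, int(src), gid, syn_type, weight=weight_exc, delay_steps=delay_steps
                )
        if net.K_I:
            draws = rng.keyed_randint(N - n_excit, seed, rng.PURPOSE_WIRING, gid, idx_inh)
            for src in draws:
                table.add_connection(
                    t, n_excit + int(src), gid, "static", weight=weight_inh, delay_steps=delay_steps
                )
    return tables


def exchange_and_deliver(
    events: list[SpikeEvent],
    tables: list[SparseConnectionTable],
    buffers: list[RingBufferArray],
    grid: VPGrid,
    *,
    histories: list[SpikeHistory | None] | None = None,
    stdp_params: STDPParams | None = None,
    h: float = 0.1,
    step_window: tuple[int, int] | None = None,
    bytes_per_gid: float = 4.0,
) -> ExchangeStats:
    """Broadcast emitted spikes to all VPs and enqueue them at their targets.

    Every VP receives the full concatenated event list; the per-VP occupancy
    bit decides in O(1) whether an event has local targets, and misses are
    discarded.  Plastic synapses are advanced by :func:`stdp_on_presyn_spike`
    before their (updated) weight is enqueued; the targets' ring buffers
    accumulate at ``emission step + delay_steps``.

    Events are processed in (step, gid) order within each VP, which fixes the
    floating-point summation order per target neuron independently of the
    decomposition.
    """
    if step_window is not None:
        lo, hi = step_window
        for ev in events:
            if not lo <= ev.step < hi:
                raise ValueError(f"event step {ev.step} outside current interval [{lo}, {hi})")
    events = sorted(events)
    n_vp = grid.n_vp
    stats = ExchangeStats(
        received_per_vp=len(events),
        comm_bytes_per_vp=len(events) * bytes_per_gid,
    )
    for p, table in enumerate(tables):
        for t in range(table.n_threads):
            vp = p * grid.T + t
            buf = buffers[vp]
            for ev in events:
                if not table.has_local_targets(t, ev.gid):
                    stats.discarded += 1
                    continue
                t_pre = ev.step * h
                for syn_type, records in table.targets_of(t, ev.gid).items():
                    plastic = syn_type == "stdp" and stdp_params is not None
                    for rec in records:
                        if plastic:
                            post = histories[rec.target] if histories else None
                            if post is not None:
                                stdp_on_presyn_spike(rec, t_pre, post, stdp_params)
                        buf.enqueue(rec.target // n_vp, rec.weight, rec.delay_steps, ev.step)
                        stats.deliveries += 1
                        stats.delivered_weight += rec.weight
    return stats


@dataclass
class SimResult:
    """Outcome of a benchmark simulation."""

    spikes: list[tuple[int, int]]  # (step, gid), sorted
    tables: list[SparseConnectionTable]
    grid: VPGrid
    h: float  # ms
    n_steps: int
    exchange_stats: ExchangeStats
    n_exchanges: int

    def spike_text(self) -> str:
        """gdf-style record: one ``gid<TAB>time_ms`` line per spike, sorted."""
        lines = [f"{gid}\t{step * self.h:.4f}" for step, gid in self.spikes]
        return "\n".join(lines) + ("\n" if lines else "")

    def weights_text(self) -> str:
        """Canonical sorted edge list including final weights."""
        return serialize_edges(self.tables)

    def memory_reports(self, params: MemoryParams = MemoryParams()):
        return [t.memory_report(params) for t in self.tables]


def run_simulation(config: "BenchmarkConfig") -> SimResult:
    """Build and run a benchmark network; see :mod:`spikescale.benchmark`.

    Loops over min-delay blocks: per-VP time-driven neuron updates with keyed
    Poisson drive, then a collective exchange with event-driven plasticity.
    The spike record is sorted by (step, gid); rerunning with the same config
    reproduces it bit for bit.
    """
    from .benchmark import build_benchmark  # local import; benchmark builds on this module

    built = build_benchmark(config)
    net, grid, tables = built.net, built.grid, built.tables
    lif: LIFParams = config.lif_params()
    stdp: STDPParams = config.stdp_params()
    prop = make_propagator(lif)
    h = config.h_ms
    interval = round(config.min_delay_ms / h)
    n_steps = round(config.t_sim_ms / h)
    delay_steps = round(config.delay_ms / h)
    n_vp = grid.n_vp

    local_gids = [np.arange(vp, net.N, n_vp) for vp in range(n_vp)]
    V = [np.full(len(g), lif.E_L) for g in local_gids]
    I = [np.zeros(len(g)) for g in local_gids]
    refr = [np.zeros(len(g), dtype=np.int64) for g in local_gids]
    buffers = [RingBufferArray(len(g), delay_steps) for g in local_gids]
    histories: list[SpikeHistory | None] = [None] * net.N
    for g in range(net.N):
        histories[g] = SpikeHistory()

    spikes: list[tuple[int, int]] = []
    pending: list[SpikeEvent] = []
    totals = ExchangeStats()
    n_exchanges = 0

    def do_exchange(evts: list[SpikeEvent], window: tuple[int, int]) -> None:
        nonlocal n_exchanges
        st = exchange_and_deliver(
            evts,
            tables,
            buffers,
            grid,
            histories=histories,
            stdp_params=stdp,
            h=h,
            step_window=window,
        )
        totals.accumulate(st)
        n_exchanges += 1

    prev_window = (0, 0)
    for block_start in range(0, n_steps, interval):
        block_end = min(block_start + interval, n_steps)
        if pending or block_start:
            do_exchange(pending, prev_window)
        pending = []
        for vp in range(n_vp):
            gids = local_gids[vp]
            if len(gids) == 0:
                continue
            for step in range(block_start, block_end):
                drive = np.zeros(len(gids))
                if config.nu_ext > 0 and config.weight_ext != 0.0:
                    counts = poisson_input_array(gids, step, config.nu_ext, config.seed, h)
                    drive = counts * config.weight_ext
                ring_input = buffers[vp].read(step) + drive
                spiked = update_population(V[vp], I[vp], refr[vp], ring_input, lif, prop)
                if spiked.any():
                    t_ms = step * h
                    for gid in gids[spiked]:
                        gid = int(gid)
                        histories[gid].append(t_ms)
                        pending.append(SpikeEvent(step, gid))
                        spikes.append((step, gid))
        prev_window = (block_start, block_end)
    if pending:
        do_exchange(pending, prev_window)  # final flush keeps plasticity current

    spikes.sort()
    return SimResult(
        spikes=spikes,
        tables=tables,
        grid=grid,
        h=h,
        n_steps=n_steps,
        exchange_stats=totals,
        n_exchanges=n_exchanges,
    )
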