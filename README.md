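# spikescale

Memory planning and desk-scale verification for distributed spiking-network
simulation.

Simulations of networks with 10⁷–10⁸ leaky integrate-and-fire (LIF) neurons
and ~10⁴ synapses per neuron are feasible on large clusters, but whether a
given simulation *fits* is decided by memory, not FLOPs: synapses dominate,
and some data structures grow with the total network size `N` on every node
("serial overhead"), no matter how many nodes share the work.  `spikescale`
gives researchers and simulator developers two coupled tools:

1. **A closed-form memory model and capacity planner.**  Per process
   (M processes × T threads),

       M_total = m_base + (N/M)·m_n + N·m_n0/8
                 + T·N·m_c0/8 + T·N_∅·m_c∅ + T·(N−N_∅)·m_c+ + (K·N/M)·m_c

   where `N_∅ = N·(1 − 1/N)^{K_T}` is the expected number of source neurons
   without targets on a thread holding `K_T = N·K/(M·T)` synapses.  From this
   the planner answers: the largest network a machine fits
   (`max_network_size`), the smallest machine a network needs
   (`min_machine_size`), maximum-filling curves, and per-interval
   spike-communication buffer sizes.

2. **An emulated distributed simulator** whose data structures are exactly
   what the model prices: thread-partitioned sparse connection tables with
   bit-field occupancy, an exact-integration LIF kernel with ring-buffer
   delays, event-driven spike-timing-dependent plasticity (STDP) driven by
   postsynaptic spike histories, and collective spike exchange every
   minimal-delay interval across `M × T` virtual processes.  Wiring and
   Poisson drive come from counter-style keyed random streams, so spike
   records and final weights are **bit-identical for every factorization
   (M, T)** of the same virtual-process count.

## Worked example

How many neurons fit a 2048-core machine with 4 threads per node and 1.84 GB
usable per node, at 11,250 synapses per neuron?

```python
from spikescale import MachineSpec, MemoryParams, max_network_size

n = max_network_size(MachineSpec(M=512, T=4), K=11250,
                     params=MemoryParams(), budget=1.84e9)
print(n)        # 1150188
```

About 1.15 million neurons — the per-node budget is almost entirely consumed
by the `(K·N/M)·m_c` connection-object term plus the per-source overheads.
And the spike traffic such a machine must absorb per communication interval
(`python examples/communication_load.py`):

```
events per core per interval : 20.7
buffer per node per interval : 8.15 MB (2.0 M events network-wide)
fraction of a 16 GB node     : 0.051 %
```

2000 neurons per core firing at 6.9/s over a 1.5 ms interval give ~20.7
events per core; all-gathered over ~10⁵ cores that is ~8 MB per node —
memory pressure comes from connections, not communication.

Running the plastic benchmark network and checking the reproducibility
contract (`python examples/verify_invariance.py`):

```
grid 1x4:   339 spikes, 8501 deliveries -> reference
grid 2x2:   339 spikes, 8501 deliveries -> identical
grid 4x1:   339 spikes, 8501 deliveries -> identical
```

The other scripts in `examples/` walk through memory accounting of a wired
network against the model (`build_and_report.py`), rate measurement of the
benchmark (`simulate_benchmark.py`), and machine sizing
(`plan_capacity.py`).

## Command line

A thin CLI wraps the library for shell use:

```sh
spikescale capacity -m 512 -t 4 -k 11250 --budget-gb 1.84
spikescale machine -n 10000000 -k 11250 -t 8 --node-gb 13.85
spikescale curve --nodes 1024,2048,4096 -t 8 -k 11250 --budget-gb 13.85
spikescale commload
spikescale build --config bench.yaml
spikescale simulate --config bench.yaml --out-spikes run.gdf
spikescale verify-invariance --config bench.yaml
```

Configurations are YAML files (see `spikescale.BenchmarkConfig`); spike files
are plain text, one `gid<TAB>time_ms` per line.

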