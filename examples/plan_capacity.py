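"""How large a network fits a machine — and how small a machine a network needs.

The memory model sums, per process: a base footprint, neuron state, and the
connection infrastructure (sparse-table bits, per-source overhead, connection
objects).  Terms proportional to the total network size N are "serial
overhead": they recur on every node and eventually dominate.
"""

from spikescale import (
    MachineSpec,
    MemoryParams,
    NetworkSpec,
    max_filling_curve,
    max_network_size,
    memory_breakdown,
    min_machine_size,
)

K = 11250  # incoming synapses per neuron (production benchmark)
params = MemoryParams()  # published connection costs; 1000 B neuron state

# A 2048-core machine: 512 nodes x 4 threads, 1.84 GB usable per node.
machine = MachineSpec(M=512, T=4, mem_per_node=1.84e9)
n_max = max_network_size(machine, K, params)
bd = memory_breakdown(NetworkSpec(n_max, K_E=K), machine, params)
print(f"max network on 512x4 nodes @ 1.84 GB : {n_max:,} neurons")
print(f"  per-process total {bd.bytes_total / 1e9:.3f} GB "
      f"(connections {bd.bytes_connections / 1e9:.3f} GB, "
      f"neurons {bd.bytes_neurons / 1e6:.1f} MB)")

# The inverse question, for a 16-core-per-node machine with 13.85 GB usable.
n_target = 10_000_000
m_min = min_machine_size(n_target, K, T=8, mem_per_node=13.85e9, params=params)
print(f"\n{n_target:,} neurons at K={K} need >= {m_min:,} nodes ({8 * m_min:,} cores)")

# Maximum filling over growing machines: neurons per core declines because
# the sparse tables grow with total N on every node.
print("\nmaximum-filling curve (13.85 GB nodes, 8 threads):")
df = max_filling_curve([1024, 2048, 4096, 8192], T=8, K=K, params=params, budget=13.85e9)
print(df.to_string(index=False))
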