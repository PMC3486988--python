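# Methods

## Scope and model

`spikescale` addresses a planning-and-verification problem from large-scale
spiking-network simulation: before requesting time on a big machine, a
researcher needs to know how much memory a network of `N` leaky
integrate-and-fire (LIF) neurons with `K` incoming synapses each will consume
per node, and conversely how large a network a given machine can hold.  The
package pairs a closed-form memory model with a small but faithful simulator
whose data structures realize exactly what the model prices, so every model
term can be checked against a structure the package itself builds.

Distribution is *emulated*: `n_vp = M × T` virtual processes (M processes ×
T threads) run sequentially in one OS process.  What is preserved — and
tested — is the ownership contract: which VP owns which neuron (round-robin,
`gid mod n_vp`), which connections it stores (those of its local targets),
which random draws belong to it, and what every VP sees at a spike exchange.
Actual MPI/threads, network topology and wall-clock performance are out of
scope.

## Memory model

Per-process consumption is modelled as `M_total = M_0 + M_n + M_c`:

- `M_0 = m_base` — base footprint (code, libraries, communicator state).
- `M_n = (N/M)·m_n + N·m_n0/8` — neuron state plus serial per-neuron
  infrastructure.
- `M_c = T·N·m_c0/8 + T·N_∅·m_c∅ + T·(N−N_∅)·m_c+ + (K·N/M)·m_c` — the
  connection side: per-thread sparse-table bits over all N sources,
  per-source infrastructure for sources with/without local targets, and the
  connection objects themselves.

Under uniform random wiring with replacement, a source has no targets on a
thread holding `K_T = N·K/(M·T)` synapses with probability
`p_∅ = (1 − 1/N)^{K_T}` (evaluated as `exp(K_T·log1p(−1/N))` for numerical
stability at large N), giving `N_∅ = p_∅·N`.

Parameter defaults, with units and provenance:

| parameter | default | meaning | provenance |
|---|---|---|---|
| `m_c` | 48 B | one connection object (double precision) | published cost of the modelled production simulator |
| `m_c_plus` | 136 B | per-source infrastructure when targets exist | same |
| `m_c0` | 2.67 bit | sparse-table cost per neuron per thread | same |
| `m_c_empty` | 0 B | per-source cost without targets | same |
| `m_n` | 1000 B | neuron state | typical LIF state-variable storage |
| `m_n0` | 0 bit | serial neuron infrastructure | measured from this implementation (locality is round-robin arithmetic; no per-neuron table) |
| `m_base` | 0 B | process base footprint | measured from this implementation (negligible at desk scale) |

`m_n0`/`m_base` must be overridden when planning for a real simulator; they
are deliberately not silently mixed with the published connection costs.

Numerical conventions: bit-valued parameters are divided by 8 exactly when
summed (no rounding to whole bytes, preserving the 2.67-bit granularity);
MB/GB are decimal (1e6/1e9) everywhere; planning formulas use real-valued
`N/M` and `N/(M·T)` (the model is continuous), whereas the simulator uses the
exact integer round-robin partition — a model-vs-implementation distinction
that matters by at most one neuron per VP.  `p_∅` is degenerate at `N = 1`
(`0` for any positive draw count), so monotonicity of the total in N is
claimed from `N ≥ 2`.

The capacity solvers bracket by doubling and bisect on the monotone total;
`max_network_size` returns the unique N with
`bytes(N) ≤ budget < bytes(N+1)`, `min_machine_size` the smallest feasible M.
`min_machine_size` first checks the `M → ∞` floor (the serial terms); if that
alone exceeds node memory it raises — the scaling limit serial overhead
imposes.  Both are tested against exhaustive linear scans for `N ≤ 1e4`,
`M ≤ 64`.

Communication load: with spikes exchanged once per global-minimal-delay
interval `min(d)`, a core holding `N_T` neurons firing at rate `ν` produces
`N_T·ν·min(d)` events per interval; an all-gather makes every node buffer
every event at `bytes_per_gid` (default 4 B).  At maximum filling
(`N_T = 2000`, `ν = 6.9/s`, `min(d) = 1.5 ms`, 98,394 cores) this is 20.7
events/core and ≈8.1 MB per node — about 0.05% of a 16 GB node, which is why
connection storage, not spike traffic, determines machine size.

## Connection store

Per process, a vector of `T` sparse occupancy tables over the global source
index space: groups of 48 entries, one bit per entry ("does source j have a
target on this thread?"), and for set bits per-synapse-type homogeneous
record vectors (`static`, `stdp`).  The bit answers the spike-filtering
question in O(1) without touching target lists.  Accounting is analytic
(counts × unit costs): the per-entry cost `m_c0` decomposes exactly as 1 bit
of bit-field plus `(m_c0 − 1)·48` bits of per-group overhead, so for N a
multiple of 48 the realized report equals the model formula with realized
occupancy substituted — the tests exploit this identity.  RSS probing is
deliberately avoided: it folds in allocator and OS behaviour the model does
not describe.

Connection records store weight/delay/plasticity state in double precision.
Deletion and open-addressing internals of production sparse tables are out of
scope.

## Kernel

Subthreshold dynamics (exponential postsynaptic currents, chosen so the
linear system has a 2-state exact propagator):

    tau_syn dI/dt = −I
    tau_m dV/dt = −(V − E_L) + (tau_m/C_m)·I

One step of length `h` (default 0.1 ms) is advanced by the closed-form matrix
exponential; grid values match the analytic solution to < 1e-10 over hundreds
of steps ("exact integration" — there is no step-size convergence question).
`tau_m = tau_syn` makes the propagator degenerate and is rejected rather than
special-cased.

Fixed update order per step: propagate → add the consumed ring-buffer slot to
the synaptic current → threshold test on V → on spike: reset, start
`t_ref/h` refractory steps.  Input summed at step t therefore first moves V
at t+1.  During refractoriness V is clamped to `V_reset` while I continues to
evolve and accumulate.  Delays are quantized in steps; each neuron's ring
buffer has `max_delay + 1` slots and the slot read for the current step is
zeroed after consumption.

### Plasticity

Excitatory-to-excitatory synapses follow an all-to-all, trace-based pairing
rule, updated only at presynaptic spikes (event-driven) from the target's
spike history:

- potentiation per (pre, post) pair, Δt = t_post − t_pre > 0:
  `Δw = λ · w0^{1−μ} · w^μ · exp(−Δt/τ+)`
- depression per (post, pre) pair, Δt = t_pre − t_post > 0:
  `Δw = −λ · α · w · exp(−Δt/τ−)`

with τ+ = 15 ms, τ− = 30 ms, λ = 0.1, μ = 0.4, α = 0.0513 by default and
`w0` set to the initial E→E weight (dimensional consistency of the power
law; configurable).  Tie-break: simultaneous pre/post spikes pair in neither
direction; within one update, potentiations are applied in time order before
the triggering depression; weights clip at 0 from below (once per update).
The synapse keeps its presynaptic trace incrementally (`kplus`,
`last_update`), so splitting the update across presynaptic spikes reproduces
a single time-ordered pass exactly — verified against a brute-force all-pairs
oracle to < 1e-12 relative error.  The precise functional form (in
particular weight-proportional depression) is this package's documented
choice among the standard trace-based variants; updates use emission times
(no separate dendritic-delay bookkeeping), and the weight seen by the target
is the post-update weight.

### External drive

Per neuron and step, a Poisson count with mean `rate·h` drawn by exact CDF
inversion of one keyed uniform.  Keys are `(seed, purpose, gid, step)` words
mixed by the splitmix64 finalizer (vectorized over uint64 arrays), making
every draw a pure function of its key: independent of machine decomposition
and of any other draw's existence.  The same construction keys wiring by
`(seed, target gid, draw index)`.  This is stronger than the conventional
discipline of equal variate counts per stateful generator — invariance holds
by construction, even across different `n_vp`.

## Simulation loop and exchange

Time advances in blocks of `min_delay/h` steps (delays must be ≥ the
interval, so deliveries never land in the current block).  Per block: each VP
updates its neurons vectorized over steps' local populations and collects
emissions; at the boundary all events are concatenated, sorted by
(step, gid), and every VP filters them through its occupancy bits, advances
plastic synapses, and enqueues weights at `emission step + delay`.  The fixed
global event order pins the floating-point summation order per target, which
is what makes spike records *bit*-identical across factorizations.  A final
exchange after the last block keeps plasticity state current.

## Benchmark generator

The generator emulates the standard scaling benchmark family: 80%
excitatory/20% inhibitory populations (gid-contiguous, excitatory first),
fixed in-degrees `k_exc` from the excitatory and `k_inh` from the inhibitory
pool (production values 9000/2250; the 0.8 fraction is inferred from that
4:1 ratio and configurable), STDP on E→E only, uniform delay equal to
`min(d) = 1.5 ms`, independent Poisson drive per neuron.  Fixed in-degrees —
not fixed connection probability — keep networks of different sizes in
comparable dynamical states.

Dynamical defaults are the package's own choice of a sparse asynchronous
regime and are *configuration, not results*: LIF with τ_m = 10 ms,
C_m = 250 pF, τ_syn = 2 ms, 15 mV threshold distance, 2 ms refractoriness;
J_E = 20 pA (≈0.16 mV PSP), g = 5 (J_I = −100 pA), external rate 8600/s at
J_E.  At N = 1000, K = 100 this yields ≈10–13 spikes/s network rate.  The
emergent rate is reported by `measure_rate`, never asserted against any
external figure, because its determinants are free parameters here.

What the generator does *not* emulate: distance-dependent or structured
connectivity (random wiring is the worst case for memory, which is the
regime the model targets), conductance-based neurons, heterogeneous delays
(supported but defaulted uniform), and any hardware effect (cache, SIMD,
network contention).  Passing tests therefore validate the algorithms and
the accounting, not wall-clock behaviour on real machines.

## Problem sizes used in the tests

Chosen so the full suite and the acceptance script each run in minutes on
one core: in-degree checks at N = 100 with the production 9000/2250
(1.125 M connections); occupancy statistics at N = 2000, K = 200, 8 VPs over
20 seeds, and a sparser N = 500, K = 6 regime where `p_∅ ≈ 0.22`;
decomposition invariance on a 1000-neuron, K = 100 plastic network for 1 s of
biological time across (M, T) ∈ {(1,4), (2,2), (4,1)}; capacity solvers
exhaustively cross-checked up to N = 1e4, M = 64.

## Known limitations

- Virtual processes are sequential; no actual concurrency or MPI is
  exercised, and runtime is not modelled at all.
- The memory model ignores allocator/kernel overhead of many small
  allocations; analytic accounting is exact for the modelled structures only.
- `p_∅` assumes independent with-replacement draws; without-replacement
  wiring would make it an approximation.
- Spike emission times are grid-quantized; off-grid (double-precision) spike
  timing schemes are not implemented.
- The splitmix64 keyed stream is statistically adequate for these
  simulations' scale but is not a cryptographic or extensively batteried
  generator.
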