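"""Run the plastic benchmark network and measure population rates.

A balanced random network (80% excitatory) with fixed in-degrees, external
Poisson drive, and spike-timing dependent plasticity on the excitatory-to-
excitatory connections.  Fixed in-degrees keep differently sized networks in
comparable dynamical states.
"""

from spikescale import BenchmarkConfig, measure_rate, run_simulation

cfg = BenchmarkConfig(
    n_neurons=500, k_exc=40, k_inh=10,
    t_sim_ms=500.0, seed=11, M=2, T=2,
)
result = run_simulation(cfg)

print(f"simulated {cfg.t_sim_ms:.0f} ms on a {cfg.M}x{cfg.T} grid: "
      f"{len(result.spikes)} spikes")
for name, pop in (("all", None),
                  ("excitatory", range(cfg.n_excit)),
                  ("inhibitory", range(cfg.n_excit, cfg.n_neurons))):
    s = measure_rate(result.spikes, cfg.n_neurons, (100.0, cfg.t_sim_ms), cfg.h_ms, pop)
    print(f"  {name:<11} rate {s.rate_hz:6.2f} /s  ({s.n_spikes} spikes, {s.n_neurons} neurons)")

weights = [rec.weight
           for table in result.tables
           for _, _, syn_type, rec in table.iter_connections()
           if syn_type == "stdp"]
drift = sum(weights) / len(weights) - cfg.weight_exc
print(f"  plastic synapses: {len(weights)}, mean weight drift {drift:+.4f} pA")
# Rates around 10/s are the intended sparse asynchronous regime; the weight
# drift shows the event-driven plasticity at work.
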