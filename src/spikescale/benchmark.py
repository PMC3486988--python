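"""Benchmark network definition, configuration and measurement.

The benchmark is a recurrent random network of current-based
integrate-and-fire neurons: an excitatory population (fraction
``frac_excit``, default 0.8) and an inhibitory one, each neuron receiving a
*fixed* number of incoming connections — ``k_exc`` from the excitatory pool
and ``k_inh`` from the inhibitory pool — drawn uniformly with replacement.
Constant in-degrees keep networks of different sizes in comparable dynamical
states, which is what makes the family usable for scaling studies.
Excitatory-to-excitatory connections carry spike-timing dependent plasticity;
all others are static.  Each neuron additionally receives an independent
Poisson input train of rate ``nu_ext``.

The production-scale in-degrees are ``k_exc`` = 9000 and ``k_inh`` = 2250
(11,250 synapses per neuron); desk-scale runs use reduced values.  The
dynamical parameters (LIF constants, weights, drive) are configurable
defaults chosen for a sparsely firing balanced network — they are inputs to
the tool, not results.

Configurations round-trip through YAML byte-stably (sorted keys), so a run is
fully described by one text file plus the package version.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .kernel import LIFParams, STDPParams
from .memory_model import NetworkSpec
from .parallel import SparseConnectionTable, VPGrid, wire_network

__all__ = [
    "BenchmarkConfig",
    "BuiltNetwork",
    "RateSummary",
    "build_benchmark",
    "measure_rate",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Complete description of one benchmark run.

    Weights in pA, times in ms, rates in 1/s.  ``frac_excit`` = 0.8 mirrors
    the 4:1 excitatory:inhibitory ratio implied by the 9000:2250 in-degrees.
    All delays default to the global minimal delay (1.5 ms).
    """

    n_neurons: int = 1000
    frac_excit: float = 0.8
    k_exc: int = 80
    k_inh: int = 20
    weight_exc: float = 20.0
    weight_inh: float = -100.0
    weight_ext: float = 20.0
    nu_ext: float = 8600.0  # external Poisson rate per neuron (1/s)
    delay_ms: float = 1.5
    min_delay_ms: float = 1.5
    t_sim_ms: float = 1000.0
    h_ms: float = 0.1
    seed: int = 1
    M: int = 1
    T: int = 1
    stdp_exc_exc: bool = True
    lif: dict = field(default_factory=dict)  # overrides of LIFParams fields
    stdp: dict = field(default_factory=dict)  # overrides of STDPParams fields

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not 0.0 <= self.frac_excit <= 1.0:
            raise ValueError("frac_excit must lie in [0, 1]")
        if self.k_exc < 0 or self.k_inh < 0:
            raise ValueError("in-degrees must be nonnegative")
        if self.k_exc > 0 and self.n_excit < 1:
            raise ValueError("k_exc > 0 but the excitatory pool is empty")
        if self.k_inh > 0 and self.n_inhib < 1:
            raise ValueError("k_inh > 0 but the inhibitory pool is empty")
        if self.t_sim_ms <= 0 or self.h_ms <= 0:
            raise ValueError("t_sim_ms and h_ms must be positive")
        for name in ("delay_ms", "min_delay_ms"):
            steps = getattr(self, name) / self.h_ms
            if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
                raise ValueError(f"{name} must be a positive integer multiple of h_ms")
        if self.delay_ms < self.min_delay_ms:
            raise ValueError("delay_ms must be >= min_delay_ms")
        if self.M < 1 or self.T < 1:
            raise ValueError("M and T must be >= 1")
        # constructing parameter sets validates the overrides early
        self.lif_params()
        self.stdp_params()

    @property
    def n_excit(self) -> int:
        return round(self.n_neurons * self.frac_excit)

    @property
    def n_inhib(self) -> int:
        return self.n_neurons - self.n_excit

    @property
    def delay_steps(self) -> int:
        return round(self.delay_ms / self.h_ms)

    def lif_params(self) -> LIFParams:
        return LIFParams(**{"h": self.h_ms, **self.lif})

    def stdp_params(self) -> STDPParams:
        """Plasticity parameters; ``w0`` defaults to the initial E-E weight
        (falling back to 1 pA when that weight is not positive)."""
        w0 = self.weight_exc if self.weight_exc > 0 else 1.0
        return STDPParams(**{"w0": w0, **self.stdp})

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(self.n_neurons, K_E=self.k_exc, K_I=self.k_inh)

    def grid(self) -> VPGrid:
        return VPGrid(self.M, self.T, seed=self.seed)

    # -- text round trip ----------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "BenchmarkConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_grid(self, M: int, T: int) -> "BenchmarkConfig":
        return replace(self, M=M, T=T)


@dataclass
class BuiltNetwork:
    """A wired benchmark network ready for simulation."""

    net: NetworkSpec
    grid: VPGrid
    tables: list[SparseConnectionTable]
    n_excit: int


def build_benchmark(config: BenchmarkConfig) -> BuiltNetwork:
    """Wire the benchmark network for the configured machine grid.

    Populations are laid out gid-contiguously (excitatory first), wiring goes
    through :func:`spikescale.parallel.wire_network` with E-to-E records typed
    ``stdp`` (when enabled) and everything else ``static``.
    """
    net = config.network_spec()
    grid = config.grid()
    tables = wire_network(
        net,
        grid,
        config.seed,
        n_excit=config.n_excit,
        weight_exc=config.weight_exc,
        weight_inh=config.weight_inh,
        delay_steps=config.delay_steps,
        stdp_exc_exc=config.stdp_exc_exc,
    )
    return BuiltNetwork(net=net, grid=grid, tables=tables, n_excit=config.n_excit)


@dataclass(frozen=True)
class RateSummary:
    """Mean firing rate of a population over a time window."""

    rate_hz: float
    n_spikes: int
    n_neurons: int
    t_start_ms: float
    t_stop_ms: float


def measure_rate(
    spikes: list[tuple[int, int]],
    n_neurons: int,
    window_ms: tuple[float, float],
    h_ms: float = 0.1,
    population: range | None = None,
) -> RateSummary:
    """Population mean firing rate: spikes / (neurons * window).

    ``spikes`` are (step, gid) pairs; the window ``[t_start, t_stop)`` is in
    ms.  ``population`` restricts to a gid range (default: whole network).
    """
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("empty measurement window")
    if population is None:
        population = range(n_neurons)
    n_pop = len(population)
    if n_pop == 0:
        raise ValueError("empty population")
    count = sum(1 for step, gid in spikes if t0 <= step * h_ms < t1 and gid in population)
    rate = count / (n_pop * (t1 - t0) * 1e-3)
    return RateSummary(
        rate_hz=rate, n_spikes=count, n_neurons=n_pop, t_start_ms=t0, t_stop_ms=t1
    )
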