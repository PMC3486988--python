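"""Hybrid time-driven / event-driven simulation kernel.

Neurons are leaky integrate-and-fire units with exponential (current-based)
postsynaptic currents.  Their subthreshold dynamics

    tau_syn dI/dt = -I
    tau_m   dV/dt = -(V - E_L) + (tau_m / C_m) I

are linear, so a time step of length ``h`` is advanced *exactly* by the matrix
exponential of the system matrix — no discretization error at grid points.
The only non-linearity is the threshold test, followed by reset and an
integer-step refractory period.  Incoming spike weights for a future step are
lumped into a ring buffer slot and consumed as a single summed increment to
the synaptic current.

Synapses with spike-timing dependent plasticity are updated *event-driven*:
only when the presynaptic neuron fires is the synapse advanced across all
postsynaptic spikes since its last update, using the target's spike history.
The pairing scheme is all-to-all with exponential traces: each (pre, post)
pair with positive lag potentiates by a weight-dependent power law,
``dw = lambda * w0**(1-mu) * w**mu * exp(-dt/tau_plus)``, and each (post, pre)
pair depresses proportionally to the weight,
``dw = -lambda * alpha * w * exp(-dt/tau_minus)``.  Simultaneous pre/post
spikes (dt = 0) pair in neither direction.  Within one update, potentiations
are applied in time order, then the depression of the triggering presynaptic
spike; weights are clipped at zero from below.

Update-order contract (fixed, and relied on by the tests): propagate ->
add ring-buffer input to the synaptic current -> threshold test -> reset.
Input summed at step t therefore first moves the membrane at step t+1.

External drive is Poisson: per neuron and step a count is drawn from a
counter-style stream keyed by ``(seed, gid, step)``, making the drive
independent of how neurons are distributed over processes and threads.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np

from . import rng
from .connection_store import ConnectionRecord

__all__ = [
    "LIFParams",
    "LIFState",
    "Propagator",
    "RingBuffer",
    "RingBufferArray",
    "STDPParams",
    "SpikeHistory",
    "make_propagator",
    "step_neuron",
    "update_population",
    "stdp_on_presyn_spike",
    "poisson_input",
    "poisson_input_array",
]


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters (ms, pF, mV, pA).

    The defaults are generic values for a current-based cortical-network
    model; they are configuration, not ground truth of any particular study.
    """

    tau_m: float = 10.0  # membrane time constant (ms)
    C_m: float = 250.0  # capacitance (pF)
    tau_syn: float = 2.0  # synaptic current time constant (ms)
    V_th: float = -55.0  # spike threshold (mV)
    V_reset: float = -70.0  # reset potential (mV)
    E_L: float = -70.0  # resting potential (mV)
    t_ref: float = 2.0  # refractory period (ms)
    h: float = 0.1  # time step (ms)

    def __post_init__(self):
        if min(self.tau_m, self.tau_syn, self.h) <= 0:
            raise ValueError("time constants and h must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be nonnegative")
        steps = self.t_ref / self.h
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("t_ref must be an integer multiple of h")

    @property
    def ref_steps(self) -> int:
        return round(self.t_ref / self.h)


@dataclass(slots=True)
class LIFState:
    """Instantaneous neuron state."""

    V: float  # membrane potential (mV)
    I: float = 0.0  # synaptic current (pA)
    refr_steps_left: int = 0

    def __post_init__(self):
        if self.refr_steps_left < 0:
            raise ValueError("refr_steps_left must be nonnegative")


@dataclass(frozen=True)
class Propagator:
    """Entries of the exact one-step solution operator.

    For state (I, V - E_L):  I' = decay_syn * I;
    V' - E_L = decay_mem * (V - E_L) + mix * I.
    """

    decay_syn: float
    decay_mem: float
    mix: float
    h: float


def make_propagator(params: LIFParams) -> Propagator:
    """Closed-form matrix exponential of the subthreshold system over one step.

    Degenerate at ``tau_m == tau_syn`` (the mixing entry becomes t*exp(-t/tau);
    not implemented), which is rejected.
    """
    tm, ts, h, cm = params.tau_m, params.tau_syn, params.h, params.C_m
    if abs(tm - ts) <= 1e-12 * max(tm, ts):
        raise ValueError("degenerate propagator: tau_m == tau_syn is not supported")
    em = math.exp(-h / tm)
    es = math.exp(-h / ts)
    mix = (es - em) / ((1.0 / tm - 1.0 / ts) * cm)
    return Propagator(decay_syn=es, decay_mem=em, mix=mix, h=h)


def update_population(
    V: np.ndarray,
    I: np.ndarray,
    refr: np.ndarray,
    ring_input: np.ndarray,
    params: LIFParams,
    prop: Propagator,
) -> np.ndarray:
    """Advance arrays of neuron state by one step, in place.

    This is the single update path of the kernel; :func:`step_neuron` wraps it
    for one neuron.  Returns the boolean spike mask.
    """
    active = refr == 0
    V_new = params.E_L + prop.decay_mem * (V - params.E_L) + prop.mix * I
    np.copyto(V, V_new, where=active)
    V[~active] = params.V_reset  # clamped during refractoriness
    I *= prop.decay_syn
    I += ring_input
    spiked = active & (V >= params.V_th)
    V[spiked] = params.V_reset
    refr[~active] -= 1
    refr[spiked] = params.ref_steps
    return spiked


def step_neuron(
    state: LIFState,
    ring_input: float,
    params: LIFParams,
    prop: Propagator | None = None,
) -> tuple[LIFState, bool]:
    """One time step of a single neuron; returns ``(new_state, spiked)``."""
    if not (math.isfinite(state.V) and math.isfinite(state.I) and math.isfinite(ring_input)):
        raise ValueError("non-finite neuron state or input")
    if prop is None:
        prop = make_propagator(params)
    V = np.array([state.V])
    I = np.array([state.I])
    refr = np.array([state.refr_steps_left])
    spiked = update_population(V, I, refr, np.array([ring_input]), params, prop)
    return LIFState(V=float(V[0]), I=float(I[0]), refr_steps_left=int(refr[0])), bool(spiked[0])


class RingBuffer:
    """Delayed-input accumulator for one neuron.

    Slot ``(step + delay_steps) mod len`` collects the summed weight arriving
    ``delay_steps`` in the future; the slot for the current step is zeroed
    after consumption so it can be reused one revolution later.
    """

    def __init__(self, max_delay_steps: int):
        if max_delay_steps < 1:
            raise ValueError("max_delay_steps must be >= 1")
        self.max_delay_steps = max_delay_steps
        self._slots = np.zeros(max_delay_steps + 1)

    def __len__(self) -> int:
        return len(self._slots)

    def enqueue_spike(self, weight: float, delay_steps: int, current_step: int) -> None:
        if not 1 <= delay_steps <= self.max_delay_steps:
            raise ValueError(
                f"delay_steps {delay_steps} outside [1, {self.max_delay_steps}]"
            )
        self._slots[(current_step + delay_steps) % len(self._slots)] += weight

    def read(self, step: int) -> float:
        """Consume (return and zero) the accumulated input for ``step``."""
        idx = step % len(self._slots)
        value = float(self._slots[idx])
        self._slots[idx] = 0.0
        return value


class RingBufferArray:
    """Ring buffers for a population, one row per local neuron."""

    def __init__(self, n_neurons: int, max_delay_steps: int):
        if max_delay_steps < 1:
            raise ValueError("max_delay_steps must be >= 1")
        self.max_delay_steps = max_delay_steps
        self._slots = np.zeros((n_neurons, max_delay_steps + 1))

    def enqueue(self, local_idx: int, weight: float, delay_steps: int, current_step: int) -> None:
        if not 1 <= delay_steps <= self.max_delay_steps:
            raise ValueError(
                f"delay_steps {delay_steps} outside [1, {self.max_delay_steps}]"
            )
        self._slots[local_idx, (current_step + delay_steps) % self._slots.shape[1]] += weight

    def read(self, step: int) -> np.ndarray:
        idx = step % self._slots.shape[1]
        values = self._slots[:, idx].copy()
        self._slots[:, idx] = 0.0
        return values


@dataclass(frozen=True)
class STDPParams:
    """All-to-all trace-based plasticity parameters.

    ``w0`` is the reference weight of the power-law potentiation; by
    convention it is set to the initial excitatory-excitatory weight when a
    benchmark network is built.
    """

    tau_plus: float = 15.0  # potentiation trace time constant (ms)
    tau_minus: float = 30.0  # depression trace time constant (ms)
    lam: float = 0.1  # learning rate
    mu: float = 0.4  # weight-dependence exponent of potentiation
    alpha: float = 0.0513  # relative strength of depression
    w0: float = 1.0  # reference weight (pA)

    def __post_init__(self):
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("trace time constants must be positive")
        if self.lam < 0 or self.alpha < 0:
            raise ValueError("lam and alpha must be nonnegative")
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must lie in [0, 1]")
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")


class SpikeHistory:
    """Ordered spike times of one neuron, as needed by its plastic synapses."""

    __slots__ = ("times",)

    def __init__(self, times=()):
        self.times: list[float] = []
        for t in times:
            self.append(t)

    def append(self, t: float) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("spike times must be strictly increasing")
        self.times.append(t)

    def between(self, t_lo: float, t_hi: float) -> list[float]:
        """Spike times in the half-open interval ``(t_lo, t_hi]``."""
        lo = bisect.bisect_right(self.times, t_lo)
        hi = bisect.bisect_right(self.times, t_hi)
        return self.times[lo:hi]

    def trace_before(self, t: float, tau: float) -> float:
        """Exponential trace ``sum exp(-(t - s)/tau)`` over spikes ``s < t``."""
        hi = bisect.bisect_left(self.times, t)
        return sum(math.exp(-(t - s) / tau) for s in self.times[:hi])

    def prune(self, before: float) -> None:
        """Drop entries older than ``before`` (no synapse needs them anymore)."""
        lo = bisect.bisect_left(self.times, before)
        del self.times[:lo]


def stdp_on_presyn_spike(
    syn: ConnectionRecord,
    presyn_time: float,
    post_history: SpikeHistory,
    params: STDPParams,
) -> ConnectionRecord:
    """Advance one plastic synapse across a presynaptic spike, in place.

    Processes, in time order, every postsynaptic spike in
    ``(syn.last_update, presyn_time]`` (potentiation, using the synapse's own
    presynaptic trace ``kplus``) and finally the depression triggered at
    ``presyn_time`` by the postsynaptic trace.  The presynaptic trace is then
    decayed and incremented, and ``last_update`` moved to ``presyn_time`` — so
    repeated calls at successive presynaptic spikes reproduce one continuous
    time-ordered pass.
    """
    if presyn_time < syn.last_update:
        raise ValueError("presyn_time precedes the synapse's last update")
    w = syn.weight
    factor = params.lam * params.w0 ** (1.0 - params.mu)
    for t_post in post_history.between(syn.last_update, presyn_time):
        k = syn.kplus * math.exp(-(t_post - syn.last_update) / params.tau_plus)
        w += factor * w**params.mu * k
    kminus = post_history.trace_before(presyn_time, params.tau_minus)
    w -= params.lam * params.alpha * w * kminus
    w = max(w, 0.0)
    syn.kplus = syn.kplus * math.exp(-(presyn_time - syn.last_update) / params.tau_plus) + 1.0
    syn.last_update = presyn_time
    syn.weight = w
    return syn


def poisson_input(gid: int, step: int, rate: float, seed: int, h: float = 0.1) -> int:
    """Poisson spike count for one neuron and step, mean ``rate * h``.

    ``rate`` in 1/s, ``h`` in ms.  The draw is keyed by ``(seed, gid, step)``
    and therefore identical under any machine decomposition.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    return rng.keyed_poisson(rate * h * 1e-3, seed, rng.PURPOSE_POISSON, gid, step)


def poisson_input_array(gids: np.ndarray, step: int, rate: float, seed: int, h: float = 0.1):
    """Vectorized :func:`poisson_input` over an array of gids."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    return rng.keyed_poisson(rate * h * 1e-3, seed, rng.PURPOSE_POISSON, gids, step)
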