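"""Counter-style keyed random streams.

Every random quantity in the simulator is a pure function of a small tuple of
integers ``(seed, purpose, gid, index-or-step)``.  This makes wiring and
Poisson input *decomposition invariant by construction*: a draw belonging to a
neuron does not depend on which emulated process or thread happens to own that
neuron, nor on how many draws other neurons have consumed.  Stateful
per-thread generators achieve the same goal only under a strict "same number
of variates per generator" discipline; keyed streams sidestep the bookkeeping.

The bit mixer is the splitmix64 finalizer (Steele, Lea & Flood's SplittableRandom
avalanche function), applied to each key word in sequence.  It is vectorized
over numpy ``uint64`` arrays; wrap-around arithmetic is intentional.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy import stats

__all__ = [
    "PURPOSE_POISSON",
    "PURPOSE_WIRING",
    "keyed_u64",
    "keyed_uniform",
    "keyed_randint",
    "keyed_poisson",
]

# purpose words keep independent uses of the same (seed, gid) apart
PURPOSE_POISSON = 0x50_4F_49_53  # "POIS"
PURPOSE_WIRING = 0x57_49_52_45  # "WIRE"

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_INV53 = float(2.0**-53)


def _mix(z: np.ndarray) -> np.ndarray:
    z = (z ^ (z >> _S30)) * _MIX1
    z = (z ^ (z >> _S27)) * _MIX2
    return z ^ (z >> _S31)


def keyed_u64(seed: int, *words) -> np.ndarray | int:
    """Mix ``seed`` and key ``words`` into 64 uniform bits.

    Words may be ints or integer arrays; arrays broadcast against each other.
    Returns a python int for all-scalar input, else a uint64 array.
    """
    scalar = all(np.isscalar(w) for w in words)
    # 1-d at minimum: numpy scalar arithmetic warns on the (intended) wrap-around
    z = _mix(np.atleast_1d(np.uint64(int(seed) & 0xFFFFFFFFFFFFFFFF)) + _GOLDEN)
    for w in words:
        wa = np.atleast_1d(np.asarray(w)).astype(np.uint64, copy=False)
        z = _mix((z ^ wa) + _GOLDEN)
    if scalar:
        return int(z[0])
    return z


def keyed_uniform(seed: int, *words):
    """Uniform draw(s) in [0, 1) with 53-bit resolution, keyed by ``words``."""
    bits = keyed_u64(seed, *words)
    if isinstance(bits, int):
        return (bits >> 11) * _INV53
    return (bits >> np.uint64(11)).astype(np.float64) * _INV53


def keyed_randint(n: int, seed: int, *words):
    """Uniform integer draw(s) in [0, n), keyed by ``words``."""
    if n < 1:
        raise ValueError("empty range")
    u = keyed_uniform(seed, *words)
    out = np.minimum((np.asarray(u) * n).astype(np.int64), n - 1)
    if all(np.isscalar(w) for w in words):
        return int(out)
    return out


@functools.lru_cache(maxsize=32)
def _poisson_cdf(mean: float) -> np.ndarray:
    # support covering the distribution to below float resolution; the final
    # 1.0 entry catches the (probability < 1e-15) tail
    k_hi = int(np.ceil(mean + 12.0 * np.sqrt(mean) + 30.0))
    cdf = stats.poisson.cdf(np.arange(k_hi + 1), mean)
    return np.append(cdf, 1.0)


def keyed_poisson(mean: float, seed: int, *words):
    """Poisson count(s) with the given mean, keyed by ``words``.

    Drawn by exact CDF inversion of a single keyed uniform, so each count is a
    deterministic function of ``(seed, *words)`` alone.
    """
    if mean < 0:
        raise ValueError("mean must be nonnegative")
    scalar = all(np.isscalar(w) for w in words)
    u = np.atleast_1d(keyed_uniform(seed, *words))
    if mean == 0.0:
        counts = np.zeros(u.shape, dtype=np.int64)
    else:
        counts = np.searchsorted(_poisson_cdf(float(mean)), u, side="right").astype(np.int64)
    if scalar:
        return int(counts[0])
    return counts
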