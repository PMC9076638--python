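"""Shared helpers: keyed RNG streams and angle arithmetic."""

from __future__ import annotations

import zlib

import numpy as np

TWO_PI = 2.0 * np.pi


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def keyed_rng(seed: int, *keys) -> np.random.Generator:
    """Independent, reproducible RNG stream for (seed, *keys).

    Every stochastic stage derives its generator this way so that e.g.
    subject 7 / trial 12 can be regenerated without replaying the whole
    session.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def wrap_angle(theta):
    """Wrap angles to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.angle(np.exp(1j * theta))
    # np.angle returns [-pi, pi); map -pi to +pi for the half-open convention
    if wrapped.ndim == 0:
        return float(np.pi) if wrapped == -np.pi else float(wrapped)
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


def circ_mean_resultant(angles, axis=None):
    """Mean direction and resultant length of unit vectors."""
    z = np.mean(np.exp(1j * np.asarray(angles, dtype=float)), axis=axis)
    return np.angle(z), np.abs(z)


def sample_von_mises(rng: np.random.Generator, mu: float, kappa: float, size):
    """von Mises draws; kappa == 0 degrades to the circular uniform."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, size=size)
    return wrap_angle(rng.vonmises(mu, kappa, size=size))
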