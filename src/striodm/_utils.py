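"""Shared numerics: clamped sigmoid, seed derivation, array validation."""

from __future__ import annotations

import zlib

import numpy as np

from .exceptions import ShapeError

#: Sigmoid arguments are clamped to +-EXP_CLAMP before exponentiation so that
#: extreme circuit offsets saturate near the open-interval limits. 36 is the
#: largest clamp for which 1/(1+exp(-x)) stays strictly below 1 in float64.
EXP_CLAMP = 36.0


def sigmoid(x):
    """Logistic function 1/(1+exp(-x)) with overflow clamping.

    Output is strictly inside (0, 1): at the clamp the value is
    ~1/(1+e^50) ~ 2e-22, never exactly 0 or 1.
    """
    x = np.clip(np.asarray(x, dtype=float), -EXP_CLAMP, EXP_CLAMP)
    return 1.0 / (1.0 + np.exp(-x))


def derive_seed(master_seed: int, name: str) -> int:
    """Deterministically derive a sub-seed for a named operation.

    Every stochastic operation in a scenario run draws its generator from
    ``derive_seed(master_seed, operation_path)`` so that re-running with the
    same master seed is bit-identical while operations stay decorrelated.
    """
    return (int(master_seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31 - 1)


def rng_for(seed, name: str | None = None) -> np.random.Generator:
    """Build a Generator from a seed, optionally derived for a named operation."""
    if isinstance(seed, np.random.Generator):
        return seed
    if name is not None:
        seed = derive_seed(seed, name)
    return np.random.default_rng(seed)


def as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ShapeError(f"{name} must be 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ShapeError(f"{name} contains non-finite entries")
    return arr
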