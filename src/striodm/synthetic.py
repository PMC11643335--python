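"""Synthetic cortical-activity generators.

Cortical input to the model is a mixture of latent sources (reward, cost,
novelty, ...) with fixed loading vectors plus i.i.d. Gaussian noise:

    x(t) = sum_k a_k * z_k(t) * u_k + noise,   z_k ~ N(0, 1)

The generators control the number of sources, their loading structure, the
per-source amplitudes (signal-to-noise ratio), and the noise floor. They
emulate mixed-selectivity cortical populations, not any recorded dataset.
"""

from __future__ import annotations

import numpy as np

from ._utils import rng_for
from .exceptions import InvalidParameterError

__all__ = ["make_source_loadings", "generate_cortical_activity", "gaussian_with_spectrum"]


def make_source_loadings(n_neurons: int, n_sources: int, seed) -> np.ndarray:
    """Random orthonormal loading vectors, one per latent source."""
    rng = rng_for(seed)
    a = rng.standard_normal((n_neurons, n_sources))
    q, _ = np.linalg.qr(a)
    return q[:, :n_sources]


def generate_cortical_activity(
    n_samples: int,
    n_neurons: int,
    amplitudes=(1.0,),
    loadings: np.ndarray | None = None,
    noise_sd: float = 0.1,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a (time x neuron) cortical activity matrix.

    Returns ``(activity, loadings)``; per-source amplitudes set the signal
    scale relative to ``noise_sd``.
    """
    if n_samples < 1 or n_neurons < 1:
        raise InvalidParameterError("n_samples and n_neurons must be >= 1")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    rng = rng_for(seed)
    if loadings is None:
        loadings = make_source_loadings(n_neurons, amplitudes.size, rng)
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (n_neurons, amplitudes.size):
        raise InvalidParameterError("loadings must be (n_neurons, n_sources)")
    z = rng.standard_normal((n_samples, amplitudes.size)) * amplitudes
    x = z @ loadings.T + noise_sd * rng.standard_normal((n_samples, n_neurons))
    return x, loadings


def gaussian_with_spectrum(n_samples: int, eigenvalues, seed, rotate: bool = True):
    """Zero-mean Gaussian samples with a prescribed covariance spectrum.

    Returns ``(samples, components)`` where ``components`` columns are the
    true covariance eigenvectors in descending-eigenvalue order. Used as
    ground truth for principal-component learning.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < 0):
        raise InvalidParameterError("eigenvalues must be >= 0")
    rng = rng_for(seed)
    p = ev.size
    if rotate:
        u, _ = np.linalg.qr(rng.standard_normal((p, p)))
    else:
        u = np.eye(p)
    z = rng.standard_normal((n_samples, p)) * np.sqrt(ev)
    return z @ u.T, u
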