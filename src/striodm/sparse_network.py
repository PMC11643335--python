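"""Sparse-connectivity circuit instance.

Many small groups of cortical neurons each project onto one FSI and one SPN
per decision-dimension and pathway. Per-group cortex->SPN weights are the
leading principal components of the group's input, learned online with
Sanger's rule (a deflated variant of Oja's rule that yields ordered
components). Activities are

    sSPN_{i,C} = (1/|C|) sum_{q in C} w^(i)_q x_q / FSI_C + b_sSPN
    daSNC_i    = sigmoid( -( mean_C w_s->da,i sSPN_{i,C} + RMTg - z_i ) )
    mSPN_{i,C} = (d_i/|C|) sum_{q in C} w^(i)_q x_q / FSI_C

with d_i the dopamine gate of dimension i. FSI activity is driven by the
group's own cortical afferents; chronic stress is modelled as a reduction in
the NUMBER of cortex->FSI connections per group (not their weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._utils import rng_for, sigmoid
from .exceptions import InvalidParameterError, ShapeError, UndefinedStatisticError

__all__ = [
    "SparseNetwork",
    "build_sparse_network",
    "learn_oja_weights",
    "learn_network_weights",
    "compute_fsi",
    "compute_sparse_activities",
    "apply_stress",
    "bhattacharyya_distance",
]

#: Small floor keeping FSI divisive normalization positive.
FSI_FLOOR = 0.5


@dataclass
class SparseNetwork:
    """Sparse cortex->FSI->SPN wiring and weights.

    groups      : (G, k) cortical indices per group
    w_s, w_m    : (G, q, k) cortex->sSPN / cortex->mSPN weights
    fsi_members : (G, k') cortical indices driving each group's FSI
    w_s_to_dasnc: (q,) striosome->daSNC weights
    """

    groups: np.ndarray
    w_s: np.ndarray
    w_m: np.ndarray
    fsi_members: np.ndarray
    w_s_to_dasnc: np.ndarray
    n_cortex: int

    @property
    def n_groups(self) -> int:
        return self.groups.shape[0]

    @property
    def group_size(self) -> int:
        return self.groups.shape[1]

    @property
    def q(self) -> int:
        return self.w_s.shape[1]


def build_sparse_network(
    n_cortex: int = 50,
    n_groups: int = 1000,
    group_size: int = 4,
    q: int = 4,
    seed=0,
) -> SparseNetwork:
    """Wire a sparse network of randomly sampled cortical groups.

    Each group samples ``group_size`` distinct cortical neurons uniformly.
    Weights start as random unit-norm vectors; call
    :func:`learn_network_weights` to replace them with learned principal
    components. Defaults are a desk-scale version of the reference
    configuration (thousands of 4-neuron groups).
    """
    if group_size > n_cortex:
        raise InvalidParameterError("group_size cannot exceed n_cortex")
    if n_groups < 1:
        raise InvalidParameterError("n_groups must be >= 1")
    if q > group_size:
        raise InvalidParameterError("q cannot exceed group_size (per-group PCs)")
    rng = rng_for(seed)
    groups = np.stack(
        [rng.choice(n_cortex, size=group_size, replace=False) for _ in range(n_groups)]
    )
    w_s = rng.standard_normal((n_groups, q, group_size))
    w_s /= np.linalg.norm(w_s, axis=2, keepdims=True)
    w_m = rng.standard_normal((n_groups, q, group_size))
    w_m /= np.linalg.norm(w_m, axis=2, keepdims=True)
    return SparseNetwork(
        groups=groups,
        w_s=w_s,
        w_m=w_m,
        fsi_members=groups.copy(),
        w_s_to_dasnc=np.ones(q),
        n_cortex=n_cortex,
    )


def learn_oja_weights(
    samples: np.ndarray,
    k: int,
    lr: float = 0.05,
    epochs: int = 40,
    seed=0,
) -> np.ndarray:
    """Learn the top-k principal components online with Sanger's rule.

    Sequential deflation orders the components; the learning rate decays as
    1/t over presentations. Returns a (p, k) matrix of unit-norm component
    vectors. A rank-deficient sample covariance triggers a convergence
    warning (the trailing components are then arbitrary within the null
    space).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ShapeError("samples must be (n_samples, n_features)")
    n, p = x.shape
    if k > p:
        raise InvalidParameterError("cannot learn more components than features")
    if lr < 0:
        raise InvalidParameterError("lr must be >= 0")
    rank = np.linalg.matrix_rank(np.cov(x.T)) if n > 1 else 0
    if rank < k:
        warnings.warn(
            f"sample covariance rank {rank} < requested components {k}; "
            "trailing components may not converge",
            RuntimeWarning,
        )
    rng = rng_for(seed)
    W = rng.standard_normal((k, p))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    if lr == 0:
        return W.T
    t = 0
    lower = np.tril(np.ones((k, k)))
    for _ in range(epochs):
        for i in rng.permutation(n):
            t += 1
            lr_t = lr * n / (n + t)
            xi = x[i]
            y = W @ xi
            # Sanger: dW = lr ( y x^T - LT(y y^T) W )
            W += lr_t * (np.outer(y, xi) - (lower * np.outer(y, y)) @ W)
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    W /= np.where(norms > 0, norms, 1.0)
    return W.T


def learn_network_weights(
    net: SparseNetwork, samples: np.ndarray, lr: float = 0.05, epochs: int = 20, seed=0
) -> SparseNetwork:
    """Replace every group's cortex->SPN weights with its local principal
    components, learned online with the same Sanger rule as
    :func:`learn_oja_weights` but vectorized across all groups at once.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != net.n_cortex:
        raise ShapeError("samples must be (n_samples, n_cortex)")
    n = x.shape[0]
    q, k = net.q, net.group_size
    rng = rng_for(seed)
    xloc = x[:, net.groups]  # (n, G, k) local views of each sample
    W = net.w_s.copy()
    lower = np.tril(np.ones((q, q)))
    t = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            t += 1
            lr_t = lr * n / (n + t)
            xi = xloc[i]  # (G, k)
            y = np.einsum("gqk,gk->gq", W, xi)
            hebb = y[:, :, None] * xi[:, None, :]
            defl = np.einsum(
                "qr,gq,gr,grk->gqk", lower, y, y, W, optimize=True
            )
            W += lr_t * (hebb - defl)
    norms = np.linalg.norm(W, axis=2, keepdims=True)
    W /= np.where(norms > 0, norms, 1.0)
    return replace(net, w_s=W, w_m=W.copy())


def compute_fsi(net: SparseNetwork, x: np.ndarray) -> np.ndarray:
    """Per-group FSI activity: floor + mean |activity| of its cortical afferents."""
    x = np.asarray(x, dtype=float)
    return FSI_FLOOR + np.abs(x[net.fsi_members]).mean(axis=1)


def apply_stress(net: SparseNetwork, n_removed: int, seed=0) -> SparseNetwork:
    """Chronic-stress perturbation: remove cortex->FSI connections per group.

    Each group loses ``n_removed`` of its FSI afferents (sampled without
    replacement), degrading divisive normalization without touching weights.
    """
    k = net.fsi_members.shape[1]
    if not 0 <= n_removed < k:
        raise InvalidParameterError("must keep at least one FSI connection")
    rng = rng_for(seed)
    keep = k - n_removed
    new_members = np.stack(
        [rng.choice(net.fsi_members[g], size=keep, replace=False) for g in range(net.n_groups)]
    )
    return replace(net, fsi_members=new_members)


def compute_sparse_activities(
    net: SparseNetwork,
    x: np.ndarray,
    rmtg: float = 0.0,
    z_dasnc=0.0,
    b_sspn: float = 0.0,
    d=None,
    gate_threshold: float | None = None,
) -> dict:
    """sSPN, daSNC and mSPN activities of the sparse network for input x.

    ``d`` fixes the per-dimension dopamine gates; by default the continuous
    daSNC activations are used, or thresholded to binary gates when
    ``gate_threshold`` is given.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != net.n_cortex:
        raise ShapeError("input length must equal n_cortex")
    fsi = compute_fsi(net, x)
    xg = x[net.groups]  # (G, k)
    proj_s = np.einsum("gqk,gk->gq", net.w_s, xg) / net.group_size
    sspn = proj_s / fsi[:, None] + b_sspn  # (G, q)
    z = np.broadcast_to(np.asarray(z_dasnc, dtype=float), (net.q,))
    drive = net.w_s_to_dasnc * sspn.mean(axis=0)
    dasnc = sigmoid(-(drive + rmtg - z))
    if d is None:
        d_vec = dasnc if gate_threshold is None else (dasnc >= gate_threshold).astype(float)
    else:
        d_vec = np.broadcast_to(np.asarray(d, dtype=float), (net.q,))
    proj_m = np.einsum("gqk,gk->gq", net.w_m, xg) / net.group_size
    mspn = d_vec * proj_m / fsi[:, None]
    return {"sspn": sspn, "dasnc": dasnc, "d": np.asarray(d_vec, float), "mspn": mspn, "fsi": fsi}


def bhattacharyya_distance(a, b, method: str = "gaussian", bins: int = 30) -> float:
    """Bhattacharyya distance between two activity samples.

    ``gaussian`` uses the closed form under normal approximations,
    (1/4) ln((sa²/sb² + sb²/sa² + 2)/4) + (1/4)(mu_a - mu_b)²/(sa² + sb²);
    ``histogram`` uses -ln(sum sqrt(p q)) on a shared binning.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise UndefinedStatisticError("each sample needs >= 2 points")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise UndefinedStatisticError("Bhattacharyya undefined for zero-variance sample")
    if method == "gaussian":
        term_var = 0.25 * np.log(0.25 * (va / vb + vb / va + 2.0))
        term_mean = 0.25 * (a.mean() - b.mean()) ** 2 / (va + vb)
        return float(term_var + term_mean)
    if method == "histogram":
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        pa, edges = np.histogram(a, bins=bins, range=(lo, hi), density=False)
        pb, _ = np.histogram(b, bins=edges, density=False)
        pa = pa / pa.sum()
        pb = pb / pb.sum()
        bc = np.sqrt(pa * pb).sum()
        return float(-np.log(max(bc, 1e-300)))
    raise InvalidParameterError(f"unknown method {method!r}")
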