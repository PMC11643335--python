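"""Decision-space dimensionality distribution and valuation scoring.

The number of decision-dimensions gated into the decision-space is a sum of
independent (generally non-identical) Bernoulli gates, i.e. Poisson-binomial.
With a common gate probability d this reduces to the printed binomial form
P(m) = C(q, m) d^m (1-d)^(q-m). On top of the distribution the module scores
reward x cost action-value grids along six subjective-valuation axes
(riskiness, safety, high action, low action, exploit, explore).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import CircuitParameters, gating_probabilities
from .exceptions import (
    InvalidParameterError,
    ShapeError,
    UndefinedStatisticError,
)

__all__ = [
    "DimensionalityPMF",
    "ValuationProfile",
    "dimensionality_pmf",
    "binomial_dimensionality_pmf",
    "decision_space_probability_map",
    "gini_coefficient",
    "score_valuation_axes",
    "outlier_rate",
]


@dataclass
class DimensionalityPMF:
    """P(m dimensions in the decision-space) for m = 0..q."""

    probs: np.ndarray
    pmf: np.ndarray

    @property
    def q(self) -> int:
        return self.probs.size

    @property
    def mean(self) -> float:
        return float(np.arange(self.q + 1) @ self.pmf)


@dataclass
class ValuationProfile:
    """Six-axis subjective-valuation summary of a reward x cost value grid."""

    riskiness: float
    safety: float
    high_action: float
    low_action: float
    exploit: float
    explore: float
    thresholds: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "riskiness": self.riskiness,
            "safety": self.safety,
            "high_action": self.high_action,
            "low_action": self.low_action,
            "exploit": self.exploit,
            "explore": self.explore,
        }

    def scores(self) -> np.ndarray:
        return np.array(
            [self.riskiness, self.safety, self.high_action,
             self.low_action, self.exploit, self.explore]
        )


def dimensionality_pmf(probs) -> DimensionalityPMF:
    """Exact Poisson-binomial pmf of the decision-space dimensionality.

    Computed by iterative convolution: starting from P(0)=1, each gate i
    splits the mass by (1-p_i, p_i). Exact to floating precision for any
    heterogeneous probability vector.
    """
    p = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("gate probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return DimensionalityPMF(probs=p, pmf=pmf)


def binomial_dimensionality_pmf(q: int, d: float) -> DimensionalityPMF:
    """Common-gate shortcut: P(m) = C(q,m) d^m (1-d)^(q-m)."""
    from scipy.stats import binom

    if not 0 <= d <= 1:
        raise InvalidParameterError("d must lie in [0, 1]")
    m = np.arange(q + 1)
    return DimensionalityPMF(probs=np.full(q, float(d)), pmf=binom.pmf(m, q, d))


def decision_space_probability_map(
    sspn_offsets,
    dasnc_offsets,
    lhb_offsets,
    params: CircuitParameters | None = None,
    pathway: str = "direct",
) -> pd.DataFrame:
    """Dimensionality distribution over a grid of circuit offsets.

    At each (sSPN offset, daSNC offset, LHb offset) point the feedforward
    gates are evaluated and the Poisson-binomial pmf computed. High-
    dimensional spaces tend to form where sSPN and LHb activity are low and
    daSNC excitability is high.
    """
    if params is None:
        params = CircuitParameters()
    x0 = np.zeros(params.q)
    rows = []
    for b in sspn_offsets:
        for dz in dasnc_offsets:
            for lhb in lhb_offsets:
                p = CircuitParameters(
                    q=params.q,
                    weights_direct=params.weights_direct,
                    weights_indirect=params.weights_indirect,
                    pallido=type(params.pallido)(
                        w_gpi=params.pallido.w_gpi,
                        z_gpi=params.pallido.z_gpi,
                        z_lhb=float(lhb),
                        z_rmtg=params.pallido.z_rmtg,
                    ),
                    gate_direct=type(params.gate_direct)(
                        w_sd=params.gate_direct.w_sd,
                        z_dasnc=params.gate_direct.z_dasnc + float(dz),
                    ),
                    gate_indirect=type(params.gate_indirect)(
                        w_sd=params.gate_indirect.w_sd,
                        z_dasnc=params.gate_indirect.z_dasnc + float(dz),
                    ),
                    beta=params.beta,
                    alpha=params.alpha,
                )
                probs_d, probs_i = gating_probabilities(x0, p, b_sspn=float(b))
                probs = probs_d if pathway == "direct" else probs_i
                dist = dimensionality_pmf(probs)
                row = {
                    "sspn_offset": float(b),
                    "dasnc_offset": float(dz),
                    "lhb_offset": float(lhb),
                    "expected_dimensionality": dist.mean,
                }
                for m, pm in enumerate(dist.pmf):
                    row[f"p_dim_{m}"] = float(pm)
                rows.append(row)
    return pd.DataFrame(rows)


def gini_coefficient(values) -> float:
    """Gini coefficient: mean absolute pairwise difference / (2 * mean).

    0 for perfectly equal values, (n-1)/n in the single-holder limit.
    """
    v = np.atleast_1d(np.asarray(values, dtype=float))
    if v.size < 2:
        raise UndefinedStatisticError("Gini needs >= 2 values")
    if np.any(v < 0):
        raise UndefinedStatisticError("Gini undefined for negative values")
    mean = v.mean()
    if mean == 0:
        raise UndefinedStatisticError("Gini undefined for all-zero values")
    # O(n log n) via the sorted-rank identity, equivalent to the pairwise mean
    v_sorted = np.sort(v)
    n = v.size
    ranks = np.arange(1, n + 1)
    return float((2 * ranks - n - 1) @ v_sorted / (n * n * mean))


def score_valuation_axes(
    grid: np.ndarray,
    high_sum: float = 0.5,
    low_sum: float = 0.2,
    high_gini: float = 0.5,
    low_gini: float = 0.25,
) -> ValuationProfile:
    """Score a reward x cost action-value grid along six valuation axes.

    ``grid`` has shape (n_reward, n_cost, n_actions): axis 0 indexes
    increasing reward, axis 1 increasing cost, and each cell holds the
    per-action value vector. Riskiness/safety are the mean summed value in
    the high-reward/high-cost and low-reward/low-cost corner quadrants;
    high/low action are the grid fractions with summed value above/below the
    sum thresholds; exploit/explore the fractions with per-cell Gini above
    ``high_gini`` / below ``low_gini``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 3:
        raise ShapeError("grid must be (n_reward, n_cost, n_actions)")
    nr, nc, _ = grid.shape
    sums = grid.sum(axis=2)
    hr, hc = nr - nr // 2, nc - nc // 2  # start of the upper quadrant halves
    riskiness = float(sums[hr:, hc:].mean())
    safety = float(sums[: nr // 2 or 1, : nc // 2 or 1].mean())
    high_action = float((sums > high_sum).mean())
    low_action = float((sums < low_sum).mean())
    ginis = np.empty((nr, nc))
    for i in range(nr):
        for j in range(nc):
            try:
                ginis[i, j] = gini_coefficient(grid[i, j])
            except UndefinedStatisticError:
                ginis[i, j] = np.nan
    with np.errstate(invalid="ignore"):
        exploit = float(np.nanmean(ginis > high_gini))
        explore = float(np.nanmean(ginis < low_gini))
    return ValuationProfile(
        riskiness=riskiness,
        safety=safety,
        high_action=high_action,
        low_action=low_action,
        exploit=exploit,
        explore=explore,
        thresholds={
            "high_sum": high_sum,
            "low_sum": low_sum,
            "high_gini": high_gini,
            "low_gini": low_gini,
        },
    )


def outlier_rate(groups: dict, decile: float = 0.10) -> dict:
    """Per-group fraction of scores in the global top decile.

    ``groups`` maps group label -> 1-D array of scores. The decile cut is
    taken over the pooled scores, so the observation-weighted mean of the
    returned fractions is ~``decile`` by construction.
    """
    if len(groups) < 2:
        raise InvalidParameterError("need >= 2 groups")
    pooled = np.concatenate([np.atleast_1d(np.asarray(v, float)) for v in groups.values()])
    if pooled.size < 10:
        raise InvalidParameterError("need >= 10 total observations")
    cutoff = np.quantile(pooled, 1.0 - decile)
    return {
        k: float((np.atleast_1d(np.asarray(v, float)) > cutoff).mean())
        for k, v in groups.items()
    }
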