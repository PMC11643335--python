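"""Between-trial circuit adaptation on the decision-space landscape.

The advantage of operating the circuit at activity x is a score-weighted sum
over all 2^q possible decision-spaces of their formation probabilities,

    advantage(x) = sum_l score_l P(space_l | x),

with independent per-dimension gates so P(space_l | x) factorizes over the
mask bits. Moving the circuit away from its baseline carries a quadratic-
distance cost, and the net advantage is

    net(x) = advantage(x) - constant * ||x - x_baseline||.

Between trials the baseline activity ascends the net-advantage gradient
(central finite differences) at a fixed rate, auto-halved whenever a step
would overshoot downhill. The incubation simulation raises the score of an
exposure-linked ("rare") decision-space after an exposure event and follows
two initial baselines; depending on their attraction basins they end
vulnerable (rare space forming frequently) or resilient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import rng_for
from .exceptions import InvalidParameterError, ShapeError, StriodmError

__all__ = [
    "AdvantageModel",
    "AdaptationTrajectory",
    "enumerate_spaces",
    "space_probabilities",
    "advantage",
    "cost",
    "net_advantage",
    "adapt_trajectory",
    "incubation_simulation",
]

MAX_EXACT_Q = 12


def enumerate_spaces(q: int) -> np.ndarray:
    """All 2^q decision-space masks, ordered by binary code (bit i = dim i)."""
    if q > MAX_EXACT_Q:
        raise InvalidParameterError(
            f"exact enumeration capped at q={MAX_EXACT_Q}; got q={q}"
        )
    codes = np.arange(2**q)
    return (codes[:, None] >> np.arange(q)) & 1


@dataclass
class AdvantageModel:
    """Scores per decision-space plus the gate-probability model.

    ``gate_probs(x)`` maps an activity vector to per-dimension inclusion
    probabilities; ``advantage_fn`` optionally overrides the score-weighted
    form with an analytic landscape (used for constructed test landscapes).
    """

    scores: np.ndarray
    gate_probs: object = None
    cost_constant: float = 0.0
    rate: float = 0.1
    baseline: np.ndarray = None
    advantage_fn: object = None

    def __post_init__(self):
        self.scores = np.atleast_1d(np.asarray(self.scores, dtype=float))
        n = self.scores.size
        if self.advantage_fn is None:
            q = int(np.log2(n))
            if 2**q != n:
                raise InvalidParameterError("scores length must be a power of two")
            self.q = q
            self.masks = enumerate_spaces(q)
        if self.cost_constant < 0:
            raise InvalidParameterError("cost_constant must be >= 0")
        if self.rate <= 0:
            raise InvalidParameterError("rate must be > 0")
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=float)


def space_probabilities(probs: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """P(space_l) for every mask under independent per-dimension gates."""
    p = np.asarray(probs, dtype=float)
    return np.prod(np.where(masks == 1, p, 1.0 - p), axis=1)


def advantage(x, m: AdvantageModel) -> float:
    """Score-weighted sum of decision-space formation probabilities."""
    if m.advantage_fn is not None:
        return float(m.advantage_fn(np.asarray(x, dtype=float)))
    p = np.asarray(m.gate_probs(np.asarray(x, dtype=float)), dtype=float)
    pl = space_probabilities(p, m.masks)
    total = pl.sum()
    if abs(total - 1.0) > 1e-10:
        raise StriodmError(
            f"decision-space probabilities sum to {total!r}, not 1"
        )
    return float(m.scores @ pl)


def cost(x, baseline) -> float:
    """Euclidean distance between circuit activity and its baseline."""
    x = np.asarray(x, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if x.shape != baseline.shape:
        raise ShapeError("activity and baseline must have equal shape")
    return float(np.linalg.norm(x - baseline))


def net_advantage(x, m: AdvantageModel) -> float:
    """advantage(x) minus the weighted distance-to-baseline cost."""
    base = m.baseline if m.baseline is not None else np.asarray(x, dtype=float)
    return advantage(x, m) - m.cost_constant * cost(x, base)


def _gradient(f, x, step=1e-4):
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = step
        g[i] = (f(x + e) - f(x - e)) / (2 * step)
    return g


@dataclass
class AdaptationTrajectory:
    """Baseline activities across trials with their (net) advantage and cost."""

    baselines: np.ndarray
    advantage: np.ndarray
    cost: np.ndarray
    net_advantage: np.ndarray
    rate_final: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.baselines, columns=[f"x{i}" for i in range(self.baselines.shape[1])]
        )
        df.insert(0, "trial", np.arange(len(df)))
        df["advantage"] = self.advantage
        df["cost"] = self.cost
        df["net_advantage"] = self.net_advantage
        return df


def adapt_trajectory(
    x0, m: AdvantageModel, n_trials: int, fd_step: float = 1e-4
) -> AdaptationTrajectory:
    """Gradient-ascent adaptation of the baseline circuit activity.

    Per trial the baseline moves by rate * grad(net advantage); whenever a
    step would decrease net advantage the rate is halved (with a warning the
    first time), so the recorded net advantage is non-decreasing.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    x = np.asarray(x0, dtype=float).copy()
    anchor = m.baseline if m.baseline is not None else x.copy()
    mm = AdvantageModel(
        scores=m.scores,
        gate_probs=m.gate_probs,
        cost_constant=m.cost_constant,
        rate=m.rate,
        baseline=anchor,
        advantage_fn=m.advantage_fn,
    )
    f = lambda z: net_advantage(z, mm)
    rate = m.rate
    warned = False
    xs = [x.copy()]
    vals = [f(x)]
    for _ in range(n_trials):
        g = _gradient(f, x, fd_step)
        for _halving in range(60):
            x_new = x + rate * g
            v_new = f(x_new)
            if v_new >= vals[-1] - 1e-12:
                break
            if not warned:
                warnings.warn("adaptation rate too large; halving", RuntimeWarning)
                warned = True
            rate *= 0.5
        else:
            x_new, v_new = x, vals[-1]
        x = x_new
        xs.append(x.copy())
        vals.append(v_new)
    xs = np.asarray(xs)
    adv = np.array([advantage(z, mm) for z in xs])
    cst = np.array([cost(z, anchor) for z in xs])
    return AdaptationTrajectory(
        baselines=xs,
        advantage=adv,
        cost=cst,
        net_advantage=np.asarray(vals),
        rate_final=rate,
    )


def incubation_simulation(
    scenario: dict,
    baselines,
    m: AdvantageModel,
    n_trials: int,
    seed=0,
) -> dict:
    """Exposure/incubation simulation over two initial circuit baselines.

    ``scenario`` keys: ``exposure_trial`` (int or None), ``rare_space``
    (mask index), ``boost`` (score added to the rare space's target after
    exposure), ``score_lr`` (EMA rate at which scores track their target),
    ``classify_threshold`` and ``window`` (classification of the final
    rare-space formation probability).

    Returns per-trial rare-space formation probabilities and sampled
    formations for each baseline, plus a vulnerable/resilient classification.
    """
    if m.advantage_fn is not None:
        raise InvalidParameterError("incubation requires a gate-probability model")
    exposure = scenario.get("exposure_trial")
    rare = int(scenario["rare_space"])
    boost = float(scenario.get("boost", 1.0))
    score_lr = float(scenario.get("score_lr", 0.2))
    threshold = float(scenario.get("classify_threshold", 0.25))
    window = int(scenario.get("window", max(1, n_trials // 10)))
    rng = rng_for(seed)
    results = {}
    for b_idx, x0 in enumerate(np.atleast_2d(np.asarray(baselines, dtype=float))):
        scores = m.scores.copy()
        target = m.scores.copy()
        x = x0.copy()
        rows = []
        rate = m.rate
        for t in range(n_trials):
            if exposure is not None and t == exposure:
                target = target.copy()
                target[rare] += boost
            scores = scores + score_lr * (target - scores)
            mt = AdvantageModel(
                scores=scores,
                gate_probs=m.gate_probs,
                cost_constant=m.cost_constant,
                rate=rate,
                baseline=m.baseline,
                advantage_fn=None,
            )
            f = lambda z: net_advantage(z, mt)
            g = _gradient(f, x)
            x = x + rate * g
            p = np.asarray(m.gate_probs(x), dtype=float)
            p_rare = float(space_probabilities(p, mt.masks)[rare])
            rows.append(
                {
                    "trial": t,
                    "p_rare": p_rare,
                    "formed": bool(rng.random() < p_rare),
                }
            )
        df = pd.DataFrame(rows)
        tail = df.p_rare.tail(window).mean()
        results[b_idx] = {
            "trace": df,
            "final_rare_rate": float(tail),
            "classification": "vulnerable" if tail > threshold else "resilient",
        }
    return results
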