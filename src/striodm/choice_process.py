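"""Race-to-threshold choice model.

Each action value v_j,direct and inaction value v_j,indirect drives a
drift-plus-Wiener (Merton) accumulator

    dY = v dt + sigma dW,   Y(0) = 0,

discretized with a constant time step (Euler-Maruyama). An action j is
eligible if its direct accumulator reaches the threshold h before its
inaction accumulator; among eligible actions the earliest hitter is enacted.
If no accumulator reaches h before t_max, or no action is eligible, nothing
is chosen.

For noisy races the first passage between grid points is resolved with a
Brownian-bridge crossing test (the standard correction for discretely
monitored first-passage problems); with sigma = 0 hitting happens exactly on
the grid, at ceil((h/v)/dt)*dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._utils import rng_for
from .exceptions import InvalidParameterError, UndefinedStatisticError

__all__ = [
    "RaceConfig",
    "RaceOutcome",
    "first_passage_times",
    "simulate_race",
    "deliberation_skewness",
    "deliberation_distribution",
]


@dataclass
class RaceConfig:
    """Noise scale, threshold, step size and censoring horizon of the race."""

    sigma: float = 0.2
    h: float = 1.0
    dt: float = 0.01
    t_max: float = 100.0
    #: Brownian-bridge sub-step crossing detection (only meaningful for sigma > 0).
    bridge: bool = True

    def __post_init__(self):
        if self.h <= 0:
            raise InvalidParameterError(f"threshold h must be > 0, got {self.h}")
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")
        if self.t_max <= self.dt:
            raise InvalidParameterError("t_max must exceed dt")


@dataclass
class RaceOutcome:
    """Result of one race: chosen action (or None) and per-process hit times."""

    chosen_action: int | None
    t_action: np.ndarray
    t_inaction: np.ndarray
    censored_action: np.ndarray
    censored_inaction: np.ndarray
    deliberation_time: float | None = None
    trajectories: dict | None = None


def first_passage_times(drifts, cfg: RaceConfig, seed, n_paths: int | None = None):
    """First-passage times of independent accumulators to the threshold h.

    Parameters
    ----------
    drifts : scalar or (n,) array
        Drift v per path. With a scalar drift, ``n_paths`` replicates it.
    Returns
    -------
    times : (n,) array, censored paths set to t_max
    censored : (n,) bool array
    """
    v = np.atleast_1d(np.asarray(drifts, dtype=float))
    if n_paths is not None:
        if v.size != 1:
            raise InvalidParameterError("n_paths only valid with a scalar drift")
        v = np.full(n_paths, v[0])
    n = v.size
    rng = rng_for(seed)

    if cfg.sigma == 0.0:
        # Deterministic ramp: hits iff v > 0 and h/v within the horizon,
        # exactly at the first grid point where v*k*dt >= h.
        times = np.full(n, cfg.t_max)
        censored = np.ones(n, dtype=bool)
        pos = v > 0
        k = np.ceil(cfg.h / (v[pos] * cfg.dt) - 1e-12)
        t_hit = k * cfg.dt
        ok = t_hit <= cfg.t_max
        idx = np.flatnonzero(pos)[ok]
        times[idx] = t_hit[ok]
        censored[idx] = False
        return times, censored

    y = np.zeros(n)
    times = np.full(n, cfg.t_max)
    censored = np.ones(n, dtype=bool)
    active = np.arange(n)
    sdt = cfg.sigma * np.sqrt(cfg.dt)
    n_steps = int(np.ceil(cfg.t_max / cfg.dt))
    for step in range(n_steps):
        t0 = step * cfg.dt
        dy = v[active] * cfg.dt + sdt * rng.standard_normal(active.size)
        y_new = y + dy
        hit = y_new >= cfg.h
        if cfg.bridge:
            # Crossing between grid points: for a Brownian bridge tied at
            # (y, y_new) below h, P(max >= h) = exp(-2 (h-y)(h-y_new)/(sigma^2 dt)).
            gap0 = cfg.h - y
            gap1 = cfg.h - y_new
            with np.errstate(over="ignore"):
                p_cross = np.exp(
                    -2.0 * np.clip(gap0, 0, None) * np.clip(gap1, 0, None)
                    / (cfg.sigma**2 * cfg.dt)
                )
            bridge_hit = (~hit) & (rng.random(active.size) < p_cross)
        else:
            bridge_hit = np.zeros(active.size, dtype=bool)
        if hit.any():
            frac = (cfg.h - y[hit]) / np.maximum(dy[hit], 1e-300)
            frac = np.clip(frac, 0.0, 1.0)
            idx = active[hit]
            times[idx] = t0 + frac * cfg.dt
            censored[idx] = False
        if bridge_hit.any():
            idx = active[bridge_hit]
            times[idx] = t0 + 0.5 * cfg.dt
            censored[idx] = False
        keep = ~(hit | bridge_hit)
        y = y_new[keep]
        active = active[keep]
        if active.size == 0:
            break
    return times, censored


def simulate_race(values, cfg: RaceConfig, seed) -> RaceOutcome:
    """Run one race between paired action/inaction accumulators.

    ``values`` is the (direct, indirect) ActionValueSet pair; both must cover
    the same actions. Ties between simultaneous hitters resolve to the lowest
    action index.
    """
    v_direct, v_indirect = values
    vd = np.atleast_1d(np.asarray(getattr(v_direct, "values", v_direct), dtype=float))
    vi = np.atleast_1d(np.asarray(getattr(v_indirect, "values", v_indirect), dtype=float))
    if vd.shape != vi.shape:
        raise InvalidParameterError("direct and indirect pathways must cover equal action sets")
    rng = rng_for(seed)
    t_all, cens_all = first_passage_times(np.concatenate([vd, vi]), cfg, rng)
    n = vd.size
    t_act, t_inact = t_all[:n], t_all[n:]
    c_act, c_inact = cens_all[:n], cens_all[n:]
    eligible = (~c_act) & (t_act < t_inact)
    if eligible.any():
        # earliest eligible hitter; np.argmin takes the lowest index on ties
        j = int(np.argmin(np.where(eligible, t_act, np.inf)))
        chosen, t_delib = j, float(t_act[j])
    else:
        chosen, t_delib = None, None
    return RaceOutcome(
        chosen_action=chosen,
        t_action=t_act,
        t_inaction=t_inact,
        censored_action=c_act,
        censored_inaction=c_inact,
        deliberation_time=t_delib,
    )


def deliberation_skewness(times) -> float:
    """Adjusted Fisher-Pearson sample skewness of deliberation times.

    The model's proxy for task difficulty: harder tasks produce more
    right-skewed deliberation-time distributions.
    """
    t = np.asarray(times, dtype=float)
    t = t[np.isfinite(t)]
    if t.size < 3:
        raise UndefinedStatisticError("skewness needs >= 3 finite samples")
    if np.var(t) == 0:
        raise UndefinedStatisticError("skewness undefined for zero-variance sample")
    return float(stats.skew(t, bias=False))


def deliberation_distribution(values, cfg: RaceConfig, n: int, seed) -> dict:
    """Sample n independent races and summarize the deliberation times.

    Returns the per-trial times (NaN when no action was enacted) together
    with mean, skewness (None when undefined), the fraction of trials with no
    enacted action, and per-action choice fractions.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    v_direct, v_indirect = values
    vd = np.atleast_1d(np.asarray(getattr(v_direct, "values", v_direct), dtype=float))
    vi = np.atleast_1d(np.asarray(getattr(v_indirect, "values", v_indirect), dtype=float))
    rng = rng_for(seed)
    n_actions = vd.size
    t_act = np.empty((n, n_actions))
    t_inact = np.empty((n, n_actions))
    c_act = np.empty((n, n_actions), dtype=bool)
    for j in range(n_actions):
        t_act[:, j], c_act[:, j] = first_passage_times(vd[j], cfg, rng, n_paths=n)
        t_inact[:, j], _ = first_passage_times(vi[j], cfg, rng, n_paths=n)
    eligible = (~c_act) & (t_act < t_inact)
    t_eligible = np.where(eligible, t_act, np.inf)
    winner = np.argmin(t_eligible, axis=1)
    any_eligible = eligible.any(axis=1)
    times = np.full(n, np.nan)
    times[any_eligible] = t_eligible[any_eligible, winner[any_eligible]]
    finite = times[np.isfinite(times)]
    try:
        skew = deliberation_skewness(finite) if finite.size else None
    except UndefinedStatisticError:
        skew = None
    choice_counts = np.bincount(winner[any_eligible], minlength=n_actions)
    return {
        "times": times,
        "mean": float(np.mean(finite)) if finite.size else None,
        "skewness": skew,
        "no_action_fraction": float(1.0 - any_eligible.mean()),
        "choice_fractions": choice_counts / n,
    }
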