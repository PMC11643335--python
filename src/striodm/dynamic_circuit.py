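"""Dynamic circuit instance: coupled rate ODEs with dopamine feedback,
striosome->daSNC plasticity, and thresholded dopamine gating over time.

Per decision-dimension i and pathway P:

    tau ds_sSPN/dt = -s_sSPN + x - w_da->sSPN (y - 1/2)
    tau ds_mSPN/dt = -s_mSPN + x + w_da->mSPN (y - 1/2)
        dw_sd/dt   = kappa * s_sSPN
    y = sigmoid( -( w_sd s_sSPN + RMTg - z_daSNC ) )
    gate: direct dimension on when y >= threshold,
          indirect dimension on when y < threshold.

Dopamine feedback enters sSPN and mSPN with opposite signs (dopamine
lengthens direct-matrix upstates and shortens indirect-matrix upstates).
The direct pathway's striosomes inhibit their daSNC subpopulation
(w_sd > 0); the indirect pathway's disinhibit theirs (w_sd < 0), and its
gate polarity is inverted: dopamine recruits direct decision-dimensions and
releases indirect ones, so low dopamine yields a low-dimensional direct
space alongside a high-dimensional indirect space.

Integration is explicit Euler by default (RK4 behind a flag) with a
divergence guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import sigmoid
from .exceptions import DivergenceError, InvalidParameterError

__all__ = [
    "DynamicParams",
    "DynamicState",
    "step_dynamics",
    "simulate_dynamics",
    "run_prediction_error_protocol",
    "run_rebound_protocol",
    "pathway_dimensionality_sweep",
]

PATHWAYS = ("direct", "indirect")
DIVERGENCE_GUARD = 1e6


@dataclass
class DynamicParams:
    """Time constants, couplings and gating of the dynamic instance.

    Arrays are (q, 2): one column per pathway (direct, indirect).
    """

    q: int = 4
    tau: float = 0.5
    dt: float = 0.0025
    kappa: float = 0.0
    w_da_to_sspn: np.ndarray | float = 0.0
    w_da_to_mspn: np.ndarray | float = 0.0
    w_sd0: np.ndarray | None = None
    z_dasnc: np.ndarray | float = 0.0
    gate_threshold: float = 0.5
    rmtg: float = 0.0
    method: str = "euler"
    #: plasticity epoch mask: callable t -> bool, None = continuous
    plasticity_mask: object = None

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidParameterError("tau must be > 0")
        if not self.dt < self.tau / 5:
            raise InvalidParameterError("stability guard: dt must be < tau/5")
        if self.w_sd0 is None:
            # striosomal inhibition on the direct pathway, disinhibition indirect
            self.w_sd0 = np.column_stack([np.ones(self.q), -np.ones(self.q)])
        self.w_sd0 = np.asarray(self.w_sd0, dtype=float)
        self.z_dasnc = np.broadcast_to(
            np.asarray(self.z_dasnc, dtype=float), (self.q, 2)
        ).copy()
        self.w_da_to_sspn = np.broadcast_to(
            np.asarray(self.w_da_to_sspn, dtype=float), (self.q, 2)
        ).copy()
        self.w_da_to_mspn = np.broadcast_to(
            np.asarray(self.w_da_to_mspn, dtype=float), (self.q, 2)
        ).copy()


@dataclass
class DynamicState:
    """Instantaneous circuit state; arrays are (q, 2)."""

    s_sspn: np.ndarray
    s_mspn: np.ndarray
    w_sd: np.ndarray
    y: np.ndarray
    gate: np.ndarray
    t: float = 0.0

    @classmethod
    def initial(cls, p: DynamicParams) -> "DynamicState":
        zeros = np.zeros((p.q, 2))
        state = cls(
            s_sspn=zeros.copy(),
            s_mspn=zeros.copy(),
            w_sd=p.w_sd0.copy(),
            y=np.zeros((p.q, 2)),
            gate=np.zeros((p.q, 2), dtype=int),
        )
        state.y = _dasnc_output(state.s_sspn, state.w_sd, p)
        state.gate = _gates(state.y, p)
        return state


def _dasnc_output(s_sspn, w_sd, p: DynamicParams):
    return sigmoid(-(w_sd * s_sspn + p.rmtg - p.z_dasnc))


def _gates(y, p: DynamicParams):
    gate = np.empty_like(y, dtype=int)
    gate[:, 0] = y[:, 0] >= p.gate_threshold
    gate[:, 1] = y[:, 1] < p.gate_threshold  # dopamine releases indirect dims
    return gate


def _derivatives(s_sspn, s_mspn, w_sd, x, p: DynamicParams, plastic: bool):
    y = _dasnc_output(s_sspn, w_sd, p)
    ds = (-s_sspn + x - p.w_da_to_sspn * (y - 0.5)) / p.tau
    dm = (-s_mspn + x + p.w_da_to_mspn * (y - 0.5)) / p.tau
    dw = p.kappa * s_sspn if plastic else np.zeros_like(w_sd)
    return ds, dm, dw


def step_dynamics(state: DynamicState, x_t, p: DynamicParams) -> DynamicState:
    """Advance the circuit one time step.

    ``x_t`` is the FSI-normalized cortical drive, broadcastable to (q, 2).
    """
    x = np.broadcast_to(np.asarray(x_t, dtype=float), (p.q, 2))
    plastic = p.kappa != 0.0 and (
        p.plasticity_mask is None or bool(p.plasticity_mask(state.t))
    )
    if p.method == "rk4":
        args = (x, p, plastic)
        k1 = _derivatives(state.s_sspn, state.s_mspn, state.w_sd, *args)
        k2 = _derivatives(
            state.s_sspn + 0.5 * p.dt * k1[0],
            state.s_mspn + 0.5 * p.dt * k1[1],
            state.w_sd + 0.5 * p.dt * k1[2],
            *args,
        )
        k3 = _derivatives(
            state.s_sspn + 0.5 * p.dt * k2[0],
            state.s_mspn + 0.5 * p.dt * k2[1],
            state.w_sd + 0.5 * p.dt * k2[2],
            *args,
        )
        k4 = _derivatives(
            state.s_sspn + p.dt * k3[0],
            state.s_mspn + p.dt * k3[1],
            state.w_sd + p.dt * k3[2],
            *args,
        )
        s_new = state.s_sspn + p.dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        m_new = state.s_mspn + p.dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        w_new = state.w_sd + p.dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    else:
        ds, dm, dw = _derivatives(state.s_sspn, state.s_mspn, state.w_sd, x, p, plastic)
        s_new = state.s_sspn + p.dt * ds
        m_new = state.s_mspn + p.dt * dm
        w_new = state.w_sd + p.dt * dw
    worst = max(np.abs(s_new).max(), np.abs(m_new).max())
    if worst > DIVERGENCE_GUARD:
        dim = int(np.unravel_index(np.abs(s_new).argmax(), s_new.shape)[0])
        raise DivergenceError(
            f"activity exceeded {DIVERGENCE_GUARD:g} at t={state.t:.4f}", dimension=dim
        )
    y_new = _dasnc_output(s_new, w_new, p)
    return DynamicState(
        s_sspn=s_new,
        s_mspn=m_new,
        w_sd=w_new,
        y=y_new,
        gate=_gates(y_new, p),
        t=state.t + p.dt,
    )


def simulate_dynamics(p: DynamicParams, x_of_t, t_end: float, record: bool = True):
    """Integrate from rest to ``t_end``; ``x_of_t(t)`` supplies the drive.

    Returns (final_state, history) where history is a tidy DataFrame
    (time, dimension, pathway, variable, value) or None.
    """
    state = DynamicState.initial(p)
    n_steps = int(round(t_end / p.dt))
    rows = [] if record else None
    for _ in range(n_steps):
        state = step_dynamics(state, x_of_t(state.t), p)
        if record:
            rows.append(
                (state.t, state.s_sspn.copy(), state.s_mspn.copy(),
                 state.y.copy(), state.gate.copy())
            )
    history = None
    if record:
        recs = []
        for t, s, m, y, g in rows:
            for i in range(p.q):
                for j, pw in enumerate(PATHWAYS):
                    recs.append((t, i, pw, s[i, j], m[i, j], y[i, j], g[i, j]))
        history = pd.DataFrame(
            recs,
            columns=["time", "dimension", "pathway", "s_sspn", "s_mspn", "y", "gate"],
        )
    return state, history


def run_prediction_error_protocol(
    p: DynamicParams | None = None,
    expected: float = 0.5,
    observed: float = 0.5,
    reward_dim: int = 0,
    switch_time: float = 2.5,
    t_end: float = 5.0,
) -> pd.DataFrame:
    """Reward-information switch protocol.

    A first source drives the reward dimension at the ``expected`` level from
    t=0; at ``switch_time`` a second source replaces it at the ``observed``
    level. The returned table holds each SPN population's activity change
    between just before the switch and its post-switch extremum — the
    emergent prediction-error signal, carried by the reward-dimension
    populations only.
    """
    if p is None:
        p = DynamicParams()

    def x_of_t(t):
        x = np.zeros((p.q, 2))
        x[reward_dim, :] = expected if t < switch_time else observed
        return x

    _, hist = simulate_dynamics(p, x_of_t, t_end)
    pre_t = hist.time[hist.time <= switch_time + p.dt * 0.5].max()
    pre = hist[hist.time == pre_t]
    post = hist[hist.time > switch_time]
    rows = []
    for (dim, pw), grp in post.groupby(["dimension", "pathway"]):
        for comp, col in (("sSPN", "s_sspn"), ("mSPN", "s_mspn")):
            base = float(
                pre[(pre.dimension == dim) & (pre.pathway == pw)][col].iloc[0]
            )
            dev = grp[col].to_numpy() - base
            rows.append(
                {
                    "dimension": dim,
                    "pathway": pw,
                    "compartment": comp,
                    "change": float(dev[np.argmax(np.abs(dev))]),
                    "is_reward_dim": dim == reward_dim,
                }
            )
    return pd.DataFrame(rows)


def run_rebound_protocol(
    p: DynamicParams | None = None,
    rebound: bool = True,
    pulse_amplitude: float = 1.0,
    pulse_duration: float = 1.25,
    kappa: float = 0.3,
    tail: float = 2.5,
) -> dict:
    """Successive single-dimension pulses with and without daSNC rebound.

    Cortical recruitment of a decision-dimension drives its striosomal
    subpopulation BELOW baseline (recruited subpopulations lower their mean
    activity), disinhibiting the corresponding daSNC gate for the pulse.
    With rebound plasticity on, the sustained deviation weakens the
    striosome->daSNC weight (dw/dt = kappa * s with s < 0), so when the pulse
    ends the gate falls back below threshold sooner: returns the per-dimension
    de-prioritization latency (time from pulse end to gate switch-off).
    """
    if p is None:
        p = DynamicParams(z_dasnc=-0.5)
    p = replace(p, kappa=kappa if rebound else 0.0)

    def x_of_t(t):
        x = np.zeros((p.q, 2))
        k = int(t // pulse_duration)
        if 0 <= k < p.q:
            x[k, 0] = -pulse_amplitude  # direct-pathway striosomal suppression
        return x

    t_end = p.q * pulse_duration + tail
    _, hist = simulate_dynamics(p, x_of_t, t_end)
    direct = hist[hist.pathway == "direct"]
    latencies = np.full(p.q, np.nan)
    for i in range(p.q):
        g = direct[direct.dimension == i]
        t_off = g.time[(g.time > (i + 1) * pulse_duration) & (g.gate == 0)]
        if len(t_off):
            latencies[i] = float(t_off.iloc[0]) - (i + 1) * pulse_duration
    return {"latencies": latencies, "history": hist, "rebound": rebound}


def pathway_dimensionality_sweep(
    p: DynamicParams | None = None,
    sweep_target: str = "sspn_offset",
    levels=(-1.0, -0.5, 0.0, 0.5, 1.0),
    settle_time: float = 4.0,
) -> dict:
    """Count gated-on dimensions per pathway across an offset sweep.

    ``sspn_offset`` shifts overall striosomal drive; ``dasnc_offset`` shifts
    all daSNC excitabilities. Per-dimension excitability offsets are staggered
    so that dimensions switch at distinct sweep levels. Reports the Spearman
    correlation between direct and indirect dimensionality across levels:
    positive for striosomal sweeps (both spaces shrink/grow together),
    negative for dopaminergic sweeps (the spaces trade off).
    """
    if sweep_target not in ("sspn_offset", "dasnc_offset"):
        raise InvalidParameterError("sweep_target must be sspn_offset or dasnc_offset")
    if p is None:
        p = DynamicParams()
        # staggered per-dimension daSNC excitabilities; the indirect column is
        # mirrored so both pathways share switch points in sSPN coordinates
        z = np.linspace(-0.75, 0.75, p.q)
        p = replace(p, z_dasnc=np.column_stack([z, -z]))
    levels = np.asarray(levels, dtype=float)
    counts = {"direct": [], "indirect": []}
    for level in levels:
        if sweep_target == "sspn_offset":
            pl = p
            x_const = np.broadcast_to(level, (p.q, 2))
        else:
            pl = replace(p, z_dasnc=p.z_dasnc + level)
            x_const = np.zeros((p.q, 2))
        final, _ = simulate_dynamics(pl, lambda t: x_const, settle_time, record=False)
        counts["direct"].append(int(final.gate[:, 0].sum()))
        counts["indirect"].append(int(final.gate[:, 1].sum()))
    d = np.asarray(counts["direct"])
    i = np.asarray(counts["indirect"])
    degenerate = d.std() == 0 or i.std() == 0 or levels.std() == 0
    rho = None if degenerate else float(stats.spearmanr(d, i).statistic)
    return {
        "levels": levels,
        "direct": d,
        "indirect": i,
        "spearman": rho,
        "degenerate": degenerate,
    }
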