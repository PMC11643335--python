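"""Feedforward full-connectivity circuit instance.

Maps cortical activity through FSI divisive normalization onto striosomal
projection neurons (sSPNs), combines the striosomal signal through the
GPi -> LHb -> RMTg relay, gates nigral dopamine subpopulations (daSNC) that
probabilistically select decision-dimensions, and finally computes matrix
(mSPN) activity and logistic action values on the selected decision-space.

The circuit per pathway P (direct or indirect) is

    s_sSPN = (1/c) W^T x + b_sSPN                    (FSI-normalized projection)
    RMTg   = z_RMTg + z_LHb + z_GPi (w_GPi . [s_d; s_i])
    daSNC_i = 1 / (1 + exp(w_sd,i s_i + RMTg - z_i))  (striosomal inhibition)
    S_ii   ~ Bernoulli(daSNC_i)                       (decision-space mask)
    m_sSPN = (1/c) S W^T x
    v_j    = 1 / (1 + exp(-(beta_j . m - alpha_j)))   (action value)

The indirect pathway can carry a negated striosome->daSNC weight so that
isSPN activity disinhibits its daSNC subpopulation, as the circuit anatomy
(striosome -> GPe -> daSNC) suggests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_1d, rng_for, sigmoid
from .exceptions import InvalidParameterError, ShapeError

__all__ = [
    "CortexInput",
    "PathwayWeights",
    "StriosomeActivity",
    "PallidoHabenularParams",
    "DopamineGate",
    "DecisionSpace",
    "ActionValueSet",
    "CircuitParameters",
    "compute_sspn",
    "compute_rmtg",
    "compute_dasnc",
    "sample_decision_space",
    "compute_mspn",
    "compute_action_values",
    "gating_probabilities",
    "expected_dimensionality_sweep",
    "psychometric_sweep",
]

#: Default number of decision-dimensions (the leading principal components of
#: cortical activity retained by the striosomal mapping).
DEFAULT_Q = 4


@dataclass
class CortexInput:
    """Cortical firing levels feeding one pathway."""

    activity: np.ndarray
    pathway: str = "direct"

    def __post_init__(self):
        self.activity = as_1d(self.activity, "cortical activity")


@dataclass
class PathwayWeights:
    """Cortex->sSPN mapping: weight matrix W, FSI normalization c, shift b."""

    W: np.ndarray
    c: float = 1.0
    b_sspn: float = 0.0

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.c <= 0:
            raise InvalidParameterError(f"FSI normalization c must be > 0, got {self.c}")

    @property
    def q(self) -> int:
        return self.W.shape[1]


@dataclass
class StriosomeActivity:
    """Per-decision-dimension sSPN activity for one pathway."""

    s: np.ndarray
    pathway: str = "direct"

    def __post_init__(self):
        self.s = as_1d(self.s, "sSPN activity")


@dataclass
class PallidoHabenularParams:
    """GPi/LHb/RMTg relay parameters (single scalar output shifting all gates)."""

    w_gpi: np.ndarray
    z_gpi: float = 0.0
    z_lhb: float = 0.0
    z_rmtg: float = 0.0

    def __post_init__(self):
        self.w_gpi = as_1d(self.w_gpi, "w_GPi")


@dataclass
class DopamineGate:
    """Per-dimension striosome->daSNC weights, shifts, and activation probs."""

    w_sd: np.ndarray
    z_dasnc: np.ndarray
    probs: np.ndarray | None = None

    def __post_init__(self):
        self.w_sd = as_1d(self.w_sd, "w_sd")
        self.z_dasnc = as_1d(self.z_dasnc, "z_daSNC")
        if self.w_sd.shape != self.z_dasnc.shape:
            raise ShapeError("w_sd and z_daSNC must have equal length")


@dataclass
class DecisionSpace:
    """Binary selection mask over decision-dimensions (diagonal of S_P)."""

    mask: np.ndarray
    pathway: str = "direct"
    probs: np.ndarray | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if not np.isin(self.mask, (0, 1)).all():
            raise InvalidParameterError("decision-space mask entries must be 0/1")
        self.mask = self.mask.astype(int)

    @property
    def dimensionality(self) -> int:
        return int(self.mask.sum())


@dataclass
class ActionValueSet:
    """Logistic action values v_j in (0,1) with their coefficients and priors."""

    values: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    pathway: str = "direct"


def compute_sspn(x: CortexInput, w: PathwayWeights) -> StriosomeActivity:
    """FSI-normalized striosomal projection: s = (1/c) W^T x + b_sSPN."""
    xv = x.activity
    if xv.shape[0] != w.W.shape[0]:
        raise ShapeError(
            f"cortical activity length {xv.shape[0]} != W rows {w.W.shape[0]}"
        )
    s = w.W.T @ xv / w.c + w.b_sspn
    return StriosomeActivity(s=s, pathway=x.pathway)


def compute_rmtg(
    s_direct: StriosomeActivity,
    s_indirect: StriosomeActivity,
    p: PallidoHabenularParams,
) -> float:
    """RMTg drive: z_RMTg + z_LHb + z_GPi * (w_GPi . [s_direct; s_indirect])."""
    s_cat = np.concatenate([s_direct.s, s_indirect.s])
    if s_cat.shape != p.w_gpi.shape:
        raise ShapeError(
            f"concatenated sSPN length {s_cat.shape[0]} != w_GPi length {p.w_gpi.shape[0]}"
        )
    return float(p.z_rmtg + p.z_lhb + p.z_gpi * (p.w_gpi @ s_cat))


def compute_dasnc(s: StriosomeActivity, g: DopamineGate, rmtg: float) -> DopamineGate:
    """daSNC activation probabilities: 1/(1+exp(w_sd s + RMTg - z_daSNC)).

    Positive ``w_sd`` realizes striosomal inhibition of dopamine (activation
    falls as sSPN activity rises); a negated weight realizes the indirect
    pathway's disinhibition.
    """
    if s.s.shape != g.w_sd.shape:
        raise ShapeError("sSPN activity and w_sd must have equal length")
    probs = sigmoid(-(g.w_sd * s.s + rmtg - g.z_dasnc))
    return DopamineGate(w_sd=g.w_sd, z_dasnc=g.z_dasnc, probs=probs)


def sample_decision_space(g: DopamineGate, seed, pathway: str = "direct") -> DecisionSpace:
    """Draw the decision-space mask: S_ii ~ Bernoulli(daSNC_i), independently."""
    if g.probs is None:
        raise InvalidParameterError("DopamineGate.probs not filled; call compute_dasnc first")
    probs = np.asarray(g.probs, dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise InvalidParameterError("gate probabilities must lie in [0, 1]")
    rng = rng_for(seed)
    mask = (rng.random(probs.shape) < probs).astype(int)
    return DecisionSpace(mask=mask, pathway=pathway, probs=probs)


def compute_mspn(x: CortexInput, w: PathwayWeights, ds: DecisionSpace) -> np.ndarray:
    """Matrix SPN activity on the selected space: m = (1/c) S W^T x.

    Dimensions outside the decision-space are exactly zero; the b_sSPN shift
    does not apply to mSPNs.
    """
    if ds.mask.shape[0] != w.q:
        raise ShapeError("decision-space mask length must equal number of dimensions")
    xv = x.activity
    if xv.shape[0] != w.W.shape[0]:
        raise ShapeError("cortical activity length must equal W rows")
    return ds.mask * (w.W.T @ xv) / w.c


def compute_action_values(
    mspn: np.ndarray, beta: np.ndarray, alpha: np.ndarray, pathway: str = "direct"
) -> ActionValueSet:
    """Logistic action values v_j = sigmoid(beta_j . m - alpha_j)."""
    mspn = as_1d(mspn, "mSPN activity")
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if beta.shape[1] != mspn.shape[0]:
        raise ShapeError("beta rows must match mSPN length")
    if alpha.shape[0] != beta.shape[0]:
        raise ShapeError("one alpha per action required")
    values = sigmoid(beta @ mspn - alpha)
    return ActionValueSet(values=values, beta=beta, alpha=alpha, pathway=pathway)


@dataclass
class CircuitParameters:
    """All static parameters of one feedforward circuit instance.

    Defaults follow the model's reference configuration: q = 4
    decision-dimensions, identity cortical mapping, unit FSI activity,
    striosomal inhibition of dopamine on the direct pathway and disinhibition
    (negated weight) on the indirect pathway, and action-value coefficients
    held constant across analyses (beta = 1 per dimension, alpha = 0.5).
    """

    q: int = DEFAULT_Q
    weights_direct: PathwayWeights = None
    weights_indirect: PathwayWeights = None
    pallido: PallidoHabenularParams = None
    gate_direct: DopamineGate = None
    gate_indirect: DopamineGate = None
    beta: np.ndarray = None
    alpha: np.ndarray = None
    beta_indirect: np.ndarray = None
    alpha_indirect: np.ndarray = None

    def __post_init__(self):
        q = self.q
        if self.weights_direct is None:
            self.weights_direct = PathwayWeights(W=np.eye(q))
        if self.weights_indirect is None:
            self.weights_indirect = PathwayWeights(W=np.eye(q))
        if self.pallido is None:
            self.pallido = PallidoHabenularParams(w_gpi=np.full(2 * q, 0.25))
        if self.gate_direct is None:
            self.gate_direct = DopamineGate(w_sd=np.ones(q), z_dasnc=np.zeros(q))
        if self.gate_indirect is None:
            self.gate_indirect = DopamineGate(w_sd=-np.ones(q), z_dasnc=np.zeros(q))
        if self.beta is None:
            self.beta = np.ones((1, q))
        if self.alpha is None:
            self.alpha = np.full(np.atleast_2d(self.beta).shape[0], 0.5)
        if self.beta_indirect is None:
            # restraint read-out weights the cost dimension (dimension 1)
            bi = np.zeros((1, q))
            bi[0, min(1, q - 1)] = 1.0
            self.beta_indirect = bi
        if self.alpha_indirect is None:
            self.alpha_indirect = np.full(
                np.atleast_2d(self.beta_indirect).shape[0], 0.5
            )


def gating_probabilities(
    x: np.ndarray, params: CircuitParameters, b_sspn: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Direct and indirect daSNC activation probabilities for cortical input x.

    Runs the deterministic part of the pipeline (sSPN -> RMTg -> daSNC) for
    both pathways; ``b_sspn`` optionally overrides the shared activity shift.
    """
    wd, wi = params.weights_direct, params.weights_indirect
    if b_sspn is not None:
        wd = PathwayWeights(W=wd.W, c=wd.c, b_sspn=b_sspn)
        wi = PathwayWeights(W=wi.W, c=wi.c, b_sspn=b_sspn)
    s_d = compute_sspn(CortexInput(x, "direct"), wd)
    s_i = compute_sspn(CortexInput(x, "indirect"), wi)
    rmtg = compute_rmtg(s_d, s_i, params.pallido)
    g_d = compute_dasnc(s_d, params.gate_direct, rmtg)
    g_i = compute_dasnc(s_i, params.gate_indirect, rmtg)
    return g_d.probs, g_i.probs


def expected_dimensionality_sweep(
    params: CircuitParameters,
    b_values,
    x: np.ndarray | None = None,
    pathway: str = "direct",
) -> pd.DataFrame:
    """Expected decision-space dimensionality (sum of gate probs) across a
    sweep of the overall sSPN activity shift b_sSPN.

    With positive direct-pathway gating weights the expectation is strictly
    decreasing in b_sSPN: higher striosomal activity suppresses dopamine and
    shrinks the direct decision-space.
    """
    x = np.zeros(params.q) if x is None else as_1d(x, "cortical activity")
    rows = []
    for b in b_values:
        pd_probs, pi_probs = gating_probabilities(x, params, b_sspn=float(b))
        probs = pd_probs if pathway == "direct" else pi_probs
        rows.append({"b_sspn": float(b), "expected_dimensionality": float(probs.sum())})
    return pd.DataFrame(rows)


def run_decision_pipeline(
    x: np.ndarray,
    params: CircuitParameters,
    seed,
    forced_mask: np.ndarray | None = None,
):
    """One full pass cortex -> decision-space -> action/inaction values.

    Returns the (direct, indirect) ActionValueSet pair. ``forced_mask``
    bypasses the stochastic gate with a fixed decision-space for both
    pathways (used e.g. to probe one-dimensional reward-only spaces).
    """
    rng = rng_for(seed)
    p_d, p_i = gating_probabilities(x, params)
    if forced_mask is not None:
        ds_d = DecisionSpace(mask=forced_mask, pathway="direct")
        ds_i = DecisionSpace(mask=forced_mask, pathway="indirect")
    else:
        gd = DopamineGate(params.gate_direct.w_sd, params.gate_direct.z_dasnc, p_d)
        gi = DopamineGate(params.gate_indirect.w_sd, params.gate_indirect.z_dasnc, p_i)
        ds_d = sample_decision_space(gd, rng, "direct")
        ds_i = sample_decision_space(gi, rng, "indirect")
    xi_d = CortexInput(x, "direct")
    xi_i = CortexInput(x, "indirect")
    m_d = compute_mspn(xi_d, params.weights_direct, ds_d)
    m_i = compute_mspn(xi_i, params.weights_indirect, ds_i)
    v_d = compute_action_values(m_d, params.beta, params.alpha, "direct")
    v_i = compute_action_values(
        m_i, params.beta_indirect, params.alpha_indirect, "indirect"
    )
    return v_d, v_i


def psychometric_sweep(
    reward_levels,
    params: CircuitParameters | None = None,
    n_trials: int = 200,
    seed=0,
    cost: float = 0.0,
    forced_mask: np.ndarray | None = None,
    race_config=None,
) -> pd.DataFrame:
    """Approach fraction across reward offer levels (psychometric function).

    For each reward level, encodes (reward, cost) on the first two
    decision-dimensions, runs the full pipeline n_trials times, races the
    approach action value against its inaction value, and tabulates the
    fraction of trials in which the approach process won.
    """
    from .choice_process import RaceConfig, simulate_race

    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    if params is None:
        params = CircuitParameters()
    cfg = race_config if race_config is not None else RaceConfig(sigma=0.3, h=1.0)
    rng = rng_for(seed)
    rows = []
    for level in reward_levels:
        x = np.zeros(params.q)
        x[0] = level
        if params.q > 1:
            x[1] = cost
        approached = 0
        for _ in range(n_trials):
            v_d, v_i = run_decision_pipeline(x, params, rng, forced_mask=forced_mask)
            outcome = simulate_race((v_d, v_i), cfg, rng)
            approached += outcome.chosen_action is not None
        rows.append(
            {
                "reward": float(level),
                "cost": float(cost),
                "n_trials": n_trials,
                "approach_fraction": approached / n_trials,
            }
        )
    return pd.DataFrame(rows)
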