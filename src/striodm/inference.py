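"""Inferring decision-spaces from striosomal activity.

Synthetic sessions carry a few environmental inputs (e.g. temperature,
music volume); each session's decision-making phenotype class uses a known
decision-space (a subset of the inputs), and sSPN activity is the
weighted sum of the in-space inputs plus i.i.d. Gaussian noise. Ordinary
least squares per class recovers the generating decision-dimension weights,
and the class using both dimensions has a slope vector that is the sum of
the two one-dimensional classes' slopes. Choices over the input plane are
interpolated by logistic regression; the decision boundary is the locus of
equal fitted action values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from ._utils import rng_for, sigmoid
from .exceptions import InvalidParameterError, ShapeError

__all__ = [
    "SessionDataset",
    "RegressionResult",
    "generate_inference_dataset",
    "infer_decision_dimensions",
    "interpolate_action_values",
]

#: The four reference decision-spaces over two environmental inputs:
#: none, first dimension only, second only, both.
DEFAULT_CLASS_SPACES = {
    "none": (),
    "dim1": (0,),
    "dim2": (1,),
    "both": (0, 1),
}


@dataclass
class SessionDataset:
    """Per-session environmental inputs, sSPN activity, class label, choice."""

    inputs: np.ndarray
    activity: np.ndarray
    labels: np.ndarray
    choices: np.ndarray
    true_weights: np.ndarray | None = None
    class_spaces: dict | None = None

    def __post_init__(self):
        n = self.inputs.shape[0]
        if not (self.activity.shape[0] == self.labels.shape[0] == self.choices.shape[0] == n):
            raise ShapeError("inconsistent session counts across fields")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.inputs, columns=[f"input{i}" for i in range(self.inputs.shape[1])]
        )
        df.insert(0, "session", np.arange(len(df)))
        df["activity"] = self.activity
        df["label"] = self.labels
        df["choice"] = self.choices
        return df


@dataclass
class RegressionResult:
    """Per-class OLS slope estimates with standard errors and diagnostics."""

    weights: dict
    stderr: dict
    r_squared: dict
    residual_var: dict


def generate_inference_dataset(
    n_sessions: int,
    true_weights,
    noise_sd: float,
    seed=0,
    class_spaces: dict | None = None,
    input_scale: float = 1.0,
) -> SessionDataset:
    """Simulate sessions: activity = sum_{i in space} w_i x_i + N(0, noise_sd²).

    Sessions are split evenly across the phenotype classes; each class's
    decision-space selects which environmental inputs reach the striosomal
    activity. Binary choices follow a logistic read-out of the activity.
    """
    if n_sessions < 1:
        raise InvalidParameterError("n_sessions must be >= 1")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    w = np.atleast_1d(np.asarray(true_weights, dtype=float))
    spaces = class_spaces if class_spaces is not None else DEFAULT_CLASS_SPACES
    rng = rng_for(seed)
    names = list(spaces)
    labels = np.array([names[i % len(names)] for i in range(n_sessions)])
    x = input_scale * rng.standard_normal((n_sessions, w.size))
    activity = np.zeros(n_sessions)
    for name, dims in spaces.items():
        sel = labels == name
        for i in dims:
            activity[sel] += w[i] * x[sel, i]
    activity += noise_sd * rng.standard_normal(n_sessions)
    choices = (rng.random(n_sessions) < sigmoid(activity)).astype(int)
    return SessionDataset(
        inputs=x,
        activity=activity,
        labels=labels,
        choices=choices,
        true_weights=w,
        class_spaces=dict(spaces),
    )


def infer_decision_dimensions(
    ds: SessionDataset, intercept: bool = False
) -> RegressionResult:
    """Per-class OLS of activity on the environmental inputs.

    The estimated slope vector of each phenotype class is its hypothesized
    decision-dimension loading; no intercept by default (the generating model
    is homogeneous-linear).
    """
    p = ds.inputs.shape[1]
    weights, stderr, r2, resvar = {}, {}, {}, {}
    for name in dict.fromkeys(ds.labels):
        sel = ds.labels == name
        if sel.sum() < p + 2:
            raise InvalidParameterError(
                f"class {name!r} needs >= {p + 2} sessions, has {int(sel.sum())}"
            )
        X = ds.inputs[sel]
        if intercept:
            X = sm.add_constant(X)
        fit = sm.OLS(ds.activity[sel], X).fit()
        coefs = fit.params[-p:]
        weights[name] = np.asarray(coefs)
        stderr[name] = np.asarray(fit.bse[-p:])
        r2[name] = float(fit.rsquared)
        resvar[name] = float(fit.mse_resid)
    return RegressionResult(
        weights=weights, stderr=stderr, r_squared=r2, residual_var=resvar
    )


def interpolate_action_values(
    inputs, choices, l2_strength: float = 1.0
) -> dict:
    """Two-class logistic interpolation of action values over the input plane.

    Fits an unpenalized logistic regression (maximum likelihood) and falls
    back to an L2-regularized fit when the classes are completely separable.
    Returns the coefficient vector, intercept, standard errors (None under
    the regularized fallback), a ``separated`` flag, and the decision
    boundary {x : w.x + b = 0} where both fitted action values are equal.
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(choices, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise InvalidParameterError("both choice classes must be present")
    separated = False
    coef = intercept = bse = None
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params)
        if np.all(np.isfinite(params)) and np.abs(params).max() < 1e3 and fit.mle_retvals.get("converged", True):
            intercept, coef = float(params[0]), params[1:]
            bse = np.asarray(fit.bse)[1:]
        else:
            separated = True
    except Exception:
        separated = True
    if separated:
        clf = LogisticRegression(C=1.0 / l2_strength)
        clf.fit(X, y)
        coef = clf.coef_[0]
        intercept = float(clf.intercept_[0])
    probs = sigmoid(X @ coef + intercept)
    return {
        "coef": np.asarray(coef, dtype=float),
        "intercept": intercept,
        "stderr": bse,
        "separated": separated,
        "probabilities": probs,
        "boundary": {"normal": np.asarray(coef, dtype=float), "offset": intercept},
    }
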