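"""Logistic-regression stacking meta-classifier over the four sub-models.

The meta-input for one segment is p = (1, p1, ..., p8): an intercept term
followed by the (normal, arousal) probability pairs from the CNN, RNN,
random forest, and pre-merged CNN+RNN sub-models.  The meta-classifier is a
plain logistic regression

    h_beta(p) = exp(p^T beta) / (1 + exp(p^T beta)),

fitted by gradient descent on the unregularized mean cross-entropy

    J(beta) = -(1/M) sum_j [ y_j log h(p_j) + (1 - y_j) log(1 - h(p_j)) ],

from beta = 0, with backtracking line search, stopping when the gradient
infinity-norm drops below tolerance.  A segment is declared an arousal when
h_beta > 0.5 (strictly).

Because each probability pair sums to 1 and an explicit intercept column is
carried, the design matrix is rank-deficient; the cost is still convex and
gradient descent converges to a minimum-J point (the fitted probabilities
are unique even though beta is not).  ``drop_redundant=True`` removes the
"normal" column of each pair for a full-rank parameterization.

Three protocols build the meta-training set: "oof" (k-fold out-of-fold
sub-model predictions, the default), "holdout" (sub-models predict a
dedicated stacking split they were not trained on — blending), and "naive"
(in-sample predictions, for comparison only; leaks training information).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .config import GdConfig

__all__ = [
    "MetaCoefs",
    "logistic",
    "cost",
    "cost_grad",
    "fit_meta",
    "predict_meta",
    "stack_probabilities",
    "META_FEATURE_NAMES",
]

N_META_INPUTS = 8  # 2 probabilities x 4 sub-models
META_FEATURE_NAMES = [
    "intercept",
    "cnn_p_normal", "cnn_p_arousal",
    "rnn_p_normal", "rnn_p_arousal",
    "forest_p_normal", "forest_p_arousal",
    "premerge_p_normal", "premerge_p_arousal",
]

_CLIP = 1e-12  # probability clipping inside the log-loss


@dataclass
class MetaCoefs:
    """Fitted coefficients beta = (beta_0, beta_1, ..., beta_8)."""

    beta: np.ndarray
    feature_names: list[str]
    n_iter: int = 0
    grad_norm: float = np.nan

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "feature_names": self.feature_names,
                    "beta": self.beta.tolist(),
                    "n_iter": self.n_iter,
                    "grad_norm": self.grad_norm,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "MetaCoefs":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            beta=np.asarray(d["beta"], dtype=np.float64),
            feature_names=d["feature_names"],
            n_iter=d.get("n_iter", 0),
            grad_norm=d.get("grad_norm", np.nan),
        )


def stack_probabilities(prob_pairs: list[np.ndarray]) -> np.ndarray:
    """Assemble meta-inputs (M, 9): intercept column then the 4 prob pairs."""
    mats = [np.asarray(p, dtype=np.float64) for p in prob_pairs]
    M = mats[0].shape[0]
    for p in mats:
        if p.shape != (M, 2):
            raise ValueError("each sub-model must contribute an (M, 2) probability array")
    return np.column_stack([np.ones(M)] + mats)


def logistic(P: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """h_beta = exp(p^T beta) / (1 + exp(p^T beta)), overflow-safe."""
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    beta = np.asarray(beta, dtype=np.float64)
    if P.shape[1] != beta.shape[0]:
        raise ValueError(f"dimension mismatch: inputs {P.shape[1]} vs beta {beta.shape[0]}")
    z = P @ beta
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cost(P: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Mean cross-entropy J(beta); probabilities clipped away from 0 and 1."""
    P = np.atleast_2d(P)
    y = np.asarray(y, dtype=np.float64)
    if len(y) == 0:
        raise ValueError("empty training set")
    h = np.clip(logistic(P, beta), _CLIP, 1.0 - _CLIP)
    return float(-np.mean(y * np.log(h) + (1.0 - y) * np.log(1.0 - h)))


def cost_grad(P: np.ndarray, y: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Gradient of J: (1/M) P^T (h - y)."""
    P = np.atleast_2d(P)
    y = np.asarray(y, dtype=np.float64)
    h = logistic(P, beta)
    return P.T @ (h - y) / len(y)


def fit_meta(
    P: np.ndarray,
    y: np.ndarray,
    config: GdConfig | None = None,
    feature_names: list[str] | None = None,
) -> MetaCoefs:
    """Gradient-descent minimizer of J from beta = 0 (deterministic).

    Backtracking line search (Armijo) guarantees monotone descent; iteration
    stops when the gradient infinity-norm falls below ``config.tol`` or
    ``config.max_iter`` is reached.  A single-class training set is rejected
    (the optimum would be unbounded).
    """
    config = config or GdConfig()
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    beta = np.zeros(P.shape[1])
    J = cost(P, y, beta)
    n_iter = 0
    g = cost_grad(P, y, beta)
    while n_iter < config.max_iter and np.abs(g).max() >= config.tol:
        step = config.step
        gsq = float(g @ g)
        while True:
            candidate = beta - step * g
            Jc = cost(P, y, candidate)
            if Jc <= J - config.armijo * step * gsq or step < 1e-15:
                break
            step *= config.backtrack
        if step < 1e-15 and Jc >= J:
            break  # descent decrement below float resolution: converged numerically
        beta, J = candidate, Jc
        g = cost_grad(P, y, beta)
        n_iter += 1
    names = feature_names or (
        META_FEATURE_NAMES if P.shape[1] == N_META_INPUTS + 1
        else [f"x{i}" for i in range(P.shape[1])]
    )
    return MetaCoefs(beta=beta, feature_names=list(names), n_iter=n_iter,
                     grad_norm=float(np.abs(g).max()))


def predict_meta(P: np.ndarray, coefs: MetaCoefs) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities): arousal declared iff h_beta > 0.5 strictly."""
    h = logistic(np.atleast_2d(P), coefs.beta)
    return (h > 0.5).astype(np.int8), h
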