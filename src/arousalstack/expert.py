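"""The 1x42 expert-defined feature vector per 30-s segment.

Time domain (6): averaged numerical gradient, kurtosis, the three Hjorth
parameters (activity, mobility, complexity), skewness.

Frequency domain (36): minimum, mean, standard deviation, and 95th
percentile of each of the 8 band-power columns (4 sub-bands, full band,
3 ratios) over the 29 frames, plus the kurtosis of the 4 sub-band columns
(delta, theta, alpha, beta).

Moment conventions are deliberate and non-textbook: kurtosis and skewness
use a 1/N numerator with the (N-1)-denominator sample standard deviation,

    K = (1/N) sum (x - mu)^4 / sigma^4,   sigma^2 = sum (x - mu)^2 / (N-1),

so a Gaussian sample still tends to K = 3 as N grows (the finite-N value is
3 (N-1)^2 / N^2).  A standard ``convention="textbook"`` mode (1/N in both
numerator and sigma) is available.  Hjorth activity is the (N-1)-denominator
sample variance; mobility and complexity are ratios of first-difference
activities, hence scale-free.
"""

from __future__ import annotations

import warnings

import numpy as np

from .preprocess import Segment
from .spectral import FEATURE_COLUMNS

__all__ = [
    "hjorth",
    "kurtosis",
    "skewness",
    "averaged_gradient",
    "assemble_expert_vector",
    "EXPERT_FEATURE_NAMES",
    "N_EXPERT_FEATURES",
]

_SUBBANDS = ("delta", "theta", "alpha", "beta")

EXPERT_FEATURE_NAMES: list[str] = (
    [
        "grad_mean",
        "kurtosis",
        "hjorth_activity",
        "hjorth_mobility",
        "hjorth_complexity",
        "skewness",
    ]
    + [f"min_{c}" for c in FEATURE_COLUMNS]
    + [f"mean_{c}" for c in FEATURE_COLUMNS]
    + [f"std_{c}" for c in FEATURE_COLUMNS]
    + [f"p95_{c}" for c in FEATURE_COLUMNS]
    + [f"kurt_{c}" for c in _SUBBANDS]
)
N_EXPERT_FEATURES = 42
assert len(EXPERT_FEATURE_NAMES) == N_EXPERT_FEATURES


def _sigma(x: np.ndarray) -> float:
    """Sample standard deviation with N-1 denominator."""
    return float(np.sqrt(np.sum((x - x.mean()) ** 2) / (len(x) - 1)))


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility, complexity of a sample vector.

    Activity is the sample variance (N-1 denominator); mobility is
    sqrt(activity(diff x) / activity(x)), a dominant-frequency proxy;
    complexity is mobility(diff x) / mobility(x), a bandwidth proxy.
    A constant signal has zero activity; mobility and complexity are then
    undefined and reported as 0 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 samples for Hjorth parameters")
    act = _sigma(x) ** 2
    if act == 0:
        warnings.warn("constant signal: Hjorth mobility/complexity undefined, returning 0",
                      stacklevel=2)
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    d2 = np.diff(d1)
    act1 = _sigma(d1) ** 2
    mob = float(np.sqrt(act1 / act))
    if act1 == 0:
        warnings.warn("first difference constant: Hjorth complexity undefined, returning 0",
                      stacklevel=2)
        return act, mob, 0.0
    mob1 = float(np.sqrt(_sigma(d2) ** 2 / act1))
    return act, mob, mob1 / mob


def _standardized_moment(x: np.ndarray, order: int, convention: str) -> float:
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    if convention == "literal":
        sig = _sigma(x)
    elif convention == "textbook":
        sig = float(np.sqrt(np.mean((x - mu) ** 2)))
    else:
        raise ValueError("convention must be 'literal' or 'textbook'")
    if sig == 0:
        warnings.warn("zero standard deviation: standardized moment undefined, returning 0",
                      stacklevel=3)
        return 0.0
    return float(np.mean((x - mu) ** order) / sig**order)


def kurtosis(x: np.ndarray, convention: str = "literal") -> float:
    """Fourth standardized moment (not excess); Gaussian limit is 3."""
    return _standardized_moment(x, 4, convention)


def skewness(x: np.ndarray, convention: str = "literal") -> float:
    """Third standardized moment; 0 for any exactly symmetric sample."""
    return _standardized_moment(x, 3, convention)


def averaged_gradient(x: np.ndarray) -> float:
    """Mean of the central-difference numerical gradient (one-sided ends)."""
    return float(np.mean(np.gradient(np.asarray(x, dtype=np.float64))))


def _percentile95(col: np.ndarray) -> float:
    # linear interpolation between order statistics
    return float(np.percentile(col, 95, method="linear"))


def assemble_expert_vector(
    segment: Segment | np.ndarray,
    band_matrix: np.ndarray,
    convention: str = "literal",
) -> np.ndarray:
    """Assemble the 42-entry expert feature vector for one segment.

    ``band_matrix`` is the segment's 29x8 band-power matrix; column order
    must match ``spectral.FEATURE_COLUMNS``.  Output order follows
    ``EXPERT_FEATURE_NAMES``.
    """
    x = segment.x if isinstance(segment, Segment) else np.asarray(segment)
    bm = np.asarray(band_matrix, dtype=np.float64)
    if bm.ndim != 2 or bm.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"band matrix must be (n_frames, 8), got {bm.shape}")
    act, mob, comp = hjorth(x)
    time_feats = [
        averaged_gradient(x),
        kurtosis(x, convention),
        act,
        mob,
        comp,
        skewness(x, convention),
    ]
    mins = bm.min(axis=0)
    means = bm.mean(axis=0)
    stds = np.array([_sigma(bm[:, j]) for j in range(bm.shape[1])])
    p95s = np.array([_percentile95(bm[:, j]) for j in range(bm.shape[1])])
    sub_idx = [FEATURE_COLUMNS.index(b) for b in _SUBBANDS]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are legitimate (e.g. zero segment)
        kurts = np.array([kurtosis(bm[:, j], convention) for j in sub_idx])
    vec = np.concatenate([time_feats, mins, means, stds, p95s, kurts])
    assert vec.shape == (N_EXPERT_FEATURES,)
    return vec


def expert_matrix(segments, band_mats: np.ndarray, convention: str = "literal") -> np.ndarray:
    """Stack expert vectors over segments -> (n_segments, 42)."""
    return np.stack(
        [assemble_expert_vector(s, bm, convention) for s, bm in zip(segments, band_mats)]
    )
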