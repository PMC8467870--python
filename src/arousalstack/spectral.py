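"""Multitaper band-power features: 29 frames x 8 features per 30-s segment.

Each 6000-sample segment is analyzed in 2-s frames (400 samples) hopped by
1 s (50% overlap), giving 29 frames.  Each frame's power spectral density is
the unweighted average of 8 single-taper periodograms built on the 8
most-concentrated DPSS (Slepian) tapers of length 400, yielding 201 one-sided
bins spaced 0.5 Hz apart.  Band powers are numerical integrals (composite
Simpson) of the PSD over fixed bin ranges:

    band    Hz        bins (1-based, inclusive)
    delta   0 - 4      1 - 9
    theta   4 - 8     10 - 17
    alpha   8 - 12    18 - 25
    beta   14 - 30    30 - 61
    full    0 - 40     1 - 81

The 8 features per frame are the 5 band powers plus 3 power ratios
(delta/theta, theta/alpha, delta/alpha).

Scaling conventions (fixed so energy bookkeeping is exact): tapers are
unit-energy; the per-taper periodogram is |DFT|^2 / N_b; interior one-sided
bins are doubled (DC and the frame Nyquist are not).  With these choices the
sum of the one-sided PSD equals the tapered frame's mean power, so the total
multitaper power of unit-variance white noise is 1 in expectation.  Frames
are not demeaned before tapering, so the DC bin carries the frame mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .config import SpectralConfig
from .preprocess import SEGMENT_SAMPLES, Segment

__all__ = [
    "BANDS",
    "FEATURE_COLUMNS",
    "TaperBank",
    "compute_dpss",
    "frame_segment",
    "multitaper_psd",
    "band_power",
    "band_matrix",
]

# 1-based inclusive bin ranges at 0.5 Hz spacing; bin 1 is DC.
BANDS: dict[str, tuple[int, int]] = {
    "delta": (1, 9),
    "theta": (10, 17),
    "alpha": (18, 25),
    "beta": (30, 61),
    "full": (1, 81),
}

FEATURE_COLUMNS = [
    "delta",
    "theta",
    "alpha",
    "beta",
    "full",
    "delta_theta",
    "theta_alpha",
    "delta_alpha",
]

N_FRAMES = 29
N_BINS = 201
BIN_HZ = 0.5


@dataclass
class TaperBank:
    """The DPSS tapers used for multitaper PSD estimation."""

    h: np.ndarray  # (n_tapers, frame_length), unit-energy rows
    time_bandwidth: float
    eigenvalues: np.ndarray

    @property
    def n_tapers(self) -> int:
        return self.h.shape[0]

    @property
    def frame_length(self) -> int:
        return self.h.shape[1]


def compute_dpss(
    frame_length: int = 400, n_tapers: int = 8, time_bandwidth: float = 4.5
) -> TaperBank:
    """The ``n_tapers`` most-concentrated Slepian sequences, unit-normalized.

    The default half-bandwidth NW = 4.5 gives K = 2NW - 1 = 8 well-
    concentrated tapers, matching the taper count.  A warning is raised when
    a requested taper's concentration eigenvalue falls below 0.9, since such
    tapers leak energy outside the design bandwidth.
    """
    if n_tapers >= frame_length:
        raise ValueError("n_tapers must be smaller than frame_length")
    h, eig = windows.dpss(
        frame_length, time_bandwidth, Kmax=n_tapers, return_ratios=True, norm=2
    )
    if np.any(eig < 0.9):
        import warnings

        warnings.warn(
            f"{int((eig < 0.9).sum())} taper(s) poorly concentrated "
            f"(min eigenvalue {eig.min():.3g}); consider fewer tapers or larger NW",
            stacklevel=2,
        )
    return TaperBank(h=h, time_bandwidth=time_bandwidth, eigenvalues=eig)


def frame_segment(x: np.ndarray, frame_length: int = 400, hop: int = 200) -> np.ndarray:
    """Slice a 6000-sample segment into 29 half-overlapping 2-s frames."""
    x = np.asarray(x)
    if x.shape != (SEGMENT_SAMPLES,):
        raise ValueError(f"expected a {SEGMENT_SAMPLES}-sample segment, got {x.shape}")
    n_frames = (len(x) - frame_length) // hop + 1
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _one_sided_scale(n_bins: int) -> np.ndarray:
    scale = np.full(n_bins, 2.0)
    scale[0] = 1.0
    scale[-1] = 1.0  # frame Nyquist (100 Hz) bin
    return scale


def multitaper_psd(frame: np.ndarray, tapers: TaperBank) -> np.ndarray:
    """One-sided multitaper PSD of one frame: 201 nonnegative bins.

    The estimate is the plain average of the squared tapered DFT magnitudes
    over the taper bank (no eigenvalue weighting).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != (tapers.frame_length,):
        raise ValueError(
            f"frame length {frame.shape} does not match taper length {tapers.frame_length}"
        )
    tapered = tapers.h * frame[None, :]
    spec = np.abs(np.fft.rfft(tapered, axis=1)) ** 2 / tapers.frame_length
    psd = spec.mean(axis=0)
    return psd * _one_sided_scale(psd.size)


def multitaper_psd_frames(frames: np.ndarray, tapers: TaperBank) -> np.ndarray:
    """Vectorized multitaper PSD for a (n_frames, frame_length) array."""
    tapered = frames[:, None, :] * tapers.h[None, :, :]
    spec = np.abs(np.fft.rfft(tapered, axis=2)) ** 2 / tapers.frame_length
    psd = spec.mean(axis=1)
    return psd * _one_sided_scale(psd.shape[1])[None, :]


def _simpson_weights(n_points: int) -> np.ndarray:
    """Composite-Simpson weights on a uniform grid (unit spacing).

    For an odd interval count the final three intervals use the Simpson 3/8
    rule, keeping the quadrature exact for cubics throughout.
    """
    n_int = n_points - 1
    w = np.zeros(n_points)
    if n_int <= 0:
        return w
    if n_int == 1:  # trapezoid is all that fits
        return np.array([0.5, 0.5])
    if n_int % 2 == 0:
        m = n_int
        w[0] = w[-1] = 1.0 / 3.0
        w[1:-1:2] = 4.0 / 3.0
        w[2:-2:2] += 2.0 / 3.0
    else:
        if n_int == 3:
            return np.array([3.0, 9.0, 9.0, 3.0]) / 8.0
        head = _simpson_weights(n_points - 3)
        w[: n_points - 3] = head
        w[n_points - 4 :] += np.array([3.0, 9.0, 9.0, 3.0]) / 8.0
    return w


def band_power(psd: np.ndarray, band: str, bin_hz: float = BIN_HZ) -> float:
    """Integrate the PSD over a named band's bin range (composite Simpson).

    The PSD is treated as a function of frequency sampled every 0.5 Hz, so
    the result carries units of power (PSD x Hz).
    """
    if band not in BANDS:
        raise KeyError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    vals = np.asarray(psd)[lo - 1 : hi]  # 1-based inclusive -> 0-based slice
    w = _simpson_weights(vals.size)
    return float(np.dot(w, vals) * bin_hz)


def _ratio(num: np.ndarray, den: np.ndarray, cap: float) -> np.ndarray:
    out = np.zeros_like(num)
    pos = den > 0
    out[pos] = num[pos] / den[pos]
    out[~pos & (num > 0)] = cap
    np.minimum(out, cap, out=out)
    return out


def band_matrix(
    segment: Segment | np.ndarray,
    tapers: TaperBank,
    config: SpectralConfig | None = None,
) -> np.ndarray:
    """The 29x8 band-power feature matrix of one 30-s segment.

    Columns: delta, theta, alpha, beta, full powers then delta/theta,
    theta/alpha, delta/alpha ratios.  Ratio convention: 0/0 -> 0; x/0 with
    x > 0 is clipped at the configured ceiling.
    """
    config = config or SpectralConfig()
    x = segment.x if isinstance(segment, Segment) else np.asarray(segment)
    frames = frame_segment(x, config.frame_length, config.hop)
    psd = multitaper_psd_frames(frames, tapers)
    powers = np.empty((psd.shape[0], 5))
    for j, band in enumerate(FEATURE_COLUMNS[:5]):
        lo, hi = BANDS[band]
        vals = psd[:, lo - 1 : hi]
        w = _simpson_weights(vals.shape[1])
        powers[:, j] = vals @ w * BIN_HZ
    delta, theta, alpha = powers[:, 0], powers[:, 1], powers[:, 2]
    ratios = np.column_stack(
        [
            _ratio(delta, theta, config.ratio_cap),
            _ratio(theta, alpha, config.ratio_cap),
            _ratio(delta, alpha, config.ratio_cap),
        ]
    )
    return np.column_stack([powers, ratios])


def band_matrices(segments, tapers: TaperBank, config: SpectralConfig | None = None) -> np.ndarray:
    """Stack ``band_matrix`` over segments -> (n_segments, 29, 8)."""
    return np.stack([band_matrix(s, tapers, config) for s in segments])
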