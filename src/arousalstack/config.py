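"""Configuration dataclasses for every pipeline stage.

All tunables live here so a single :class:`RunConfig` can be serialized to
YAML, hashed into a run manifest, and round-tripped losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml


def _default_band_weights() -> dict[str, float]:
    # 1/f-like background: slow waves dominate quiet sleep.
    return {"delta": 1.0, "theta": 0.5, "alpha": 0.3, "beta": 0.15}


@dataclass
class SynthConfig:
    """Parameters of the synthetic single-lead EEG generator.

    The generator emulates a 200 Hz central-derivation EEG contaminated by
    60 Hz powerline pickup, with arousal events realized as abrupt
    multiplicative boosts of the alpha/beta background lasting at least 3 s.
    """

    sampling_rate: float = 200.0
    record_duration: float = 3600.0  # seconds
    band_weights: dict[str, float] = field(default_factory=_default_band_weights)
    mains_freq: float = 60.0
    mains_amplitude: float = 0.5
    arousal_rate: float = 63.0  # candidate events per hour (before gap thinning)
    arousal_duration_range: tuple[float, float] = (5.0, 15.0)
    arousal_band_shift: float = 3.0
    noise_floor: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.record_duration <= 0:
            raise ValueError("record_duration must be positive")
        lo, hi = self.arousal_duration_range
        if lo < 3.0:
            raise ValueError(
                "arousal_duration_range minimum must be >= 3 s "
                "(scoring rules require events lasting at least 3 s)"
            )
        if hi < lo:
            raise ValueError("arousal_duration_range must be (min, max) with max >= min")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        highest_edge = 30.0  # beta upper edge of the synthesized background
        if self.sampling_rate <= 2 * highest_edge:
            raise ValueError("sampling_rate must exceed twice the highest synthesized band edge")
        if self.arousal_rate < 0:
            raise ValueError("arousal_rate must be >= 0")


@dataclass
class FilterSpec:
    """Low-pass anti-powerline filter: order 127, edges 40/42 Hz."""

    order: int = 127
    passband_edge: float = 40.0
    stopband_edge: float = 42.0
    realization: str = "fir"  # "fir" (linear phase, default) or "iir"
    iir_order: int = 8  # per-cascade Butterworth order in "iir" mode
    stopband_weight: float = 10.0  # least-squares weight on the stopband

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0 < self.passband_edge < self.stopband_edge < nyq):
            raise ValueError(
                f"need 0 < passband ({self.passband_edge}) < stopband "
                f"({self.stopband_edge}) < Nyquist ({nyq})"
            )
        if self.realization not in ("fir", "iir"):
            raise ValueError("realization must be 'fir' or 'iir'")


@dataclass
class SegmentationConfig:
    """30-s scoring windows; edge discard; segment labeling rule."""

    window_seconds: float = 30.0
    discard_edges_seconds: float = 3600.0
    min_arousal_run_seconds: float = 3.0  # contiguous run needed to mark a window positive


@dataclass
class SpectralConfig:
    """Multitaper settings: 2-s frames, 50% overlap, 8 DPSS tapers."""

    frame_length: int = 400  # samples (2 s at 200 Hz)
    hop: int = 200  # samples (50% overlap)
    n_tapers: int = 8
    time_bandwidth: float = 4.5  # NW; K = 2NW - 1 = 8 matches n_tapers
    ratio_cap: float = 1e6  # x/0 with x > 0 clips here; 0/0 -> 0


@dataclass
class TrainConfig:
    """Optimizer settings shared by the neural sub-models."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5
    validation_fraction: float = 0.15
    seed: int = 0


@dataclass
class ForestConfig:
    n_trees: int = 500
    max_depth: int | None = None
    class_weight: str | None = None
    seed: int = 0


@dataclass
class GdConfig:
    """Gradient descent for the logistic meta-classifier."""

    step: float = 0.1
    tol: float = 1e-8  # infinity-norm of the gradient
    max_iter: int = 100_000
    backtrack: float = 0.5
    armijo: float = 1e-4


@dataclass
class StackConfig:
    protocol: str = "oof"  # "oof" | "holdout" | "naive"
    n_folds: int = 5
    holdout_fraction: float = 0.25  # of training records, in "holdout" mode
    drop_redundant: bool = False  # drop one column of each probability pair
    gd: GdConfig = field(default_factory=GdConfig)


@dataclass
class EvalConfig:
    n_folds: int = 5
    test_fraction: float = 0.2  # held-out records


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one serializable object."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    stack: StackConfig = field(default_factory=StackConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        # the master seed flows into sub-configs whose seed was left at 0
        for sub in (self.synth, self.train, self.forest):
            if sub.seed == 0:
                sub.seed = self.seed

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            default = f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
            if dataclasses.is_dataclass(default):
                sub = {k: v for k, v in d[f.name].items()}
                # nested GdConfig inside StackConfig
                if isinstance(default, StackConfig) and isinstance(sub.get("gd"), dict):
                    sub["gd"] = GdConfig(**sub["gd"])
                if isinstance(default, SynthConfig) and isinstance(sub.get("arousal_duration_range"), list):
                    sub["arousal_duration_range"] = tuple(sub["arousal_duration_range"])
                kwargs[f.name] = type(default)(**sub)
            else:
                kwargs[f.name] = d[f.name]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
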