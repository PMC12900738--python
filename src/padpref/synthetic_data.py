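"""Synthetic raters and EEG epochs with the structure the analysis assumes.

The rating generator inverts the PAD scoring map exactly, so with zero
noise every simulated record scores back to its target; with noise the
per-dimension sampling error is noise_sd/2 per record (each dimension
averages four items).

The EEG generator adds a Gaussian-shaped late positive component to white
Gaussian background noise (optionally 1/f-shaped), with a multiplicative
left/right lateralization that embodies the valence hypothesis: for a
"like" trial the left frontal channels carry amplitude × (1 + λ) and the
right frontal channels amplitude × (1 − λ); "dislike" mirrors this;
"neutral" is unlateralized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from padpref.erp_pipeline import (
    DEFAULT_CHANNELS,
    EpochSet,
    LEFT_FRONTAL,
    REFERENCE_CHANNELS,
    RIGHT_FRONTAL,
)
from padpref.pad_core import ITEM_MAX, ITEM_MIN, PADVector, RatingRecord

__all__ = [
    "RaterSimConfig",
    "EegSimConfig",
    "generate_ratings",
    "generate_epochs",
    "pad_to_items",
]


class SimConfigError(ValueError):
    """Raised for simulation parameters outside their valid domain."""


def pad_to_items(pad: PADVector) -> np.ndarray:
    """Exact right-inverse of the scoring map, as mean item values.

    V1 = V7 = P, V4 = V10 = −P; V5 = V11 = A, V2 = V8 = −A;
    V3 = V9 = D, V6 = V12 = −D.
    """
    p, a, d = pad.as_tuple()
    return np.array([p, -a, d, -p, a, -d, p, -a, d, -p, a, -d])


@dataclass(frozen=True)
class RaterSimConfig:
    """Latent group-level PAD targets plus iid Gaussian rater noise."""

    targets: Mapping[tuple[str, str], PADVector]  # (group, stimulus) -> PAD
    n_raters: int
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise SimConfigError("n_raters must be >= 1")
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be non-negative")
        for key, pad in self.targets.items():
            for c in pad.as_tuple():
                if not (ITEM_MIN <= c <= ITEM_MAX):
                    raise SimConfigError(
                        f"target PAD for {key} outside [{ITEM_MIN:g}, {ITEM_MAX:g}]"
                    )


def generate_ratings(config: RaterSimConfig) -> list[RatingRecord]:
    """Simulate one cohort of raters per (group, stimulus) target.

    Item means follow the exact inverse scoring map; iid Gaussian noise
    (sd = noise_sd) is added per item and the result clipped to the
    instrument range.  Clipping attenuates recovered means toward zero for
    |target| ≳ 3.5 when noise_sd > 0.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    records: list[RatingRecord] = []
    for (group, stimulus), pad in config.targets.items():
        base = pad_to_items(pad)
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_raters, 12))
        items = np.clip(base + noise, ITEM_MIN, ITEM_MAX)
        for r in range(config.n_raters):
            records.append(
                RatingRecord(
                    participant_id=f"sim-{group}-{r + 1:03d}",
                    group=group,
                    stimulus_id=stimulus,
                    items=tuple(items[r]),
                )
            )
    return records


@dataclass(frozen=True)
class EegSimConfig:
    """Background noise + lateralized Gaussian LPP bump, per condition."""

    fs: float = 500.0
    n_trials: int = 40  # per condition
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    noise_sd: float = 5.0  # uV per sample
    lpp_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"like": 5.0, "neutral": 5.0, "dislike": 5.0}
    )
    lpp_latency_ms: float = 400.0
    lpp_width_ms: float = 80.0
    lateralization: float = 0.5
    t0_ms: float = -200.0
    duration_ms: float = 1000.0
    noise_model: str = "white"  # or "pink"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise SimConfigError("n_trials must be >= 1")
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be non-negative")
        if not (250.0 <= self.lpp_latency_ms <= 600.0):
            raise SimConfigError("lpp_latency_ms must lie in [250, 600] ms")
        end_ms = self.t0_ms + self.duration_ms
        if not (self.t0_ms < self.lpp_latency_ms < end_ms):
            raise SimConfigError("lpp_latency_ms outside epoch span")
        if self.noise_model not in ("white", "pink"):
            raise SimConfigError("noise_model must be 'white' or 'pink'")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 1/f-shaped noise along the last axis."""
    white = rng.normal(size=shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.zeros_like(freqs)
    np.divide(1.0, np.sqrt(freqs, where=freqs > 0, out=np.ones_like(freqs)),
              where=freqs > 0, out=scale)
    shaped = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def lateral_gain(channel: str, condition: str, lam: float) -> float:
    """Multiplicative gain applied to the bump amplitude on a channel."""
    if condition == "like":
        sign = 1.0
    elif condition == "dislike":
        sign = -1.0
    else:
        sign = 0.0
    if channel in LEFT_FRONTAL:
        return 1.0 + sign * lam
    if channel in RIGHT_FRONTAL:
        return 1.0 - sign * lam
    return 1.0


def generate_epochs(config: EegSimConfig) -> EpochSet:
    """Simulate an epoch set with n_trials per condition.

    Every non-reference channel carries the condition's bump amplitude
    times its lateral gain; mastoids carry noise only.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration_ms * config.fs / 1000.0))
    times = config.t0_ms + np.arange(n_samples) * 1000.0 / config.fs
    bump = np.exp(-0.5 * ((times - config.lpp_latency_ms) / config.lpp_width_ms) ** 2)

    conditions: list[str] = []
    trials: list[np.ndarray] = []
    for cond in ("like", "neutral", "dislike"):
        if cond not in config.lpp_amplitude:
            continue
        amp = float(config.lpp_amplitude[cond])
        gains = np.array(
            [
                0.0
                if ch in REFERENCE_CHANNELS
                else amp * lateral_gain(ch, cond, config.lateralization)
                for ch in config.channels
            ]
        )
        template = gains[:, None] * bump[None, :]
        for _ in range(config.n_trials):
            if config.noise_sd > 0:
                if config.noise_model == "pink":
                    noise = config.noise_sd * _pink_noise(
                        rng, (len(config.channels), n_samples)
                    )
                else:
                    noise = rng.normal(
                        0.0, config.noise_sd, size=(len(config.channels), n_samples)
                    )
            else:
                noise = 0.0
            trials.append(template + noise)
            conditions.append(cond)

    return EpochSet(
        data=np.stack(trials, axis=0),
        fs=config.fs,
        t0_ms=config.t0_ms,
        channels=config.channels,
        conditions=tuple(conditions),
    )
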