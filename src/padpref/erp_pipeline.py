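"""Desk-scale ERP chain: filter, segment, baseline, re-reference, reject,
average, late-window peak extraction, frontal-asymmetry valence.

Fixed processing order (order-sensitive, so it is part of the contract):

    lowpass -> notch -> segment -> baseline_correct -> rereference
            -> reject_artifacts -> average_epochs -> peak_amplitude

Voltages are in microvolts throughout; time is in milliseconds in every
interface and converted to 0-based sample indices internally with
half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EpochSet",
    "ErpWaveform",
    "PeakTable",
    "AsymmetryResult",
    "ANALYSIS_CHANNELS",
    "DEFAULT_CHANNELS",
    "REFERENCE_CHANNELS",
    "CONDITIONS",
    "lowpass",
    "notch",
    "segment",
    "baseline_correct",
    "rereference",
    "reject_artifacts",
    "average_epochs",
    "peak_amplitude",
    "frontal_asymmetry",
    "run_erp_pipeline",
    "LPP_WINDOW_MS",
]

#: Scalp channels entering peak analysis, in montage order.
ANALYSIS_CHANNELS = ("Fp1", "Fpz", "Fp2", "F3", "F4", "Fz", "Cz", "Pz")
#: Bilateral mastoid reference channels.
REFERENCE_CHANNELS = ("M1", "M2")
DEFAULT_CHANNELS = ANALYSIS_CHANNELS + REFERENCE_CHANNELS
CONDITIONS = ("like", "neutral", "dislike")

LEFT_FRONTAL = ("Fp1", "F3")
RIGHT_FRONTAL = ("Fp2", "F4")

#: Analysis window for late-positive-potential peak extraction, ms.
LPP_WINDOW_MS = (250.0, 600.0)


class ParameterError(ValueError):
    """Raised for physically impossible filter/window parameters."""


class ConfigurationError(ValueError):
    """Raised when required channels or conditions are missing."""


def _ms_to_index(t_ms: float, t0_ms: float, fs: float) -> int:
    # half-up rounding of the ms -> sample mapping
    return int(np.floor((t_ms - t0_ms) * fs / 1000.0 + 0.5))


@dataclass
class EpochSet:
    """Multi-trial voltage array with montage and per-trial conditions.

    ``data`` is indexed (trial, channel, sample), in μV.  ``t0_ms`` is the
    time of the first sample relative to stimulus onset.
    """

    data: np.ndarray
    fs: float
    t0_ms: float
    channels: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, channel, sample)")
        self.channels = tuple(self.channels)
        self.conditions = tuple(self.conditions)
        n_trials, n_channels, _ = self.data.shape
        if len(self.channels) != n_channels:
            raise ValueError(
                f"{n_channels} channels in data but {len(self.channels)} names"
            )
        if len(self.conditions) != n_trials:
            raise ValueError(
                f"{n_trials} trials but {len(self.conditions)} condition labels"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise ConfigurationError(
                f"channel {name!r} not in montage {self.channels}"
            ) from None


@dataclass
class ErpWaveform:
    """Trial-averaged waveform: (channel, sample) mean voltages in μV."""

    data: np.ndarray
    fs: float
    t0_ms: float
    channels: tuple[str, ...]
    n_trials: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (channel, sample)")
        if self.n_trials < 1:
            raise ValueError("an averaged waveform needs at least one trial")

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise ConfigurationError(
                f"channel {name!r} not in montage {self.channels}"
            ) from None


@dataclass(frozen=True)
class PeakTable:
    """Signed extremal amplitude per channel within the analysis window."""

    peaks: Mapping[str, float]
    window_ms: tuple[float, float]
    latencies_ms: Mapping[str, float] = field(default_factory=dict)

    def __getitem__(self, channel: str) -> float:
        return self.peaks[channel]


@dataclass(frozen=True)
class AsymmetryResult:
    """Frontal left-minus-right peak asymmetry and its valence call."""

    left_mean: float
    right_mean: float
    index: float
    valence: str
    epsilon: float


def _filter_epochs(epochs: EpochSet, sos_or_ba, *, is_sos: bool) -> EpochSet:
    flat = epochs.data.reshape(-1, epochs.n_samples)
    if is_sos:
        out = signal.sosfiltfilt(sos_or_ba, flat, axis=-1)
    else:
        b, a = sos_or_ba
        out = signal.filtfilt(b, a, flat, axis=-1)
    return replace(epochs, data=out.reshape(epochs.data.shape))


def lowpass(epochs: EpochSet, cutoff_hz: float = 30.0, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth low-pass per trial × channel; DC preserved."""
    nyq = epochs.fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ParameterError(
            f"low-pass cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=epochs.fs, output="sos")
    return _filter_epochs(epochs, sos, is_sos=True)


def notch(epochs: EpochSet, freq_hz: float = 50.0, q: float = 30.0) -> EpochSet:
    """Zero-phase IIR notch (mains suppression) per trial × channel."""
    nyq = epochs.fs / 2.0
    if not 0 < freq_hz < nyq:
        raise ParameterError(
            f"notch frequency {freq_hz} Hz must lie in (0, {nyq}) Hz"
        )
    b, a = signal.iirnotch(freq_hz, q, fs=epochs.fs)
    return _filter_epochs(epochs, (b, a), is_sos=False)


def segment(
    continuous: np.ndarray,
    fs: float,
    event_samples: Sequence[int],
    conditions: Sequence[str],
    channels: Sequence[str],
    window_ms: tuple[float, float] = (-200.0, 800.0),
) -> tuple[EpochSet, list[dict]]:
    """Cut stimulus-locked epochs out of a continuous (channel, sample) array.

    The epoch spans ``[event + window_ms[0], event + window_ms[1])`` with a
    half-open right edge, so a 1000 ms window at fs Hz yields exactly
    round(fs) samples and the sample at event time falls on the
    post-stimulus side.  Events without full window support are dropped and
    logged, not raised.

    Returns the epochs plus a rejection log (one dict per dropped event).
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise ValueError("continuous recording must be (channel, sample)")
    if len(conditions) != len(event_samples):
        raise ValueError("one condition label required per event")
    lo_ms, hi_ms = window_ms
    if hi_ms <= lo_ms:
        raise ParameterError("window end must exceed window start")
    n_pre = int(np.floor(-lo_ms * fs / 1000.0 + 0.5))
    n_post = int(np.floor(hi_ms * fs / 1000.0 + 0.5))
    n_total = n_pre + n_post
    n_samples = continuous.shape[1]

    kept: list[np.ndarray] = []
    kept_conditions: list[str] = []
    log: list[dict] = []
    for event, cond in zip(event_samples, conditions):
        start = int(event) - n_pre
        stop = int(event) + n_post
        if start < 0 or stop > n_samples:
            log.append(
                {
                    "event_sample": int(event),
                    "condition": cond,
                    "reason": "window outside recording bounds",
                }
            )
            continue
        kept.append(continuous[:, start:stop])
        kept_conditions.append(cond)

    data = (
        np.stack(kept, axis=0)
        if kept
        else np.empty((0, continuous.shape[0], n_total))
    )
    epochs = EpochSet(
        data=data,
        fs=fs,
        t0_ms=lo_ms,
        channels=tuple(channels),
        conditions=tuple(kept_conditions),
    )
    return epochs, log


def baseline_correct(
    epochs: EpochSet, window_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the pre-stimulus mean per trial × channel."""
    i0 = _ms_to_index(window_ms[0], epochs.t0_ms, epochs.fs)
    i1 = _ms_to_index(window_ms[1], epochs.t0_ms, epochs.fs)
    i0 = max(i0, 0)
    if i1 <= i0:
        raise ParameterError("baseline window contains no samples")
    baseline = epochs.data[:, :, i0:i1].mean(axis=-1, keepdims=True)
    return replace(epochs, data=epochs.data - baseline)


def rereference(
    epochs: EpochSet, ref_channels: Sequence[str] = REFERENCE_CHANNELS
) -> EpochSet:
    """Subtract the mean of the mastoid channels from every channel."""
    idx = [epochs.channel_index(name) for name in ref_channels]
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - ref)


def reject_artifacts(
    epochs: EpochSet,
    threshold_uv: float = 100.0,
    channels: Sequence[str] | None = None,
) -> tuple[EpochSet, list[dict]]:
    """Drop trials with any |v| > threshold on an analysis channel.

    ``channels`` defaults to every non-reference channel present.  Returns
    the surviving epochs and a per-trial rejection log.  Idempotent.
    """
    if threshold_uv <= 0:
        raise ParameterError("rejection threshold must be positive")
    if channels is None:
        channels = [c for c in epochs.channels if c not in REFERENCE_CHANNELS]
    idx = [epochs.channel_index(name) for name in channels]
    sub = epochs.data[:, idx, :]
    keep = np.ones(epochs.n_trials, dtype=bool)
    log: list[dict] = []
    for t in range(epochs.n_trials):
        bad = np.abs(sub[t]) > threshold_uv
        if bad.any():
            keep[t] = False
            ch_i, smp_i = np.unravel_index(np.argmax(np.abs(sub[t])), sub[t].shape)
            log.append(
                {
                    "trial": t,
                    "condition": epochs.conditions[t],
                    "channel": channels[ch_i],
                    "peak_uv": float(sub[t, ch_i, smp_i]),
                    "reason": f"|v| > {threshold_uv:g} uV",
                }
            )
    cleaned = replace(
        epochs,
        data=epochs.data[keep],
        conditions=tuple(c for c, k in zip(epochs.conditions, keep) if k),
    )
    return cleaned, log


def average_epochs(
    epochs: EpochSet, by_condition: bool = True
) -> dict[str, ErpWaveform]:
    """Pointwise mean over trials, optionally split by condition label."""
    if epochs.n_trials == 0:
        return {}
    if by_condition:
        groups = {}
        for cond in dict.fromkeys(epochs.conditions):
            mask = np.array([c == cond for c in epochs.conditions])
            groups[cond] = mask
    else:
        groups = {"all": np.ones(epochs.n_trials, dtype=bool)}
    out = {}
    for cond, mask in groups.items():
        out[cond] = ErpWaveform(
            data=epochs.data[mask].mean(axis=0),
            fs=epochs.fs,
            t0_ms=epochs.t0_ms,
            channels=epochs.channels,
            n_trials=int(mask.sum()),
        )
    return out


def peak_amplitude(
    erp: ErpWaveform,
    window_ms: tuple[float, float] = LPP_WINDOW_MS,
    channels: Sequence[str] = ANALYSIS_CHANNELS,
) -> PeakTable:
    """Signed extremal amplitude per channel in the inclusive window.

    The value at the sample of maximal |v| is reported with its sign; an
    exact tie in |v| is broken by earliest latency (argmax convention).
    """
    i0 = _ms_to_index(window_ms[0], erp.t0_ms, erp.fs)
    i1 = _ms_to_index(window_ms[1], erp.t0_ms, erp.fs)
    n = erp.data.shape[1]
    if i0 < 0 or i1 > n - 1:
        raise ParameterError(
            f"window {window_ms} ms exceeds epoch span "
            f"[{erp.t0_ms}, {erp.t0_ms + (n - 1) * 1000.0 / erp.fs}] ms"
        )
    peaks: dict[str, float] = {}
    latencies: dict[str, float] = {}
    for name in channels:
        row = erp.data[erp.channel_index(name), i0 : i1 + 1]
        k = int(np.argmax(np.abs(row)))
        peaks[name] = float(row[k])
        latencies[name] = erp.t0_ms + (i0 + k) * 1000.0 / erp.fs
    return PeakTable(peaks=peaks, window_ms=tuple(window_ms), latencies_ms=latencies)


def frontal_asymmetry(peaks: PeakTable, epsilon_uv: float = 0.5) -> AsymmetryResult:
    """Classify valence from left-minus-right frontal peak amplitudes.

    index = mean(Fp1, F3) − mean(Fp2, F4); like iff index > ε, dislike iff
    index < −ε, neutral otherwise.
    """
    if epsilon_uv < 0:
        raise ParameterError("epsilon must be non-negative")
    try:
        left = float(np.mean([peaks[c] for c in LEFT_FRONTAL]))
        right = float(np.mean([peaks[c] for c in RIGHT_FRONTAL]))
    except KeyError as exc:
        raise ConfigurationError(f"peak table missing channel {exc}") from None
    index = left - right
    if index > epsilon_uv:
        valence = "like"
    elif index < -epsilon_uv:
        valence = "dislike"
    else:
        valence = "neutral"
    return AsymmetryResult(
        left_mean=left,
        right_mean=right,
        index=index,
        valence=valence,
        epsilon=epsilon_uv,
    )


def run_erp_pipeline(
    epochs: EpochSet,
    *,
    lowpass_hz: float = 30.0,
    notch_hz: float = 50.0,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    threshold_uv: float = 100.0,
    window_ms: tuple[float, float] = LPP_WINDOW_MS,
    channels: Sequence[str] = ANALYSIS_CHANNELS,
    epsilon_uv: float = 0.5,
    rereference_refs: Sequence[str] | None = REFERENCE_CHANNELS,
) -> dict[str, dict]:
    """Run the fixed post-segmentation chain on an epoch set.

    Returns, per condition, the averaged waveform, its peak table, the
    asymmetry result, and the artifact-rejection log.
    """
    x = lowpass(epochs, lowpass_hz)
    x = notch(x, notch_hz)
    x = baseline_correct(x, baseline_ms)
    if rereference_refs is not None:
        x = rereference(x, rereference_refs)
    x, rejection_log = reject_artifacts(x, threshold_uv)
    out: dict[str, dict] = {}
    for cond, erp in average_epochs(x, by_condition=True).items():
        peaks = peak_amplitude(erp, window_ms, channels)
        out[cond] = {
            "erp": erp,
            "peaks": peaks,
            "asymmetry": frontal_asymmetry(peaks, epsilon_uv),
            "rejection_log": [e for e in rejection_log if e["condition"] == cond],
        }
    return out
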