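"""Signal conditioning: mains-notch and band-pass filtering, min-max scaling.

Raw scalp EEG carries 50/60 Hz interference from the amplifier and power
lines; a notch filter removes it. The blink artifact lives in the
low-frequency bands (1-12 Hz), so a band-pass isolates that range. Each
channel is then independently scaled to [0,1],

    X' = (X - X_min) / (X_max - X_min),

with the channel's own extrema as reference values. Both filters are
applied forward-backward (zero phase) so event-marker positions stay
aligned with the waveform features they tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EEGRecording


class FilterError(ValueError):
    pass


class DegenerateChannelError(ValueError):
    """A channel is constant, so min-max scaling is undefined for it."""


@dataclass(frozen=True)
class FilterSpec:
    """Filter parameters.

    notch_freq : mains frequency to suppress [Hz]
    notch_q    : notch quality factor (bandwidth = notch_freq / Q)
    band_low, band_high : band-pass edges [Hz]
    order      : Butterworth band-pass order
    """

    notch_freq: float = 60.0
    notch_q: float = 30.0
    band_low: float = 1.0
    band_high: float = 12.0
    order: int = 4

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.band_low < self.band_high < nyq):
            raise FilterError(
                f"band-pass edges must satisfy 0 < {self.band_low} < {self.band_high} < fs/2 = {nyq}"
            )
        if not (0 < self.notch_freq < nyq):
            raise FilterError(f"notch frequency {self.notch_freq} must lie below fs/2 = {nyq}")
        if self.order < 1:
            raise FilterError("band-pass order must be >= 1")


def notch_filter(rec: EEGRecording, spec: FilterSpec = FilterSpec()) -> EEGRecording:
    """Suppress a narrow band around the mains frequency on every channel."""
    spec.validate(rec.fs)
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=rec.fs)
    filtered = signal.filtfilt(b, a, rec.data, axis=1)
    return rec.copy_with(data=filtered)


def bandpass_filter(rec: EEGRecording, spec: FilterSpec = FilterSpec()) -> EEGRecording:
    """Keep only the configured frequency band (Butterworth, zero phase)."""
    spec.validate(rec.fs)
    sos = signal.butter(spec.order, [spec.band_low, spec.band_high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=filtered)


def minmax_normalize(rec: EEGRecording, reference: EEGRecording | None = None) -> EEGRecording:
    """Scale each channel independently to [0,1].

    Reference extrema are taken from ``reference`` if given (e.g. the
    training portion only, to avoid leaking validation amplitudes),
    otherwise from the recording itself. A constant channel raises
    :class:`DegenerateChannelError` naming the channel.
    """
    ref = reference.data if reference is not None else rec.data
    lo = ref.min(axis=1, keepdims=True)
    hi = ref.max(axis=1, keepdims=True)
    flat = np.nonzero((hi - lo).ravel() == 0)[0]
    if flat.size:
        labels = ", ".join(rec.channel_labels[i] for i in flat)
        raise DegenerateChannelError(f"constant channel(s) cannot be min-max scaled: {labels}")
    return rec.copy_with(data=(rec.data - lo) / (hi - lo))


def preprocess(
    rec: EEGRecording,
    spec: FilterSpec = FilterSpec(),
    normalize_scope: str = "full",
    train_samples: int | None = None,
) -> EEGRecording:
    """Fixed cleaning chain: notch, band-pass, then min-max scaling.

    ``normalize_scope="train_only"`` computes the scaling extrema on the
    first ``train_samples`` samples instead of the whole recording.
    """
    out = bandpass_filter(notch_filter(rec, spec), spec)
    if normalize_scope == "train_only":
        if train_samples is None:
            raise ValueError("train_only scope requires train_samples")
        ref = out.copy_with(data=out.data[:, :train_samples].copy(), markers=[])
        return minmax_normalize(out, reference=ref)
    if normalize_scope != "full":
        raise ValueError(f"normalize_scope must be 'full' or 'train_only', got {normalize_scope!r}")
    return minmax_normalize(out)
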