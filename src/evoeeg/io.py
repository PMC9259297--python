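"""Reading, writing and in-memory representation of EEG recordings.

The on-disk dialect is deliberately minimal: the signal is a CSV with one
row per sample and one numeric column per channel (header with channel
labels optional); event markers live in a sidecar text/CSV file with one
``sample_index[,label]`` row per event. All indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: 10-20 system electrode names used by the reference 8-channel montage.
DEFAULT_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "P1", "P2", "O1", "O2")

#: Sampling rate [Hz] of the reference acquisition hardware; windows of
#: 250 samples are then one second long.
DEFAULT_FS = 250.0


class RecordingError(ValueError):
    """Raised when a recording or marker file violates its invariants."""


@dataclass(frozen=True)
class EventMarker:
    """A labeled event at an exact sample position in a recording."""

    sample_index: int
    label: str = "blink"

    def __post_init__(self):
        if not (isinstance(self.sample_index, (int, np.integer)) and self.sample_index >= 0):
            raise RecordingError(f"marker sample_index must be a non-negative integer, got {self.sample_index!r}")


@dataclass
class EEGRecording:
    """Multichannel EEG with sampling rate, channel labels and event markers.

    Parameters
    ----------
    data
        Voltage matrix [µV], shape ``(n_channels, n_samples)``.
    fs
        Sampling rate [Hz].
    channel_labels
        Unique channel names, one per row of ``data``.
    markers
        Event markers; kept sorted ascending by sample index.
    """

    data: np.ndarray
    fs: float = DEFAULT_FS
    channel_labels: tuple[str, ...] = ()
    markers: list[EventMarker] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise RecordingError(f"data must be (n_channels, n_samples) with both >= 1, got shape {self.data.shape}")
        if not self.fs > 0:
            raise RecordingError(f"fs must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = tuple(
                DEFAULT_CHANNELS[: self.n_channels]
                if self.n_channels <= len(DEFAULT_CHANNELS)
                else (f"ch{i}" for i in range(self.n_channels))
            )
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.n_channels:
            raise RecordingError(
                f"{len(self.channel_labels)} channel labels for {self.n_channels} channels"
            )
        if len(set(self.channel_labels)) != self.n_channels:
            raise RecordingError("channel labels must be unique")
        for m in self.markers:
            if not (0 <= m.sample_index < self.n_samples):
                raise RecordingError(
                    f"marker at {m.sample_index} outside recording of {self.n_samples} samples"
                )
        self.markers = sorted(self.markers, key=lambda m: m.sample_index)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def marker_indices(self) -> np.ndarray:
        return np.array([m.sample_index for m in self.markers], dtype=np.int64)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "EEGRecording":
        """Return a copy with some fields replaced (data is not shared)."""
        out = dict(
            data=self.data.copy(), fs=self.fs,
            channel_labels=self.channel_labels, markers=list(self.markers),
        )
        out.update(kwargs)
        return EEGRecording(**out)


def _read_markers(marker_path) -> list[EventMarker]:
    markers = []
    with open(marker_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            try:
                idx = int(parts[0])
            except ValueError:
                if lineno == 1:  # tolerated header line
                    continue
                raise RecordingError(
                    f"{marker_path}: line {lineno}: non-integer sample index {parts[0]!r}"
                ) from None
            label = parts[1] if len(parts) > 1 and parts[1] else "blink"
            markers.append(EventMarker(idx, label))
    return markers


def read_recording(csv_path, marker_path=None, fs: float = DEFAULT_FS) -> EEGRecording:
    """Read a recording from a signal CSV plus an optional marker sidecar.

    The CSV has one row per sample and one numeric column per channel; a
    header row of channel labels is accepted and optional. Markers out of
    range for the signal raise :class:`RecordingError`.
    """
    def _is_number(v) -> bool:
        try:
            float(v)
            return True
        except (TypeError, ValueError):
            return False

    head = pd.read_csv(csv_path, header=None, nrows=1)
    has_header = not all(_is_number(v) for v in head.iloc[0])
    df = pd.read_csv(csv_path, header=0 if has_header else None)
    labels = tuple(str(c) for c in df.columns) if has_header else ()
    try:
        data = df.to_numpy(dtype=float).T
    except ValueError:
        # locate the offending cell for a precise error
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any() and not df[col].isna().all():
                i = int(bad.index[bad.isna()][0])
                raise RecordingError(
                    f"{csv_path}: non-numeric cell at row {i}, column {j} ({df[col].iloc[i]!r})"
                ) from None
        raise
    markers = _read_markers(marker_path) if marker_path is not None else []
    return EEGRecording(data=data, fs=fs, channel_labels=labels, markers=markers)


def write_recording(rec: EEGRecording, csv_path, marker_path=None) -> None:
    """Write a recording to CSV (with channel-label header) plus markers.

    Voltages are written with enough digits that a read-back round-trip
    agrees to at least 6 significant figures; marker indices round-trip
    exactly.
    """
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(csv_path, index=False, float_format="%.10g")
    if marker_path is not None:
        with open(marker_path, "w") as fh:
            fh.write("sample_index,label\n")
            for m in rec.markers:
                fh.write(f"{m.sample_index},{m.label}\n")
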