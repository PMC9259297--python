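"""Windowing: event-based splitting and window dataset construction.

Three segmentations are used downstream:

* ``split_by_events`` — the 70/30 recording split: the leading signal
  segment that encompasses 70% of the events becomes the training
  portion, the remainder the validation portion.
* ``make_training_set`` — one positive window centered on each marker;
  the union of those sample ranges is removed and each remaining
  contiguous run is cut into overlapped negative windows.
* ``make_sliding_set`` — plain overlapped sliding windows over the whole
  recording, labeled 1 whenever at least one marker falls inside; used
  for validation and test, where the same marker may appear in several
  consecutive windows.

Window intervals are half-open ``[start, start + size)`` and the stride
for overlap ``v`` is ``max(1, round(size * (1 - v)))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecording, EventMarker


class SegmentationError(ValueError):
    pass


def stride_for(size: int, overlap: float) -> int:
    """Stride in samples for a window size and fractional overlap."""
    if not (0.0 <= overlap < 1.0):
        raise SegmentationError(f"overlap must be in [0, 1), got {overlap}")
    s = int(np.floor(size * (1.0 - overlap) + 0.5))
    return max(1, s)


@dataclass(frozen=True)
class Window:
    """A fixed-length labeled segment of a recording."""

    values: np.ndarray  # (n_channels, size)
    label: int  # 1 iff the window contains >= 1 event marker
    start_index: int
    marker_ids: tuple[int, ...] = ()

    def __post_init__(self):
        if self.label != (1 if self.marker_ids else 0):
            raise SegmentationError("label must be 1 iff marker_ids is non-empty")


@dataclass
class WindowDataset:
    """An ordered collection of equally sized labeled windows.

    Stored column-stacked for efficiency: ``values`` has shape
    ``(n_windows, n_channels, size)``; :attr:`windows` materialises
    :class:`Window` objects on demand.
    """

    values: np.ndarray
    labels: np.ndarray
    starts: np.ndarray
    marker_ids: list[tuple[int, ...]]
    size: int
    overlap: float
    role: str = "train"

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != self.size:
            raise SegmentationError("values must be (n_windows, n_channels, size)")
        if not (len(self.labels) == len(self.starts) == len(self.marker_ids) == len(self.values)):
            raise SegmentationError("inconsistent dataset lengths")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def windows(self) -> list[Window]:
        return [
            Window(self.values[i], int(self.labels[i]), int(self.starts[i]), self.marker_ids[i])
            for i in range(len(self))
        ]

    def flattened(self, feature_mask: np.ndarray | None = None) -> np.ndarray:
        """Channel-major flattening to (n_windows, n_channels*size),
        optionally restricted to a boolean feature mask."""
        X = self.values.reshape(len(self), -1)
        return X if feature_mask is None else X[:, feature_mask]


def split_by_events(rec: EEGRecording, train_frac: float = 0.7) -> tuple[EEGRecording, EEGRecording]:
    """Split a recording so the first part holds ``round(train_frac * n)``
    events, cutting at the midpoint between the last training marker and
    the first validation marker (or recording end). Marker indices in the
    second part are re-based to its own origin."""
    if not rec.markers:
        raise SegmentationError("cannot split a recording with no markers")
    if not (0.0 < train_frac < 1.0):
        raise SegmentationError(f"train_frac must be in (0, 1), got {train_frac}")
    n = len(rec.markers)
    k = int(np.floor(train_frac * n + 0.5))
    k = min(max(k, 1), n)
    if k == n:
        # degenerate: all events land in the first part; cut midway to the end
        cut = min((rec.markers[-1].sample_index + rec.n_samples + 1) // 2, rec.n_samples - 1)
    else:
        cut = (rec.markers[k - 1].sample_index + rec.markers[k].sample_index + 1) // 2
    first = EEGRecording(
        data=rec.data[:, :cut].copy(), fs=rec.fs, channel_labels=rec.channel_labels,
        markers=[m for m in rec.markers[:k]],
    )
    second = EEGRecording(
        data=rec.data[:, cut:].copy(), fs=rec.fs, channel_labels=rec.channel_labels,
        markers=[EventMarker(m.sample_index - cut, m.label) for m in rec.markers[k:]],
    )
    return first, second


def make_training_set(rec: EEGRecording, size: int = 250, overlap: float = 0.0) -> WindowDataset:
    """Event-centered positives plus overlapped negatives from the rest.

    Each usable marker yields one positive window spanning
    ``[m - size//2, m - size//2 + size)``; markers too close to an edge
    to center a window are skipped with a warning. The union of positive
    ranges is removed and each remaining contiguous run at least ``size``
    long is segmented into negative windows at the configured overlap.
    """
    if size > rec.n_samples:
        raise SegmentationError(f"window size {size} exceeds recording length {rec.n_samples}")
    stride = stride_for(size, overlap)
    half = size // 2

    pos_vals, pos_starts, pos_ids = [], [], []
    covered = np.zeros(rec.n_samples, dtype=bool)
    for mid, m in enumerate(rec.markers):
        start = m.sample_index - half
        if start < 0 or start + size > rec.n_samples:
            warnings.warn(
                f"marker {mid} at sample {m.sample_index} too close to an edge "
                f"to center a {size}-sample window; skipped",
                stacklevel=2,
            )
            continue
        pos_vals.append(rec.data[:, start:start + size])
        pos_starts.append(start)
        pos_ids.append((mid,))
        covered[start:start + size] = True

    neg_vals, neg_starts = [], []
    # contiguous uncovered runs
    edges = np.flatnonzero(np.diff(np.concatenate(([False], ~covered, [False])).astype(np.int8)))
    for run_start, run_end in zip(edges[::2], edges[1::2]):
        run_len = run_end - run_start
        if run_len < size:
            continue
        for s in range(0, run_len - size + 1, stride):
            neg_vals.append(rec.data[:, run_start + s:run_start + s + size])
            neg_starts.append(int(run_start + s))

    n_pos, n_neg = len(pos_vals), len(neg_vals)
    vals = np.stack(pos_vals + neg_vals) if n_pos + n_neg else np.empty((0, rec.n_channels, size))
    return WindowDataset(
        values=vals,
        labels=np.array([1] * n_pos + [0] * n_neg, dtype=np.int8),
        starts=np.array(pos_starts + neg_starts, dtype=np.int64),
        marker_ids=pos_ids + [()] * n_neg,
        size=size, overlap=overlap, role="train",
    )


def make_sliding_set(
    rec: EEGRecording, size: int = 250, overlap: float = 0.0, role: str = "validation"
) -> WindowDataset:
    """Overlapped sliding windows tiling the recording from sample 0.

    A window starting at ``s`` is labeled 1 iff at least one marker index
    lies in ``[s, s + size)``; its ``marker_ids`` record which, so one
    marker may be shared by several consecutive windows.
    """
    if size > rec.n_samples:
        raise SegmentationError(f"window size {size} exceeds recording length {rec.n_samples}")
    stride = stride_for(size, overlap)
    starts = np.arange(0, rec.n_samples - size + 1, stride, dtype=np.int64)

    view = np.lib.stride_tricks.sliding_window_view(rec.data, size, axis=1)  # (C, n_samples-size+1, size)
    vals = np.ascontiguousarray(view[:, starts, :].transpose(1, 0, 2))

    midx = rec.marker_indices  # sorted ascending by construction
    lo = np.searchsorted(midx, starts, side="left")
    hi = np.searchsorted(midx, starts + size, side="left")
    labels = (hi > lo).astype(np.int8)
    ids = [tuple(range(int(a), int(b))) for a, b in zip(lo, hi)]
    return WindowDataset(
        values=vals, labels=labels, starts=starts, marker_ids=ids,
        size=size, overlap=overlap, role=role,
    )
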