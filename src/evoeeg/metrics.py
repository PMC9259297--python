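"""Confusion-matrix metrics and feature-selection summary statistics.

The classifier is scored per window with precision (PPV), sensitivity
(TPR) and their harmonic mean F1:

    PPV = TP / (TP + FP),  TPR = TP / (TP + FN),
    F1  = 2 * PPV * TPR / (PPV + TPR).

Ratios with zero denominators are reported as 0 and flagged — this also
gives degenerate classifiers a well-defined (worst) fitness, keeping the
evolutionary search totally ordered.

Selection statistics summarise the feature totals of repeated search
runs; the exclusion percentage phi states what fraction of the full
window-by-channel input (window_size * n_channels values) a mean
selection omits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and derived metrics for one evaluation."""

    TP: int
    FP: int
    TN: int
    FN: int
    PPV: float
    TPR: float
    F1: float
    undefined: tuple[str, ...] = ()  # metrics that had a zero denominator

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "EvalResult":
        undefined = []
        if tp + fp > 0:
            ppv = tp / (tp + fp)
        else:
            ppv, undefined = 0.0, undefined + ["PPV"]
        if tp + fn > 0:
            tpr = tp / (tp + fn)
        else:
            tpr, undefined = 0.0, undefined + ["TPR"]
        if ppv + tpr > 0:
            f1 = 2.0 * ppv * tpr / (ppv + tpr)
        else:
            f1, undefined = 0.0, undefined + ["F1"]
        return cls(tp, fp, tn, fn, ppv, tpr, f1, tuple(undefined))


def score(predictions, truths) -> EvalResult:
    """Confusion counts and PPV/TPR/F1 for paired binary label sequences."""
    p = np.asarray(predictions).ravel().astype(np.int8)
    t = np.asarray(truths).ravel().astype(np.int8)
    if p.shape != t.shape:
        raise MetricError(f"length mismatch: {p.shape} predictions vs {t.shape} truths")
    tp = int(np.sum((p == 1) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    return EvalResult.from_counts(tp, fp, tn, fn)


def score_events(predictions, window_marker_ids) -> EvalResult:
    """Event-level scoring of sliding-window predictions.

    With overlapped sliding windows, one event marker appears in several
    consecutive windows, and a detector trained on event-centered
    examples fires only on the near-centered view. Counting every such
    window as its own instance would charge a false negative for each
    off-center view of a correctly detected event, capping F1 near
    2/(1 + windows-per-marker) no matter how good the detector is.
    Event-level scoring instead counts each marker cluster (markers
    transitively sharing a window) as one positive instance, detected if
    any of its windows is predicted positive; windows with no marker
    remain individual negative instances. This is the scoring that makes
    TP + FN track the event count while TN tracks the window count.

    Parameters
    ----------
    predictions
        Binary window predictions.
    window_marker_ids
        Per-window tuples of marker ids (as in
        :attr:`~evoeeg.segment.WindowDataset.marker_ids`).
    """
    p = np.asarray(predictions).ravel().astype(np.int8)
    if len(p) != len(window_marker_ids):
        raise MetricError(
            f"length mismatch: {len(p)} predictions vs {len(window_marker_ids)} windows"
        )
    # union-find over markers: markers sharing a window form one event cluster
    parent: dict[int, int] = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ids in window_marker_ids:
        for m in ids:
            parent.setdefault(m, m)
        for m in ids[1:]:
            parent[find(ids[0])] = find(m)

    detected: dict[int, bool] = {}
    fp = tn = 0
    for pred, ids in zip(p, window_marker_ids):
        if ids:
            root = find(ids[0])
            detected[root] = detected.get(root, False) or bool(pred)
        elif pred:
            fp += 1
        else:
            tn += 1
    tp = sum(detected.values())
    fn = len(detected) - tp
    return EvalResult.from_counts(tp, fp, tn, fn)


def reduction_phi(mean_selected: float, full_input: int = 2000) -> float:
    """Percent of the full input omitted by a mean selection size.

    The reference full input is 2000 values (250-sample window x 8
    channels).
    """
    if full_input <= 0:
        raise MetricError("full_input must be positive")
    if not (0 <= mean_selected <= full_input):
        raise MetricError(f"mean_selected {mean_selected} outside [0, {full_input}]")
    return (1.0 - mean_selected / full_input) * 100.0


def events_exclusion_correlation(event_counts, phi_values) -> float:
    """Pearson correlation between per-problem event counts and the mean
    exclusion percentages of the selections found for them."""
    x = np.asarray(event_counts, dtype=float)
    y = np.asarray(phi_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MetricError("inputs must be equal-length 1-D sequences")
    if len(x) < 3:
        raise MetricError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MetricError("correlation undefined: zero variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class SelectionStats:
    """Order statistics of per-run selected-feature totals.

    ``sd`` is the sample standard deviation (ddof=1; 0 for a single run);
    ``phi`` is the mean exclusion percentage w.r.t. ``full_input``.
    """

    minimum: float
    median: float
    maximum: float
    mean: float
    sd: float
    phi: float
    full_input: int


def summarize_runs(totals, full_input: int = 2000) -> SelectionStats:
    """Summary statistics over per-run selected-feature totals."""
    t = np.asarray(totals, dtype=float)
    if t.size == 0:
        raise MetricError("empty run list")
    sd = float(np.std(t, ddof=1)) if t.size > 1 else 0.0
    mean = float(np.mean(t))
    return SelectionStats(
        minimum=float(np.min(t)), median=float(np.median(t)), maximum=float(np.max(t)),
        mean=mean, sd=sd, phi=reduction_phi(mean, full_input), full_input=full_input,
    )
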