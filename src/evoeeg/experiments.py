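"""Experiment drivers: repeated feature extraction and generalization.

``experiment1`` runs the full pipeline on one or more recordings: clean
(notch, band-pass, min-max), split 70/30 by events, then perform
``n_runs`` independent seeded evolutionary searches per recording. Each
run contributes one row — overlap percent, per-channel selected feature
counts, total, confusion counts and PPV/TPR/F1 — to a report sorted
ascending by F1 and then by total selected features (the search
maximises F1 and, among ties, prefers compact inputs).

Choosing the *best* solution is not a pure sort: an analyst criterion
requires the known event-relevant channels (Fp1/Fp2 for blinks) to be
present. ``pick_best`` implements that three-part rule: F1 at least a
floor (0.90 by default), required channels included, fewest features.

``experiment2`` revalidates a chosen solution on a held-out recording:
the recording is cleaned identically, segmented into sliding windows at
the solution's overlap, and the (deterministically retrained) model's
predictions are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EEGRecording
from .preprocess import FilterSpec, preprocess
from .segment import split_by_events, make_sliding_set
from .metrics import EvalResult, SelectionStats, score, score_events, summarize_runs
from .ga import (
    GAConfig, GARun, Individual, Phenotype, WrapperEvaluator, decode, run_ga,
)
from .mlp import MLPModel


class ExperimentError(ValueError):
    pass


REPORT_COLUMNS = ("run", "overlap_pct", "total", "TP", "FP", "TN", "FN", "PPV", "TPR", "F1")


@dataclass
class RunOutcome:
    """One evolutionary run's best solution plus context to rebuild it."""

    seed: int
    best: Individual
    phenotype: Phenotype
    run: GARun


@dataclass
class ExperimentReport:
    """Per-problem report over repeated runs."""

    problem: str
    table: pd.DataFrame            # one row per run, sorted by (F1, total) asc
    stats: SelectionStats
    outcomes: list[RunOutcome]     # in run order (unsorted)
    train_rec: EEGRecording
    val_rec: EEGRecording
    channel_labels: tuple[str, ...]

    @property
    def worst(self) -> pd.Series:
        return self.table.iloc[0]

    @property
    def median(self) -> pd.Series:
        return self.table.iloc[len(self.table) // 2]

    def outcome_for_row(self, row: pd.Series) -> RunOutcome:
        return self.outcomes[int(row["run"])]


def pick_best(
    candidates: list[Individual],
    required_channels: tuple[int, ...] = (0, 1),
    min_f1: float = 0.90,
) -> Individual | None:
    """Analyst selection rule: F1 >= ``min_f1``, all ``required_channels``
    active, fewest total selected features (F1 breaks remaining ties).
    Returns None when no candidate qualifies."""
    req = set(required_channels)
    ok = [
        ind for ind in candidates
        if ind.fitness >= min_f1 and req.issubset(decode(ind.chrom).active_channels)
    ]
    if not ok:
        return None
    return min(ok, key=lambda ind: (ind.total_selected, -ind.fitness))


def run_seed(master_seed: int, index: int) -> int:
    """Per-run seed spawned from a master seed by counter."""
    return (master_seed * 1009 + index) % (2 ** 31)


def _report_row(run_idx: int, out: RunOutcome, labels) -> dict:
    phen = out.phenotype
    res = out.best.eval_result
    row = {"run": run_idx, "overlap_pct": int(round(phen.overlap * 100))}
    for ch, label in enumerate(labels):
        row[label] = int(phen.per_channel_counts[ch])
    row.update(
        total=out.best.total_selected,
        TP=res.TP, FP=res.FP, TN=res.TN, FN=res.FN,
        PPV=res.PPV, TPR=res.TPR, F1=res.F1,
    )
    return row


def experiment1(
    recordings: list[EEGRecording],
    n_runs: int = 31,
    ga_config: GAConfig = None,
    filter_spec: FilterSpec = FilterSpec(),
    window_size: int = 250,
    train_frac: float = 0.7,
    master_seed: int = 0,
    problem_names: list[str] | None = None,
    evaluator_kwargs: dict | None = None,
) -> list[ExperimentReport]:
    """Repeated feature extraction on each recording.

    Runs share the preprocessed recording and window-dataset caches but
    use independent seeds (spawned by counter from ``master_seed``), so
    the whole experiment is reproducible bit-for-bit.
    """
    if n_runs < 1:
        raise ExperimentError("n_runs must be >= 1")
    base_cfg = ga_config if ga_config is not None else GAConfig()
    ev_kwargs = evaluator_kwargs or {}
    reports = []
    for ri, rec in enumerate(recordings):
        name = problem_names[ri] if problem_names else f"A-{ri + 1}"
        clean = preprocess(rec, filter_spec)
        train_rec, val_rec = split_by_events(clean, train_frac)
        dataset_cache: dict = {}
        outcomes = []
        for r in range(n_runs):
            seed = run_seed(master_seed, ri * 1000 + r)
            evaluator = WrapperEvaluator(
                train_rec, val_rec, window_size=window_size, seed=seed,
                dataset_cache=dataset_cache, **ev_kwargs
            )
            cfg = GAConfig(
                pop_size=base_cfg.pop_size, generations=base_cfg.generations,
                crossover_rate=base_cfg.crossover_rate,
                mutation_initial=base_cfg.mutation_initial,
                mutation_final=base_cfg.mutation_final, seed=seed,
            )
            garun = run_ga(evaluator, cfg, n_channels=rec.n_channels)
            outcomes.append(RunOutcome(seed, garun.best, garun.best_phenotype, garun))
        rows = [_report_row(r, out, rec.channel_labels) for r, out in enumerate(outcomes)]
        table = (
            pd.DataFrame.from_records(rows)
            .sort_values(["F1", "total"], ascending=[True, True], kind="mergesort")
            .reset_index(drop=True)
        )
        full_input = window_size * rec.n_channels
        stats = summarize_runs([o.best.total_selected for o in outcomes], full_input)
        reports.append(ExperimentReport(
            problem=name, table=table, stats=stats, outcomes=outcomes,
            train_rec=train_rec, val_rec=val_rec, channel_labels=rec.channel_labels,
        ))
    return reports


def rebuild_model(report: ExperimentReport, outcome: RunOutcome, **evaluator_kwargs) -> MLPModel:
    """Deterministically retrain the MLP of a run's best solution (same
    derived seed, same data) so it can be applied to new recordings."""
    evaluator = WrapperEvaluator(
        report.train_rec, report.val_rec, seed=outcome.seed, **evaluator_kwargs
    )
    f1, _, model = evaluator.evaluate_phenotype(
        outcome.phenotype, evaluator.mlp_seed(outcome.best.chrom)
    )
    if abs(f1 - outcome.best.fitness) > 1e-12:
        raise ExperimentError("rebuilt model does not reproduce the logged fitness")
    return model


def experiment2(
    phenotype: Phenotype,
    model: MLPModel,
    rec_b: EEGRecording,
    filter_spec: FilterSpec = FilterSpec(),
    window_size: int = 250,
    event_level: bool = True,
) -> EvalResult:
    """Score a trained solution on a held-out recording (test stage).

    Scoring is event-level by default: each marker cluster is one
    positive instance, each marker-free window one negative instance
    (see :func:`~evoeeg.metrics.score_events`).
    """
    if phenotype.feature_mask.shape[0] != rec_b.n_channels:
        raise ExperimentError(
            f"phenotype expects {phenotype.feature_mask.shape[0]} channels, "
            f"recording has {rec_b.n_channels}"
        )
    clean = preprocess(rec_b, filter_spec)
    test_set = make_sliding_set(clean, window_size, phenotype.overlap, role="test")
    X = test_set.flattened(phenotype.feature_mask_flat)
    pred = model.predict(X)
    if event_level:
        return score_events(pred, test_set.marker_ids)
    return score(pred, test_set.labels)
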