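"""Test a selected solution on a held-out recording.

experiment1 performs repeated evolutionary searches on a session-A
recording; the analyst-picked best solution is then deterministically
retrained and scored on an unseen session-B recording (experiment2),
event-level: each blink is one positive instance, each marker-free
window one negative.
"""

from evoeeg import (
    GAConfig, SynthConfig, WrapperEvaluator, decode, experiment1,
    experiment2, generate, pick_best,
)

rec_a = generate(SynthConfig(seed=0))
rec_b = generate(SynthConfig(seed=1000, duration=60.0, n_events=22))

report = experiment1(
    [rec_a], n_runs=2, ga_config=GAConfig(pop_size=20, generations=30),
    master_seed=0,
)[0]
print(report.table[["run", "overlap_pct", "total", "TP", "FP", "TN", "FN", "F1"]]
      .to_string(index=False))

# analyst pick over every solution the searches evaluated: a final
# population often prunes one of two redundant frontal channels, so the
# run archives are the right place to enforce "Fp1 and Fp2 present"
archive = [ind for o in report.outcomes for ind in o.run.archive]
best = pick_best(archive, required_channels=(0, 1), min_f1=0.9)
if best is None:
    raise SystemExit("no archived solution met the analyst criteria")
phen = decode(best.chrom)
print(f"\nanalyst pick: F1={best.fitness:.4f}, overlap {phen.overlap:.0%}, "
      f"channels {phen.active_channels}, {best.total_selected}/2000 features")

# retrain the picked solution deterministically (same derived seed, same data)
owner = next(o for o in report.outcomes
             if any(i.chrom.key() == best.chrom.key() for i in o.run.archive))
evaluator = WrapperEvaluator(report.train_rec, report.val_rec, seed=owner.seed)
_, _, model = evaluator.evaluate_phenotype(phen, evaluator.mlp_seed(best.chrom))

result = experiment2(phen, model, rec_b)
print(f"\nheld-out session ({len(rec_b.markers)} events): "
      f"TP={result.TP} FP={result.FP} TN={result.TN} FN={result.FN} "
      f"PPV={result.PPV:.4f} TPR={result.TPR:.4f} F1={result.F1:.4f}")
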