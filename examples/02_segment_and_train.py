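"""Split a recording by events, segment into windows, and train the MLP.

The recording is split so the leading segment holds 70% of the events.
Training windows are event-centered positives plus overlapped negatives
from the remaining signal; validation windows slide uniformly over the
held-back segment. The classifier is a two-hidden-layer ReLU network
with a sigmoid output, sized by the geometric-pyramid rule and trained
for 10 epochs on MSE.

The comparison below is the package's whole premise in miniature: with
all 2000 inputs the 10-epoch budget is not enough to learn anything,
while the same budget on the 500 frontal-channel inputs (where the
blink actually lives) detects every event. Finding such subsets
automatically is what the genetic algorithm is for (example 03).
"""

import numpy as np

from evoeeg import (
    MLPModel, SynthConfig, generate, make_sliding_set, make_training_set,
    preprocess, score_events, size_layers, split_by_events,
)

rec = preprocess(generate(SynthConfig(seed=1)))
train_rec, val_rec = split_by_events(rec, 0.7)
print(f"{len(rec.markers)} events -> {len(train_rec.markers)} train / "
      f"{len(val_rec.markers)} validation")

overlap = 0.85
train_set = make_training_set(train_rec, size=250, overlap=overlap)
val_set = make_sliding_set(val_rec, size=250, overlap=overlap)
n_pos = int(train_set.labels.sum())
print(f"training windows: {len(train_set)} ({n_pos} positive), "
      f"validation windows: {len(val_set)}")

def fit_and_score(mask, name):
    n_in = int(mask.sum())
    spec = size_layers(n_in)
    print(f"\n{name}: {spec.IL} -> {spec.HL1} -> {spec.HL2} -> {spec.OL}")
    model = MLPModel(spec).fit(train_set.flattened(mask), train_set.labels)
    pred = model.predict(val_set.flattened(mask))
    result = score_events(pred, val_set.marker_ids)
    print(f"  validation (event-level): TP={result.TP} FP={result.FP} "
          f"TN={result.TN} FN={result.FN}  F1={result.F1:.4f}")


full = np.ones(2000, dtype=bool)          # all 8 channels x 250 samples
frontal = np.zeros(2000, dtype=bool)
frontal[:500] = True                      # Fp1 + Fp2 only

fit_and_score(full, "all channels (2000 inputs)")
fit_and_score(frontal, "frontal channels only (500 inputs)")
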