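# Methods note

This note records the model implemented by `evoeeg`, the parameter
choices and their units, the numerical conventions, and the known
limitations. Nothing here asserts empirical results beyond what the
test suite and `scripts/acceptance.py` actually compute.

## 1. Problem and pipeline

The task is binary detection of eye-blink events in 8-channel scalp
EEG sampled at 250 Hz. The pipeline is:

1. **Preprocess** — 60 Hz notch, 1–12 Hz band-pass, per-channel
   min-max scaling to [0, 1].
2. **Split** — the leading signal segment containing 70% of the event
   markers becomes the training portion; the rest is validation.
3. **Segment** — fixed 250-sample (1 s) windows. Training windows are
   centered on event markers (positives) plus overlapped windows cut
   from the remaining signal (negatives); validation and test windows
   slide uniformly from sample 0.
4. **Classify** — a 2-hidden-layer MLP on the flattened, selected
   window samples.
5. **Select features** — a GA searches overlap, channel, and
   per-sample masks; fitness is the validation F1 of a model trained
   on exactly the candidate subset.
6. **Generalize** — the chosen solution is deterministically retrained
   and scored on a held-out recording.

## 2. Preprocessing

- Notch: IIR notch at 60 Hz (quality factor 30), applied zero-phase
  with `scipy.signal.filtfilt`. Removes mains interference.
- Band-pass: 4th-order Butterworth, 1–12 Hz, zero-phase
  (`sosfiltfilt`). The blink deflection is a low-frequency transient;
  this band retains it while discarding EMG and residual line noise.
- Scaling: per-channel min-max to [0, 1]. Channel gains differ across
  electrodes, and the MLP input must be bounded. A constant (flat)
  channel raises an error naming the channel. By default extrema are
  taken over the full recording; a `train_only` scope is available to
  avoid using validation samples in the scaling.

## 3. Segmentation conventions

- Window intervals are half-open `[start, start + size)`.
- Stride for overlap `v`: `max(1, floor(size * (1 - v) + 0.5))` —
  round-half-up, clamped to at least 1 sample.
- A sliding window is labeled 1 iff at least one marker index lies in
  its interval; it records *which* markers, since one marker typically
  appears in several consecutive windows at high overlap.
- Training positives are centered: `start = marker - size // 2`.
  Markers too close to an edge are skipped with a warning. The union
  of positive ranges is removed and each remaining contiguous run at
  least `size` long is cut into negatives at the configured overlap.
- Event split: with `n` markers, the first `floor(0.7 n + 0.5)` stay
  in the training part; the cut falls at the midpoint between the last
  training marker and the first validation marker, and the second
  part's markers are re-based to its own origin.

## 4. Classifier

Architecture: input `IL` (number of selected inputs), two ReLU hidden
layers, one sigmoid output. Hidden sizes follow a geometric pyramid:
`kappa = (IL / OL)^(1/3)`, `HL1 = round(OL * kappa^2)`,
`HL2 = round(OL * kappa)`, clamped so `IL >= HL1 >= HL2 >= OL`. For
the full 2000-sample input this gives 159 and 13 hidden units; for
1000 inputs, 100 and 10. A square-root sizing rule is available as an
option.

Training: minibatch backpropagation on mean squared error, 10 epochs,
learning rate 0.01, batch size 32, inclusive decision threshold 0.5,
weights initialized uniform ±1/√fan_in from a per-model seed.

**Optimizer.** The default is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8)
rather than plain gradient descent. With min-max-scaled, all-positive
inputs and a ~10:1 negative:positive class ratio, plain (and momentum)
gradient descent collapses to a constant output within the 10-epoch
budget across a wide learning-rate range: the shared sign of the
inputs drives the first ReLU layer dead and the loss plateaus at the
base-rate variance. Adam's per-parameter step normalization escapes
this regime reliably at the same learning rate and epoch budget.
`optimizer="sgd"` (with momentum 0.9) remains available.

## 5. Scoring

Window-level confusion counts (`score`) treat every window as an
instance. For overlapped sliding windows this systematically
understates detector quality: a marker spans roughly
`1 / (1 - overlap)` consecutive windows, but a detector trained on
*centered* positives fires only on the near-centered view, so every
off-center view of a correctly detected event would count as a false
negative — capping F1 near `2 / (1 + windows-per-marker)` regardless
of detector quality.

Fitness and held-out evaluation therefore use **event-level scoring**
(`score_events`): markers that transitively share a window are merged
into one cluster (union-find); each cluster is one positive instance,
detected iff any of its windows is predicted positive; marker-free
windows remain individual negative instances. Under this scheme
TP + FN equals the event count and TN tracks the window count.
Training-set style datasets, where each marker occupies exactly one
window, give identical counts under both schemes.

Derived metrics: PPV = TP/(TP+FP), TPR = TP/(TP+FN), F1 their
harmonic mean; zero denominators yield 0 and are flagged. The
reduction statistic φ = (1 − selected/2000) · 100 expresses the
percentage of the full input excluded.

## 6. Genetic algorithm

Chromosome (2015 bits):

- bits 0–6: window overlap, Gray-coded. 81 levels map to 10–90% in 1%
  steps; codes ≥ 81 wrap modulo 81. Gray coding makes adjacent
  overlap levels differ by one bit, so a single mutation perturbs the
  overlap minimally.
- bits 7–14: channel mask (8 bits).
- bits 15–2014: per-channel sample masks (8 × 250). A feature is
  active iff its own bit *and* its channel bit are set.

Operators, with defaults:

- Selection: binary tournament with replacement; higher fitness wins,
  ties go to the candidate with fewer selected features.
- Crossover: uniform, applied with probability 0.9; when applied, each
  bit position swaps independently with probability 0.5 (alleles are
  conserved position-wise across the two children).
- Mutation: independent per-bit flips at a linearly decaying rate,
  from 10/η at generation 0 to 1/η at the last generation (η = 2015):
  broad exploration early, fine tuning late.
- Survivor selection: μ+λ — parents and offspring pooled, best μ kept
  (elitist, so the best fitness trace is monotone non-decreasing).
- Scale: population 50 for 200 generations at full scale; population
  20 for 30 generations for desk-scale runs and tests.

Fitness evaluation caches (a) window datasets per overlap level —
they are independent of the feature subset — and (b) fitness per
genotype. The MLP seed for a genotype is derived from the run seed and
a CRC-32 of the bitstring, so every evaluation is reproducible.
An empty feature subset scores 0 without training.

**Best-solution rule.** The search's own ordering (F1, then fewest
features) legitimately prunes redundant channels: when Fp1 alone
suffices for F1 = 1.0, final populations drop Fp2. Selecting the
deployable solution therefore uses an analyst rule (`pick_best`):
F1 ≥ 0.90, all required channels present (Fp1 and Fp2 for blinks),
fewest features, applied over the run's *archive* — every distinct
solution evaluated during the search — not just the final population.

## 7. Synthetic data

`SynthConfig` defaults describe a desk-scale 120 s calibration clip at
250 Hz with 45 blinks (22.5/min, within the normal spontaneous range):

| parameter | default | meaning |
|---|---|---|
| `blink_channels` | (0, 1) | Fp1, Fp2 — where blink artifacts originate |
| `blink_amplitude` | 120 µV | half-sine pulse peak, ~12× background |
| `blink_width_ms` | 300 ms | pulse support |
| `background_sd` | 10 µV | white Gaussian component |
| `alpha_amp`, `alpha_freq` | 5 µV, 10 Hz | per-channel-phase rhythm |
| `line_amp`, `line_freq` | 8 µV, 60 Hz | mains interference (common phase) |
| `min_gap` | 250 samples | minimum peak spacing |
| `amplitude_jitter` | 0.2 | per-event, per-channel relative amplitude spread |

One marker is placed at each pulse peak; events keep an edge margin of
`max(blink_width, fs/2)` samples so every marker can center a 1 s
window. Event positions are sorted uniforms with re-inflated minimum
gaps. The 120 s / 45-event default was fixed once, before the recovery
experiments, so that the event-centered training split carries ~31
positive examples — enough for a well-conditioned 10-epoch fit.

What the generator *does* emulate: frontal localization and the
low-frequency transient shape of blinks, amplitude variability,
background rhythm and mains interference, realistic event rates.

What it does *not* emulate: 1/f background spectra, non-blink
artifacts (EMG, saccades, electrode pops), inter-channel correlation
structure of real EEG, drift, or variable blink morphology. Synthetic
results are a correctness and recoverability check of the pipeline,
not evidence about real-EEG performance.

`make_problem_suite` emits four A/B recording pairs with the event and
sample counts of a reference 4-participant acquisition campaign (e.g.
183 events / 183114 samples), scalable for fast reruns.

## 8. Numerical conventions and determinism

- Rounding is round-half-up (`floor(x + 0.5)`) for strides, layer
  sizes, and the event-split count.
- Ties in selection and survivor sorting break toward fewer selected
  features; exact ties preserve draw/pool order.
- Seeds: per-run seeds spawn from a master seed by counter
  (`(master * 1009 + index) mod 2^31`); MLP seeds derive from run seed
  and genotype hash. All seeds are < 2^31.
- Filters run in float64; the MLP uses float64 throughout; the
  sigmoid is computed in a numerically stable split form.

## 9. Limitations

- Event-level scoring assumes markers of one physiological event
  cluster via shared windows; at very low overlaps an event can only
  appear in one window, where event- and window-level scoring agree.
- The wrapper fitness retrains one MLP per candidate — the dominant
  cost (tens of milliseconds per evaluation at desk scale; ~10⁴
  trainings per full-scale run).
- Single-label (blink-only) detection; multi-class events would need
  a wider output layer and different scoring.
- The Adam default is a deliberate deviation from plain minibatch
  gradient descent, adopted for trainability at the 10-epoch budget
  (see §4); results with `optimizer="sgd"` will differ.
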