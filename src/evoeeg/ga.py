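"""Genetic search over window overlap, channels and sample points.

Each individual is a bitstring with three gene groups:

* a Gray-coded overlap gene (7 bits) decoding to an integer-percent
  overlap in [0.10, 0.90] (81 levels; codes beyond the range wrap by
  modulo) — Gray coding keeps single-bit mutations phenotypically small;
* one flag bit per channel (8 for the reference montage);
* one flag bit per sample offset per channel (250 each). A sample point
  is an active input feature iff its own bit AND its channel's bit are 1.

Fitness is the wrapper objective: rebuild the training set (event
centered) and validation set (sliding) at the decoded overlap, size an
MLP for the selected input width, train it 10 epochs and return the
validation F1. The search uses binary tournament selection, uniform
crossover, uniform bit mutation with a linearly decaying rate
(10/eta down to 1/eta over the generations, eta = chromosome length) and
mu+lambda survivor selection. Ties in every comparison break toward
fewer selected features, mirroring the secondary objective of a compact
input.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EEGRecording
from .segment import make_training_set, make_sliding_set
from .mlp import size_layers, MLPModel
from .metrics import EvalResult, score, score_events


class GAError(ValueError):
    pass


OVERLAP_BITS = 7
OVERLAP_LEVELS = 81       # integer percents 10..90
OVERLAP_MIN = 0.10
OVERLAP_STEP = 0.01


# ---------------------------------------------------------------------------
# Gray coding
# ---------------------------------------------------------------------------

def gray_encode(n: int, width: int) -> np.ndarray:
    """Gray code of ``n`` as a most-significant-bit-first uint8 array."""
    g = n ^ (n >> 1)
    return np.array([(g >> (width - 1 - i)) & 1 for i in range(width)], dtype=np.uint8)


def gray_decode(bits: np.ndarray) -> int:
    """Integer value of a MSB-first Gray-coded bit array."""
    g = 0
    for b in bits:
        g = (g << 1) | int(b)
    n = 0
    while g:
        n ^= g
        g >>= 1
    return n


# ---------------------------------------------------------------------------
# Genotype / phenotype
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    """Bitstring genotype: overlap gene + channel flags + feature flags."""

    bits: np.ndarray
    n_channels: int = 8
    n_features: int = 250  # per channel (max window size m)

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1 or len(bits) != self.length:
            raise GAError(f"chromosome must have {self.length} bits, got {bits.shape}")
        if not np.isin(bits, (0, 1)).all():
            raise GAError("chromosome bits must be 0/1")

    @property
    def length(self) -> int:
        return OVERLAP_BITS + self.n_channels + self.n_channels * self.n_features

    @property
    def overlap_bits(self) -> np.ndarray:
        return self.bits[:OVERLAP_BITS]

    @property
    def channel_bits(self) -> np.ndarray:
        return self.bits[OVERLAP_BITS:OVERLAP_BITS + self.n_channels]

    @property
    def feature_bits(self) -> np.ndarray:
        return self.bits[OVERLAP_BITS + self.n_channels:].reshape(self.n_channels, self.n_features)

    def key(self) -> bytes:
        return self.bits.tobytes()

    @classmethod
    def random(cls, rng: np.random.Generator, n_channels: int = 8, n_features: int = 250) -> "Chromosome":
        n = OVERLAP_BITS + n_channels + n_channels * n_features
        return cls(rng.integers(0, 2, size=n, dtype=np.uint8), n_channels, n_features)


@dataclass(frozen=True)
class Phenotype:
    """Decoded meaning of a chromosome."""

    overlap: float
    active_channels: tuple[int, ...]
    feature_mask: np.ndarray  # (n_channels, n_features) bool, channel gating applied
    total_selected: int

    @property
    def feature_mask_flat(self) -> np.ndarray:
        """Channel-major boolean mask over the full window-by-channel input."""
        return self.feature_mask.ravel()

    @property
    def per_channel_counts(self) -> np.ndarray:
        """Selected features per channel (0 for inactive channels)."""
        return self.feature_mask.sum(axis=1).astype(int)


def decode(chrom: Chromosome) -> Phenotype:
    """Genotype -> phenotype: overlap level, channel mask, gated features."""
    level = gray_decode(chrom.overlap_bits) % OVERLAP_LEVELS
    overlap = OVERLAP_MIN + level * OVERLAP_STEP
    ch = chrom.channel_bits.astype(bool)
    mask = chrom.feature_bits.astype(bool) & ch[:, None]
    return Phenotype(
        overlap=round(overlap, 2),
        active_channels=tuple(int(i) for i in np.flatnonzero(ch)),
        feature_mask=mask,
        total_selected=int(mask.sum()),
    )


def encode(
    phen: Phenotype, n_channels: int = 8, n_features: int = 250
) -> Chromosome:
    """Phenotype -> canonical chromosome (inverse of :func:`decode` for
    phenotypes whose feature mask respects the channel gating)."""
    level = int(np.floor((phen.overlap - OVERLAP_MIN) / OVERLAP_STEP + 0.5))
    if not (0 <= level < OVERLAP_LEVELS):
        raise GAError(f"overlap {phen.overlap} outside [{OVERLAP_MIN}, 0.90]")
    bits = np.zeros(OVERLAP_BITS + n_channels + n_channels * n_features, dtype=np.uint8)
    bits[:OVERLAP_BITS] = gray_encode(level, OVERLAP_BITS)
    ch = np.zeros(n_channels, dtype=np.uint8)
    ch[list(phen.active_channels)] = 1
    bits[OVERLAP_BITS:OVERLAP_BITS + n_channels] = ch
    bits[OVERLAP_BITS + n_channels:] = phen.feature_mask.astype(np.uint8).ravel()
    return Chromosome(bits, n_channels, n_features)


# ---------------------------------------------------------------------------
# Configuration and evaluated individuals
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    """Evolution parameters. Mutation endpoints default to 10/eta and
    1/eta with eta the chromosome bit length."""

    pop_size: int = 50
    generations: int = 200
    crossover_rate: float = 0.9
    mutation_initial: float | None = None
    mutation_final: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 2:
            raise GAError("population size must be >= 2")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise GAError("crossover rate must be in [0, 1]")

    def mutation_rate(self, generation: int, chrom_length: int) -> float:
        """Linearly decaying per-bit flip probability at a generation."""
        mi = self.mutation_initial if self.mutation_initial is not None else 10.0 / chrom_length
        mf = self.mutation_final if self.mutation_final is not None else 1.0 / chrom_length
        if mi < mf or mf <= 0:
            raise GAError("mutation schedule requires m_initial >= m_final > 0")
        if self.generations == 1:
            return mi
        frac = generation / (self.generations - 1)
        return mi + (mf - mi) * frac


@dataclass(frozen=True)
class Individual:
    """A chromosome with its evaluation."""

    chrom: Chromosome
    fitness: float
    total_selected: int
    eval_result: EvalResult | None = None

    @property
    def sort_key(self) -> tuple[float, int]:
        """Higher fitness is better; fewer features break ties."""
        return (-self.fitness, self.total_selected)


def _better(a: Individual, b: Individual) -> Individual:
    """The better of two by fitness, then sparsity; ``a`` wins exact ties
    (draw order)."""
    return b if b.sort_key < a.sort_key else a


# ---------------------------------------------------------------------------
# Wrapper fitness
# ---------------------------------------------------------------------------

class WrapperEvaluator:
    """Trains and validates the MLP for candidate phenotypes.

    Holds a preprocessed training/validation recording pair and caches
    (a) window datasets per decoded overlap level — they do not depend
    on the feature subset — and (b) fitness per genotype. The MLP seed
    for a genotype is derived from the run seed and a genotype hash, so
    re-evaluating an identical chromosome is deterministic.
    """

    def __init__(
        self,
        train_rec: EEGRecording,
        val_rec: EEGRecording,
        window_size: int = 250,
        epochs: int = 10,
        learning_rate: float = 0.01,
        batch_size: int = 32,
        optimizer: str = "adam",
        threshold: float = 0.5,
        seed: int = 0,
        dataset_cache: dict | None = None,
        event_level: bool = True,
    ):
        self.train_rec = train_rec
        self.val_rec = val_rec
        self.window_size = window_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.threshold = threshold
        self.seed = seed
        self.event_level = event_level
        # overlap-keyed window datasets; shareable across runs on the same pair
        self._datasets: dict[float, tuple] = dataset_cache if dataset_cache is not None else {}
        self._fitness: dict[bytes, tuple[float, EvalResult | None]] = {}
        self.n_evaluations = 0   # actual MLP trainings (cache misses)

    def datasets(self, overlap: float):
        """(X_train, y_train, X_val, y_val, val_marker_ids) at an overlap,
        full feature width."""
        key = round(overlap, 2)
        if key not in self._datasets:
            tr = make_training_set(self.train_rec, self.window_size, key)
            va = make_sliding_set(self.val_rec, self.window_size, key, role="validation")
            self._datasets[key] = (tr.flattened(), tr.labels, va.flattened(), va.labels, va.marker_ids)
        return self._datasets[key]

    def mlp_seed(self, chrom: Chromosome) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(chrom.key())) % (2 ** 31)

    def evaluate_phenotype(
        self, phen: Phenotype, mlp_seed: int
    ) -> tuple[float, EvalResult, MLPModel | None]:
        """Train and validate for a phenotype; returns (F1, result, model)."""
        if phen.total_selected == 0:
            return 0.0, EvalResult.from_counts(0, 0, 0, 0), None
        Xtr, ytr, Xva, yva, va_ids = self.datasets(phen.overlap)
        mask = phen.feature_mask_flat
        spec = size_layers(phen.total_selected)
        spec.epochs = self.epochs
        spec.learning_rate = self.learning_rate
        spec.batch_size = self.batch_size
        spec.optimizer = self.optimizer
        spec.threshold = self.threshold
        spec.seed = mlp_seed
        model = MLPModel(spec).fit(Xtr[:, mask], ytr)
        pred = model.predict(Xva[:, mask])
        result = score_events(pred, va_ids) if self.event_level else score(pred, yva)
        return result.F1, result, model

    def fitness(self, chrom: Chromosome) -> Individual:
        key = chrom.key()
        phen = decode(chrom)
        if key not in self._fitness:
            f1, res, _ = self.evaluate_phenotype(phen, self.mlp_seed(chrom))
            self._fitness[key] = (f1, res)
            self.n_evaluations += 1
        f1, res = self._fitness[key]
        return Individual(chrom, f1, phen.total_selected, res)


# ---------------------------------------------------------------------------
# Variation and selection operators
# ---------------------------------------------------------------------------

def tournament_select(pop: list[Individual], rng: np.random.Generator) -> Individual:
    """Binary tournament with replacement; fitness then sparsity decides."""
    if len(pop) < 2:
        raise GAError("tournament needs a population of >= 2")
    i, j = rng.integers(0, len(pop), size=2)
    return _better(pop[i], pop[j])


def uniform_crossover(
    a: Chromosome, b: Chromosome, rate: float, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """With probability ``rate``, swap each bit position independently
    with probability 0.5; otherwise return copies of the parents."""
    if len(a.bits) != len(b.bits):
        raise GAError("parents must have equal length")
    if rng.random() >= rate:
        return (
            Chromosome(a.bits.copy(), a.n_channels, a.n_features),
            Chromosome(b.bits.copy(), b.n_channels, b.n_features),
        )
    swap = rng.random(len(a.bits)) < 0.5
    c1 = np.where(swap, b.bits, a.bits)
    c2 = np.where(swap, a.bits, b.bits)
    return (
        Chromosome(c1.astype(np.uint8), a.n_channels, a.n_features),
        Chromosome(c2.astype(np.uint8), b.n_channels, b.n_features),
    )


def mutate(
    chrom: Chromosome, generation: int, cfg: GAConfig, rng: np.random.Generator
) -> Chromosome:
    """Flip each bit independently at the generation's scheduled rate."""
    p = cfg.mutation_rate(generation, len(chrom.bits))
    flips = rng.random(len(chrom.bits)) < p
    return Chromosome(chrom.bits ^ flips.astype(np.uint8), chrom.n_channels, chrom.n_features)


def mu_plus_lambda(
    parents: list[Individual], offspring: list[Individual], mu: int
) -> list[Individual]:
    """Keep the best ``mu`` of parents and offspring pooled (elitist)."""
    if mu < 1:
        raise GAError("mu must be >= 1")
    pool = parents + offspring
    if mu > len(pool):
        raise GAError(f"mu={mu} exceeds pooled size {len(pool)}")
    return sorted(pool, key=lambda ind: ind.sort_key)[:mu]


# ---------------------------------------------------------------------------
# The evolutionary loop
# ---------------------------------------------------------------------------

@dataclass
class GARun:
    """Outcome of one evolutionary run.

    ``archive`` holds every distinct solution evaluated during the run
    (best first). The final population prunes redundant channels
    aggressively — with ties broken toward sparsity, a channel whose
    information duplicates another's is dropped without fitness loss —
    so analyst-style selection rules that require specific channels to
    be present (see :func:`evoeeg.experiments.pick_best`) are applied to
    the archive, the full set of solutions the search produced.
    """

    best: Individual
    population: list[Individual]       # final population, best first
    archive: list[Individual]          # all distinct evaluated solutions, best first
    log: pd.DataFrame                  # per-generation best/mean fitness
    config: GAConfig
    n_evaluations: int

    @property
    def best_phenotype(self) -> Phenotype:
        return decode(self.best.chrom)


def run_ga(
    evaluator: WrapperEvaluator,
    cfg: GAConfig,
    n_channels: int = 8,
    n_features: int = 250,
) -> GARun:
    """Evolve ``cfg.generations`` generations from a seeded random
    population and return the best individual found, the final population
    and a per-generation fitness log."""
    rng = np.random.default_rng(cfg.seed)
    archive: dict[bytes, Individual] = {}

    def evaluate(chrom: Chromosome) -> Individual:
        ind = evaluator.fitness(chrom)
        archive.setdefault(chrom.key(), ind)
        return ind

    pop = [
        evaluate(Chromosome.random(rng, n_channels, n_features))
        for _ in range(cfg.pop_size)
    ]
    pop.sort(key=lambda ind: ind.sort_key)
    records = []

    def log_gen(g):
        records.append({
            "generation": g,
            "best_f1": pop[0].fitness,
            "mean_f1": float(np.mean([ind.fitness for ind in pop])),
            "best_total_selected": pop[0].total_selected,
            "best_overlap": decode(pop[0].chrom).overlap,
        })

    log_gen(0)
    for g in range(cfg.generations):
        offspring: list[Individual] = []
        while len(offspring) < cfg.pop_size:
            pa = tournament_select(pop, rng)
            pb = tournament_select(pop, rng)
            c1, c2 = uniform_crossover(pa.chrom, pb.chrom, cfg.crossover_rate, rng)
            for child in (mutate(c1, g, cfg, rng), mutate(c2, g, cfg, rng)):
                if len(offspring) < cfg.pop_size:
                    offspring.append(evaluate(child))
        pop = mu_plus_lambda(pop, offspring, cfg.pop_size)
        log_gen(g + 1)

    return GARun(
        best=pop[0],
        population=pop,
        archive=sorted(archive.values(), key=lambda ind: ind.sort_key),
        log=pd.DataFrame.from_records(records),
        config=cfg,
        n_evaluations=evaluator.n_evaluations,
    )
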