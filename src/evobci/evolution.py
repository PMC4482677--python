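"""Genetic-algorithm search over MLP architectures.

Each candidate network is a 29-bit genome: 2 bits encode the hidden-layer
count (1-3) and three 9-bit fields encode the neuron count of each layer
(clamped to [1, 500]; fields beyond the layer count are ignored).  Parents
are drawn by roulette-wheel selection on validation-kappa fitness,
children by single-point crossover, and each child has a 2% chance of one
random bit flip.  The single fittest network (the elite) survives each
generation unchanged, which makes the elite fitness trajectory
non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annealing import SAConfig, sa_train
from .mlp import (
    MAX_NEURONS,
    Architecture,
    NetworkModel,
    TrainConfig,
    init_network,
)

__all__ = [
    "GENOME_BITS",
    "Genome",
    "GAConfig",
    "GAResult",
    "decode_genome",
    "encode_architecture",
    "mutate",
    "crossover",
    "roulette_select",
    "init_population",
    "evaluate_fitness",
    "run_ga",
]

_LAYER_BITS = 2
_NEURON_BITS = 9
GENOME_BITS = _LAYER_BITS + 3 * _NEURON_BITS  # 29


@dataclass(frozen=True)
class Genome:
    """Fixed-length binary string encoding an architecture."""

    bits: tuple[int, ...]

    def __init__(self, bits):
        bits = tuple(int(b) for b in bits)
        if len(bits) != GENOME_BITS:
            raise ValueError(f"genome must have {GENOME_BITS} bits, "
                             f"got {len(bits)}")
        if any(b not in (0, 1) for b in bits):
            raise ValueError("genome bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "Genome":
        return cls([int(c) for c in s])


def _bits_to_int(bits: Sequence[int]) -> int:
    out = 0
    for b in bits:
        out = (out << 1) | b
    return out


def _int_to_bits(x: int, width: int) -> list[int]:
    return [(x >> (width - 1 - i)) & 1 for i in range(width)]


def decode_genome(g: Genome) -> Architecture:
    """Total decoding: every 29-bit string is a valid architecture.

    Layer field 0b00->1, 0b01->2, 0b10->3, 0b11->3 (clamped); each used
    9-bit neuron field is clamped into [1, 500].
    """
    n_layers = min(_bits_to_int(g.bits[:_LAYER_BITS]) + 1, 3)
    sizes = []
    for i in range(n_layers):
        lo = _LAYER_BITS + i * _NEURON_BITS
        n = _bits_to_int(g.bits[lo : lo + _NEURON_BITS])
        sizes.append(min(max(n, 1), MAX_NEURONS))
    return Architecture(sizes)


def encode_architecture(a: Architecture | Sequence[int]) -> Genome:
    """Inverse of :func:`decode_genome` on valid architectures."""
    if not isinstance(a, Architecture):
        a = Architecture(a)
    bits = _int_to_bits(a.n_layers - 1, _LAYER_BITS)
    for i in range(3):
        n = a.hidden_sizes[i] if i < a.n_layers else 1
        bits += _int_to_bits(n, _NEURON_BITS)
    return Genome(bits)


@dataclass
class GAConfig:
    """Search-budget and operator parameters of the GA."""

    population: int = 30
    generations: int = 20
    elites: int = 1
    mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0 <= self.elites < self.population:
            raise ValueError("elites must lie in [0, population)")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class GAResult:
    """Outcome of one GA run."""

    best_model: NetworkModel
    best_genome: Genome
    best_fitness: float
    history: "object"  # pandas DataFrame: generation, min/mean/max/elite
    evaluations: list[tuple[str, tuple[int, ...], float]] = field(
        default_factory=list
    )

    def history_to_csv(self, path) -> None:
        self.history.to_csv(path, index=False)


def mutate(g: Genome, rate: float, seed: int) -> Genome:
    """With probability ``rate``, flip exactly one uniformly chosen bit.

    Mutation probability is per individual (one bit at most), not per bit.
    """
    rng = np.random.default_rng(seed)
    if rng.random() >= rate:
        return g
    i = int(rng.integers(GENOME_BITS))
    bits = list(g.bits)
    bits[i] ^= 1
    return Genome(bits)


def crossover(a: Genome, b: Genome, seed: int) -> Genome:
    """Single-point crossover: child = a[:c] + b[c:], c uniform in 1..28."""
    if len(a.bits) != len(b.bits):
        raise ValueError("genomes must have equal length")
    rng = np.random.default_rng(seed)
    c = int(rng.integers(1, GENOME_BITS))
    return Genome(a.bits[:c] + b.bits[c:])


def roulette_select(fitnesses, rng_or_seed) -> int:
    """Fitness-proportional parent index.

    Kappa fitness can be negative, so selection weights are the shifted
    values f - min(f) + 1e-6; all-equal fitness degrades gracefully to a
    uniform draw.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if fitnesses.size == 0:
        raise ValueError("need at least one individual")
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    w = fitnesses - fitnesses.min() + 1e-6
    return int(rng.choice(len(w), p=w / w.sum()))


def init_population(cfg: GAConfig, seed: int | None = None) -> list[Genome]:
    """Layer-stratified random initial population.

    One-, two- and three-layer genomes appear in counts differing by at
    most 1; neuron fields are uniform over [1, 500].
    """
    if cfg.population < 3:
        raise ValueError("stratified initialisation needs population >= 3")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    layer_counts = [1 + (i % 3) for i in range(cfg.population)]
    genomes = []
    for n_layers in layer_counts:
        sizes = rng.integers(1, MAX_NEURONS + 1, size=n_layers)
        genomes.append(encode_architecture(Architecture(sizes.tolist())))
    return genomes


def evaluate_fitness(
    g: Genome,
    X: np.ndarray,
    y: np.ndarray,
    train_cfg: TrainConfig | None = None,
    sa_cfg: SAConfig | None = None,
    net_seed: int = 0,
    output_mode: str = "SOFTMAX_XENT",
) -> tuple[float, NetworkModel]:
    """Fitness of one genome: validation kappa after annealed training.

    The genome is decoded, a fresh network initialised (``net_seed``),
    trained with ``sa_train`` (pass ``sa_cfg.iterations == 0`` for plain
    SCG) and scored on its internal validation split.  The split is
    derived from ``train_cfg.seed``, so every genome in one GA run is
    scored against the same validation data; deterministic for fixed data
    and seeds.
    """
    train_cfg = train_cfg or TrainConfig()
    sa_cfg = sa_cfg or SAConfig()
    arch = decode_genome(g)
    y = np.asarray(y, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    model = init_network(X.shape[1], arch, int(y.max()) + 1, seed=net_seed,
                         output_mode=output_mode)
    trained, trace = sa_train(model, X, y, train_cfg, sa_cfg)
    kappa = trained.meta["best_val_kappa"]
    return float(kappa), trained


def run_ga(
    X: np.ndarray,
    y: np.ndarray,
    ga_cfg: GAConfig | None = None,
    train_cfg: TrainConfig | None = None,
    sa_cfg: SAConfig | None = None,
    log=None,
) -> GAResult:
    """Evolve MLP structures on (flattened epochs, labels).

    Per generation the top ``elites`` genomes survive unchanged and the
    rest of the population is rebuilt as
    ``mutate(crossover(roulette, roulette))``.  Fitness of a repeated
    genome is cached (training is deterministic given the seeds), which
    also guarantees the elite's fitness never decreases.  Returns the
    best-ever model plus the per-generation fitness table.
    """
    import pandas as pd

    ga_cfg = ga_cfg or GAConfig()
    train_cfg = train_cfg or TrainConfig()
    sa_cfg = sa_cfg or SAConfig()
    rng = np.random.default_rng(ga_cfg.seed)
    cache: dict[tuple[int, ...], tuple[float, NetworkModel]] = {}

    def fitness(g: Genome) -> tuple[float, NetworkModel]:
        if g.bits not in cache:
            cache[g.bits] = evaluate_fitness(
                g, X, y, train_cfg, sa_cfg,
                net_seed=train_cfg.seed,
            )
            if log is not None:
                f, m = cache[g.bits]
                log.info("genome=%s arch=%s fitness=%.4f",
                         g, m.hidden_sizes, f)
        return cache[g.bits]

    population = init_population(ga_cfg, seed=int(rng.integers(2**31)))
    rows, evaluations = [], []
    best_fit, best_genome, best_model = -np.inf, None, None

    for gen in range(ga_cfg.generations + 1):
        scored = []
        for g in population:
            f, m = fitness(g)
            scored.append((f, g, m))
            evaluations.append((str(g), m.hidden_sizes, f))
        scored.sort(key=lambda t: t[0], reverse=True)
        fits = np.array([f for f, _, _ in scored])
        if fits[0] > best_fit:
            best_fit, best_genome, best_model = scored[0]
        rows.append({
            "generation": gen,
            "min": float(fits.min()),
            "mean": float(fits.mean()),
            "max": float(fits.max()),
            "elite": float(best_fit),
        })
        if gen == ga_cfg.generations:
            break
        next_pop = [g for _, g, _ in scored[: ga_cfg.elites]]
        all_fits = [f for f, _, _ in scored]
        while len(next_pop) < ga_cfg.population:
            pa = roulette_select(all_fits, rng)
            pb = roulette_select(all_fits, rng)
            child = crossover(scored[pa][1], scored[pb][1],
                              seed=int(rng.integers(2**31)))
            child = mutate(child, ga_cfg.mutation_rate,
                           seed=int(rng.integers(2**31)))
            next_pop.append(child)
        population = next_pop

    history = pd.DataFrame(rows)
    return GAResult(
        best_model=best_model,
        best_genome=best_genome,
        best_fitness=float(best_fit),
        history=history,
        evaluations=evaluations,
    )
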