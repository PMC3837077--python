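"""Single-objective genetic algorithm over vote-weight matrices.

The search space is the N x O real matrix V of per-classifier,
per-class vote weights, encoded row-major as a chromosome of genes in
[0, 1].  Fitness of a chromosome is the mean strict-match F-measure of
the weighted-vote ensemble over the K cross-validation folds of a
prediction bank.  Selection is roulette-wheel proportional; crossover
is single-point with an adaptive probability; mutation perturbs genes
with Laplace noise, again with an adaptive per-chromosome probability
(Srinivas-Patnaik style: above-average chromosomes are protected, the
population best is never disrupted).  Elitism keeps the best-ever
chromosome outside the population and re-injects it each generation,
so best fitness never decreases.

The fitness landscape is piecewise constant in V (only argmax
comparisons matter), which two caches exploit: one keyed by gene bytes,
one by the decoded label signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import PredictionMatrix
from .voting import WeightMatrix, decode_ids

__all__ = [
    "GAConfig",
    "Chromosome",
    "EnsembleSolution",
    "FitnessEvaluator",
    "init_population",
    "compute_fitness",
    "roulette_select",
    "adaptive_crossover_prob",
    "adaptive_mutation_prob",
    "single_point_crossover",
    "laplacian_mutate",
    "run_ga",
]


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters.

    Defaults follow the standard setup for this ensemble problem:
    population 100, 50 generations, adaptive constants k1 = k3 = 1.0
    and k2 = k4 = 0.5, Laplace mutation scale delta = 0.1, 5-fold
    cross-validation.  ``include_o`` controls whether the O label gets
    a learned weight column or a fixed weight of 1.
    """

    population_size: int = 100
    generations: int = 50
    k1: float = 1.0
    k2: float = 0.5
    k3: float = 1.0
    k4: float = 0.5
    delta: float = 0.1
    folds: int = 5
    rng_seed: int = 0
    include_o: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("k1", "k2", "k3", "k4"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class Chromosome:
    """Row-major encoding of V with a cached fitness (percent scale)."""

    genes: np.ndarray
    fitness: float | None = None

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy(), self.fitness)


@dataclass
class EnsembleSolution:
    best: Chromosome
    weight_matrix: WeightMatrix
    fitness_trace: list[float]
    classifier_F: np.ndarray
    config: GAConfig


# ------------------------------------------------------------- fitness

class FitnessEvaluator:
    """Maps chromosomes to mean per-fold strict-match ensemble F.

    Precomputes integer-coded fold predictions, gold chunk sets and
    sentence offsets once; each evaluation decodes all folds and scores
    chunks.  Results are cached by gene bytes and by decoded-label
    signature (the landscape is piecewise constant, so distinct
    chromosomes frequently share a decode).
    """

    def __init__(self, predictions: PredictionMatrix,
                 include_o: bool = True) -> None:
        predictions.validate()
        self.bank = predictions
        self.include_o = include_o
        self.labels = predictions.labels
        self.n_clf = predictions.n_classifiers
        self.n_lab = predictions.n_labels
        if not include_o and "O" not in self.labels:
            raise ValueError("include_o=False requires an O label")
        self.n_weighted = self.n_lab - (0 if include_o else 1)
        self.chrom_len = self.n_clf * self.n_weighted
        self.F = np.asarray(predictions.classifier_F, dtype=float)
        # per-label chunking tables (O must be last in the alphabet)
        self._kind = [0 if lab == "O" else (1 if lab.startswith("B-") else 2)
                      for lab in self.labels]
        types = sorted({lab[2:] for lab in self.labels if lab != "O"})
        tindex = {t: i for i, t in enumerate(types)}
        self._ctype = [-1 if lab == "O" else tindex[lab[2:]]
                       for lab in self.labels]
        self._folds = []
        for f in range(predictions.n_folds):
            offsets = []
            pos = 0
            for ln in predictions.fold_sent_lengths[f]:
                offsets.append((pos, pos + ln))
                pos += ln
            gold = self._chunk_set(predictions.fold_gold[f].tolist(), offsets)
            self._folds.append(
                (predictions.fold_outputs[f], offsets, gold)
            )
        self._by_genes: dict[bytes, float] = {}
        self._by_decode: dict[bytes, float] = {}

    def _chunk_set(self, ids: list[int], offsets) -> frozenset:
        kind, ctype = self._kind, self._ctype
        chunks = set()
        for s, (lo, hi) in enumerate(offsets):
            start, cur = -1, -1
            for i in range(lo, hi):
                k = kind[ids[i]]
                t = ctype[ids[i]]
                if k == 1:
                    if start >= 0:
                        chunks.add((s, start, i - 1, cur))
                    start, cur = i, t
                elif k == 2:
                    if start >= 0 and t == cur:
                        continue
                    if start >= 0:
                        chunks.add((s, start, i - 1, cur))
                    start, cur = i, t
                else:
                    if start >= 0:
                        chunks.add((s, start, i - 1, cur))
                        start = -1
            if start >= 0:
                chunks.add((s, start, hi - 1, cur))
        return frozenset(chunks)

    def v_full(self, genes: np.ndarray) -> np.ndarray:
        """Effective N x O weight matrix for a chromosome."""
        genes = np.asarray(genes, dtype=float)
        if genes.shape != (self.chrom_len,):
            raise ValueError(
                f"chromosome length {genes.shape} does not match "
                f"{self.n_clf} x {self.n_weighted}"
            )
        v = genes.reshape(self.n_clf, self.n_weighted)
        if not self.include_o:
            v = np.hstack([v, np.ones((self.n_clf, 1))])
        return v

    def weight_matrix(self, genes: np.ndarray) -> WeightMatrix:
        return WeightMatrix(
            self.v_full(genes), self.bank.classifier_names, self.labels,
            include_o=self.include_o,
        )

    def evaluate(self, chromosome: Chromosome) -> float:
        if chromosome.fitness is not None:
            return chromosome.fitness
        key = chromosome.genes.tobytes()
        hit = self._by_genes.get(key)
        if hit is not None:
            chromosome.fitness = hit
            return hit
        v = self.v_full(chromosome.genes)
        decoded = [decode_ids(out, v, self.F) for out, _, _ in self._folds]
        sig = b"".join(d.tobytes() for d in decoded)
        hit = self._by_decode.get(sig)
        if hit is None:
            fs = []
            for d, (_, offsets, gold) in zip(decoded, self._folds):
                pred = self._chunk_set(d.tolist(), offsets)
                correct = len(pred & gold)
                r = 100.0 * correct / len(gold) if gold else 0.0
                p = 100.0 * correct / len(pred) if pred else 0.0
                fs.append(2 * r * p / (r + p) if (r + p) > 0 else 0.0)
            hit = float(np.mean(fs))
            self._by_decode[sig] = hit
        self._by_genes[key] = hit
        chromosome.fitness = hit
        return hit


def compute_fitness(
    chromosome: Chromosome,
    predictions: PredictionMatrix,
    include_o: bool = True,
) -> float:
    """Mean per-fold ensemble F for one chromosome (percent scale)."""
    return FitnessEvaluator(predictions, include_o).evaluate(chromosome)


# ----------------------------------------------------------- operators

def init_population(
    config: GAConfig, n_classifiers: int, n_labels: int
) -> list[Chromosome]:
    """P chromosomes with genes i.i.d. uniform on [0, 1].

    ``n_labels`` is the number of weighted label columns (all labels, or
    all but O when ``include_o`` is off — the caller passes the count it
    searches).
    """
    rng = np.random.default_rng(config.rng_seed)
    length = n_classifiers * n_labels
    return [
        Chromosome(rng.random(length))
        for _ in range(config.population_size)
    ]


def roulette_select(
    population: Sequence[Chromosome], rng: np.random.Generator
) -> Chromosome:
    """Fitness-proportional selection; uniform when all fitnesses are 0."""
    if not population:
        raise ValueError("empty population")
    fits = np.array([c.fitness for c in population], dtype=float)
    if np.any(np.isnan(fits)):
        raise ValueError("all chromosomes must be evaluated before selection")
    if (fits < 0).any():
        raise ValueError("roulette selection requires non-negative fitness")
    total = fits.sum()
    if total <= 0:
        return population[rng.integers(len(population))]
    return population[rng.choice(len(population), p=fits / total)]


def adaptive_crossover_prob(
    f_max: float, f_avg: float, f_prime: float, config: GAConfig
) -> float:
    """Adaptive crossover probability for a parent pair.

    ``f_prime`` is the larger parent fitness.  Above-average pairs get
    ``k1 * (f_max - f') / (f_max - f_avg)`` (the best pair gets 0),
    below-average pairs the fixed k3.  When the population has converged
    (f_max = f_avg) the rate is k1.
    """
    if f_prime > f_max + 1e-12:
        raise ValueError("f_prime cannot exceed f_max")
    if f_prime < f_avg:
        return config.k3
    if f_max - f_avg <= 1e-15:
        return config.k1
    return min(config.k1 * (f_max - f_prime) / (f_max - f_avg), 1.0)


def adaptive_mutation_prob(
    f_max: float, f_avg: float, f: float, config: GAConfig
) -> float:
    """Adaptive per-chromosome mutation probability.

    Above-average chromosomes get ``k2 * (f_max - f) / (f_max - f_avg)``
    (the best chromosome is never mutated), below-average ones the fixed
    k4; k2 at convergence.
    """
    if f > f_max + 1e-12:
        raise ValueError("f cannot exceed f_max")
    if f < f_avg:
        return config.k4
    if f_max - f_avg <= 1e-15:
        return config.k2
    return min(config.k2 * (f_max - f) / (f_max - f_avg), 1.0)


def single_point_crossover(
    parent_a: Chromosome,
    parent_b: Chromosome,
    mu_c: float,
    rng: np.random.Generator,
) -> tuple[Chromosome, Chromosome]:
    """Exchange gene tails at one uniform cut point with probability mu_c."""
    a, b = parent_a.genes, parent_b.genes
    if a.shape != b.shape:
        raise ValueError("parent length mismatch")
    if len(a) >= 2 and rng.random() < mu_c:
        cut = int(rng.integers(1, len(a)))
        child_a = np.concatenate([a[:cut], b[cut:]])
        child_b = np.concatenate([b[:cut], a[cut:]])
        return Chromosome(child_a), Chromosome(child_b)
    return parent_a.copy(), parent_b.copy()


def laplacian_mutate(
    chromosome: Chromosome,
    mu_m: float,
    delta: float,
    rng: np.random.Generator,
) -> Chromosome:
    """Perturb each gene with probability mu_m by Laplace(gene, delta).

    The Laplace draw concentrates near the old value but reaches any
    point of the domain with non-zero probability; results are clamped
    to [0, 1].
    """
    if not 0.0 <= mu_m <= 1.0:
        raise ValueError("mu_m must lie in [0, 1]")
    if delta <= 0:
        raise ValueError("delta must be positive")
    genes = chromosome.genes
    mask = rng.random(len(genes)) < mu_m
    if not mask.any():
        return chromosome.copy()
    out = genes.copy()
    out[mask] = np.clip(
        rng.laplace(loc=genes[mask], scale=delta), 0.0, 1.0
    )
    return Chromosome(out)


# ------------------------------------------------------------ main loop

def run_ga(
    config: GAConfig,
    predictions: PredictionMatrix,
    injected: Sequence[Chromosome] | None = None,
) -> EnsembleSolution:
    """Evolve vote weights for ``config.generations`` generations.

    Loop: evaluate -> roulette pairing -> adaptive single-point
    crossover -> adaptive Laplace mutation, with the best-ever
    chromosome held in an external elite slot that replaces the current
    worst each generation.  ``injected`` chromosomes (off by default)
    are appended to the random initial population; the population
    returns to size P after the first generation.
    """
    evaluator = FitnessEvaluator(predictions, config.include_o)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    population = init_population(
        config, evaluator.n_clf, evaluator.n_weighted
    )
    if injected:
        for ch in injected:
            if ch.genes.shape != (evaluator.chrom_len,):
                raise ValueError("injected chromosome length mismatch")
            population.append(ch.copy())
    for ch in population:
        evaluator.evaluate(ch)
    elite = max(population, key=lambda c: c.fitness).copy()
    trace: list[float] = []
    p = config.population_size

    for _ in range(config.generations):
        fits01 = np.array([c.fitness for c in population]) / 100.0
        f_max, f_avg = float(fits01.max()), float(fits01.mean())
        offspring: list[Chromosome] = []
        while len(offspring) < p:
            pa = roulette_select(population, rng)
            pb = roulette_select(population, rng)
            f_prime = max(pa.fitness, pb.fitness) / 100.0
            mu_c = adaptive_crossover_prob(f_max, f_avg, f_prime, config)
            c1, c2 = single_point_crossover(pa, pb, mu_c, rng)
            offspring.extend((c1, c2))
        offspring = offspring[:p]
        # mu_m depends on each chromosome's own fitness: evaluate
        # offspring before mutation (cache-amortized).
        for ch in offspring:
            evaluator.evaluate(ch)
        ofits01 = np.array([c.fitness for c in offspring]) / 100.0
        of_max, of_avg = float(ofits01.max()), float(ofits01.mean())
        mutated = []
        for ch in offspring:
            mu_m = adaptive_mutation_prob(
                of_max, of_avg, ch.fitness / 100.0, config
            )
            mutated.append(laplacian_mutate(ch, mu_m, config.delta, rng))
        for ch in mutated:
            evaluator.evaluate(ch)
        worst = min(range(len(mutated)), key=lambda i: mutated[i].fitness)
        mutated[worst] = elite.copy()
        population = mutated
        gen_best = max(population, key=lambda c: c.fitness)
        if gen_best.fitness > elite.fitness:
            elite = gen_best.copy()
        trace.append(elite.fitness)

    return EnsembleSolution(
        best=elite,
        weight_matrix=evaluator.weight_matrix(elite.genes),
        fitness_trace=trace,
        classifier_F=evaluator.F.copy(),
        config=config,
    )
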