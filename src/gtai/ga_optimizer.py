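"""Genetic-algorithm inference of wobble coupling efficiencies (S_ij).

The objective is the Spearman rank correlation, at the codon level, between
the reference set's RSCU values and the absolute adaptiveness W_i computed
from the tRNA gene copy numbers under a candidate S vector.  Highly expressed
genes preferentially use codons adapted to the tRNA pool, so the S vector
that maximizes this correlation is taken as the species-specific estimate.

Chromosomes are real-valued vectors of the free wobble penalties in [0, 1].
The generational loop uses tournament selection, uniform crossover, Gaussian
mutation clipped to bounds, and elitism, so the best-so-far fitness trace is
monotonically non-decreasing and runs are bit-reproducible under a seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .codon_usage import FamilyPartition, build_family_partition
from .sequence_io import TRNAGeneCopyTable
from .tai_core import (
    FREE_CLASSES_EUKARYOTE,
    FREE_CLASSES_PROKARYOTE,
    SijWeights,
    WobbleRuleSet,
    recognition_matrix,
)


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the recommended operating point of the method: a constant
    population of 60 evolved for 100 generations, held fixed across a whole
    analysis.  The operator suite (tournament k=2, uniform crossover at 0.8,
    per-gene Gaussian mutation sd 0.1 at rate 0.1, one elite) is standard for
    real-valued chromosomes and fully configurable.
    """

    population_size: int = 60
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    mutation_sigma: float = 0.1
    tournament_size: int = 2
    elite_count: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("crossover_prob", "mutation_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GAResult:
    """Outcome of one GA run: best S vector, its fitness, and the trace."""

    best_s: SijWeights
    best_fitness: float
    history: list[float]
    evaluations: int
    free_classes: tuple[str, ...]
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "best_s": self.best_s.as_dict(),
            "best_fitness": self.best_fitness,
            "history": self.history,
            "evaluations": self.evaluations,
            "free_classes": list(self.free_classes),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


class FitnessEvaluator:
    """Precomputed Spearman fitness of S vectors against fixed inputs.

    The correlation runs over the sense codons of multi-codon families whose
    reference RSCU is defined (single-codon families carry constant RSCU and
    no rank information; undefined families cannot be ranked).  The RSCU side
    is ranked once; each candidate costs one matrix-vector product and one
    ranking.
    """

    def __init__(
        self,
        tgcn: TRNAGeneCopyTable,
        ref_rscu: Mapping[str, float],
        rules: WobbleRuleSet | None = None,
        prokaryote: bool = False,
        free_classes: Sequence[str] | None = None,
        fixed_s: SijWeights | None = None,
        partition: FamilyPartition | None = None,
    ) -> None:
        rules = rules or WobbleRuleSet()
        if free_classes is None:
            free_classes = (
                FREE_CLASSES_PROKARYOTE if prokaryote else FREE_CLASSES_EUKARYOTE
            )
        self.free_classes = tuple(free_classes)
        fixed_s = fixed_s or SijWeights({})
        partition = partition or build_family_partition(rules.genetic_code_id)
        multi = {
            c for f in partition.multi_codon_families() for c in f.codons
        }
        codons = [c for c in sorted(multi) if c in ref_rscu]
        if len(codons) < 3:
            raise ValueError("fewer than 3 codons with both RSCU and W defined")
        rscu_vals = np.array([ref_rscu[c] for c in codons])
        if np.ptp(rscu_vals) == 0:
            raise ValueError("reference RSCU has zero variance")
        self.codons = codons
        self._rscu_ranks = rankdata(rscu_vals)
        _, classes, T = recognition_matrix(tgcn, rules, prokaryote, codons)
        free_idx = [classes.index(c) for c in self.free_classes]
        fixed_idx = [k for k in range(len(classes)) if k not in free_idx]
        one_minus_fixed = np.array([1.0 - fixed_s[classes[k]] for k in fixed_idx])
        self._fixed_w = T[:, fixed_idx] @ one_minus_fixed
        self._T_free = T[:, free_idx]
        self.n_free = len(self.free_classes)

    def w_absolute(self, s_vector: np.ndarray) -> np.ndarray:
        """W over the evaluation codons for a free-class S vector."""
        return self._fixed_w + self._T_free @ (1.0 - np.asarray(s_vector, float))

    def __call__(self, s_vector: np.ndarray) -> float:
        """Spearman rho between reference RSCU and W under ``s_vector``."""
        W = self.w_absolute(s_vector)
        if np.ptp(W) == 0:
            raise ValueError("W has zero variance under this S vector")
        r = np.corrcoef(self._rscu_ranks, rankdata(W))[0, 1]
        return float(r)

    def weights(self, s_vector: np.ndarray) -> SijWeights:
        return SijWeights(dict(zip(self.free_classes, map(float, s_vector))))


def fitness(
    s: SijWeights,
    tgcn: TRNAGeneCopyTable,
    ref_rscu: Mapping[str, float],
    rules: WobbleRuleSet | None = None,
    prokaryote: bool = False,
) -> float:
    """Spearman correlation between reference RSCU and W_i under ``s``."""
    free = FREE_CLASSES_PROKARYOTE if prokaryote else FREE_CLASSES_EUKARYOTE
    evaluator = FitnessEvaluator(
        tgcn, ref_rscu, rules, prokaryote, free_classes=free
    )
    return evaluator(np.array([s[c] for c in free]))


def run_ga(
    config: GAConfig,
    tgcn: TRNAGeneCopyTable,
    ref_rscu: Mapping[str, float],
    rules: WobbleRuleSet | None = None,
    prokaryote: bool = False,
    free_classes: Sequence[str] | None = None,
    fixed_s: SijWeights | None = None,
) -> GAResult:
    """Evolve S vectors to maximize the RSCU-vs-W Spearman correlation.

    Raises if the entire initial population fails fitness evaluation;
    individual degenerate candidates later on simply score -inf.
    """
    evaluator = FitnessEvaluator(
        tgcn, ref_rscu, rules, prokaryote, free_classes, fixed_s
    )
    rng = np.random.default_rng(config.seed)
    n = evaluator.n_free
    pop = rng.random((config.population_size, n))
    evaluations = 0

    def evaluate(population: np.ndarray) -> np.ndarray:
        nonlocal evaluations
        out = np.empty(len(population))
        for i, chrom in enumerate(population):
            try:
                out[i] = evaluator(chrom)
            except ValueError:
                out[i] = -np.inf
            evaluations += 1
        return out

    fit = evaluate(pop)
    if not np.any(np.isfinite(fit)):
        raise ValueError("entire initial population failed fitness evaluation")
    best_idx = int(np.argmax(fit))
    best_chrom = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    history: list[float] = []

    for _ in range(config.generations):
        order = np.argsort(fit)[::-1]
        elites = pop[order[: config.elite_count]].copy()
        n_children = config.population_size - config.elite_count
        children = np.empty((n_children, n))
        for i in range(0, n_children, 2):
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size,
                                          config.tournament_size)
                parents.append(pop[contenders[np.argmax(fit[contenders])]].copy())
            c1, c2 = parents
            if rng.random() < config.crossover_prob:
                mask = rng.random(n) < 0.5
                c1[mask], c2[mask] = c2[mask].copy(), c1[mask].copy()
            children[i] = c1
            if i + 1 < n_children:
                children[i + 1] = c2
        mut_mask = rng.random(children.shape) < config.mutation_prob
        steps = rng.normal(0.0, config.mutation_sigma, children.shape)
        children = np.clip(np.where(mut_mask, children + steps, children), 0.0, 1.0)
        pop = np.vstack([elites, children])
        fit = evaluate(pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_chrom = pop[gen_best].copy()
        history.append(best_fit)

    return GAResult(
        best_s=evaluator.weights(best_chrom),
        best_fitness=best_fit,
        history=history,
        evaluations=evaluations,
        free_classes=evaluator.free_classes,
        seed=config.seed,
    )


def grid_search_oracle(
    tgcn: TRNAGeneCopyTable,
    ref_rscu: Mapping[str, float],
    free_classes: Sequence[str],
    grid_step: float = 0.01,
    rules: WobbleRuleSet | None = None,
    prokaryote: bool = False,
    fixed_s: SijWeights | None = None,
) -> tuple[SijWeights, float]:
    """Exhaustive lattice evaluation of the fitness over <= 3 free classes.

    Serves as an independent optimum bound for GA correctness checks; the
    combinatorial guard keeps the lattice tractable.
    """
    if len(free_classes) > 3:
        raise ValueError("grid search limited to at most 3 free classes")
    evaluator = FitnessEvaluator(
        tgcn, ref_rscu, rules, prokaryote, free_classes, fixed_s
    )
    n_points = int(round(1.0 / grid_step)) + 1
    axis = np.linspace(0.0, 1.0, n_points)
    best_fit = -np.inf
    best_point: tuple[float, ...] | None = None
    for point in itertools.product(axis, repeat=len(free_classes)):
        try:
            f = evaluator(np.array(point))
        except ValueError:
            continue
        if f > best_fit:
            best_fit = f
            best_point = point
    if best_point is None:
        raise ValueError("no lattice point yielded a finite fitness")
    return evaluator.weights(np.array(best_point)), float(best_fit)
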