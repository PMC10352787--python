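"""Scikit-learn-style estimators for tRNA-adaptation scoring.

:class:`TRNAAdaptationIndex` is the package's central object: ``fit`` learns
species-specific wobble penalties (S_ij) from a genome and its tRNA gene-copy
table - reference-set selection by lowest ENc, pooled RSCU, then a genetic
algorithm maximizing the codon-level Spearman correlation between RSCU and
absolute adaptiveness W - and ``transform`` scores genes with the tAI
(geometric mean of relative adaptiveness).  :class:`CodonAdaptationIndex`
is the classical reference-weight comparator in the same shape.  Both follow
sklearn conventions (``get_params``/``set_params``, fitted attributes with a
trailing underscore) and compose with sklearn model-selection utilities.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import codon_usage as cu
from . import evaluation_stats as es
from .ga_optimizer import GAConfig, GAResult, FitnessEvaluator, run_ga
from .reference_set import (
    DEFAULT_REFERENCE_FRACTION,
    gene_enc_values,
    reference_rscu,
    select_reference,
)
from .sequence_io import (
    CodingSequence,
    CodonCountTable,
    GenomeCDSSet,
    TRNAGeneCopyTable,
    count_codons,
    read_tgcn,
)
from .tai_core import (
    FREE_CLASSES_EUKARYOTE,
    FREE_CLASSES_PROKARYOTE,
    OTAI_SIJ,
    SijWeights,
    WobbleRuleSet,
    adaptiveness,
    gene_tai,
)


def as_gene_set(X, genetic_code_id: int = 1) -> GenomeCDSSet:
    """Coerce fit/transform input into a :class:`GenomeCDSSet`.

    Accepts a ``GenomeCDSSet``, an iterable of ``CodingSequence``, or an
    iterable of raw sequence strings (ids are generated).
    """
    if isinstance(X, GenomeCDSSet):
        return X
    genes: list[CodingSequence] = []
    for i, item in enumerate(X):
        if isinstance(item, CodingSequence):
            genes.append(item)
        elif isinstance(item, str):
            genes.append(CodingSequence(f"gene_{i:05d}", item.upper().replace("U", "T")))
        else:
            raise TypeError(f"cannot interpret {type(item)} as a coding sequence")
    return GenomeCDSSet(genes, genetic_code_id)


class TRNAAdaptationIndex(TransformerMixin, BaseEstimator):
    """Species-specific tAI scorer with GA-inferred wobble penalties.

    Parameters
    ----------
    tgcn : TRNAGeneCopyTable, mapping or path
        tRNA gene copy numbers keyed by anticodon (5'->3', wobble base
        first).  Passed at construction, like a vocabulary, because it is a
        property of the organism rather than of the training genes.
    sij : "optimize", "otai" or SijWeights, default "optimize"
        "optimize" infers the wobble penalties by the genetic algorithm;
        "otai" uses the fixed literature values of the original tAI;
        an explicit :class:`SijWeights` skips inference entirely.
    ref_fraction : float, default 0.05
        Fraction of genes (lowest ENc) used as the putatively highly
        expressed reference set.
    population_size, generations, crossover_prob, mutation_prob,
    mutation_sigma, tournament_size, elite_count :
        Genetic-algorithm settings; see :class:`~gtai.ga_optimizer.GAConfig`.
    prokaryote : bool, default False
        Frees the lysidine (L:A) class and lets bacterial Ile2 tRNA decode
        ATA.
    exclude_special : bool, default False
        Exclude Met ATG / Trp TGG occurrences from the tAI geometric mean.
    random_state : int or None
        Seed for the genetic algorithm.

    Attributes
    ----------
    sij_ : SijWeights
        Fitted (or preset) wobble penalties.
    adaptiveness_ : AdaptivenessMap
        Absolute (W) and relative (w) codon adaptiveness under ``sij_``.
    fitness_ : float
        Spearman correlation between reference RSCU and W under ``sij_``.
    ga_result_ : GAResult or None
        Full optimizer trace (None when ``sij`` was preset).
    reference_ids_ : list of str
        Gene ids of the selected reference set.
    enc_ : dict
        Per-gene ENc values of the training genome.
    """

    def __init__(
        self,
        tgcn=None,
        *,
        sij: str | SijWeights = "optimize",
        ref_fraction: float = DEFAULT_REFERENCE_FRACTION,
        population_size: int = 60,
        generations: int = 100,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.1,
        mutation_sigma: float = 0.1,
        tournament_size: int = 2,
        elite_count: int = 1,
        prokaryote: bool = False,
        genetic_code_id: int = 1,
        exclude_special: bool = False,
        random_state: int | None = None,
    ) -> None:
        self.tgcn = tgcn
        self.sij = sij
        self.ref_fraction = ref_fraction
        self.population_size = population_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.mutation_sigma = mutation_sigma
        self.tournament_size = tournament_size
        self.elite_count = elite_count
        self.prokaryote = prokaryote
        self.genetic_code_id = genetic_code_id
        self.exclude_special = exclude_special
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _resolve_tgcn(self) -> TRNAGeneCopyTable:
        if isinstance(self.tgcn, TRNAGeneCopyTable):
            return self.tgcn
        if isinstance(self.tgcn, Mapping):
            return TRNAGeneCopyTable(dict(self.tgcn))
        if isinstance(self.tgcn, (str, bytes)) or hasattr(self.tgcn, "__fspath__"):
            return read_tgcn(self.tgcn)
        raise ValueError("tgcn must be a TRNAGeneCopyTable, mapping or path")

    def _free_classes(self) -> tuple[str, ...]:
        return FREE_CLASSES_PROKARYOTE if self.prokaryote else FREE_CLASSES_EUKARYOTE

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Learn S_ij (unless preset) and the codon adaptiveness map.

        ``X`` is the genome: a :class:`GenomeCDSSet` or an iterable of
        coding sequences.  ``y`` is ignored and present for API
        compatibility.
        """
        genome = as_gene_set(X, self.genetic_code_id)
        tgcn = self._resolve_tgcn()
        rules = WobbleRuleSet(self.genetic_code_id)
        partition = cu.build_family_partition(self.genetic_code_id)

        self.partition_ = partition
        self.enc_ = gene_enc_values(genome, partition)
        reference = select_reference(
            genome, self.ref_fraction, enc_values=self.enc_
        )
        self.reference_ids_ = reference.ids()
        self.reference_rscu_ = reference_rscu(reference, partition)

        if isinstance(self.sij, SijWeights):
            self.sij_ = self.sij
            self.ga_result_: GAResult | None = None
        elif self.sij == "otai":
            self.sij_ = OTAI_SIJ
            self.ga_result_ = None
        elif self.sij == "optimize":
            config = GAConfig(
                population_size=self.population_size,
                generations=self.generations,
                crossover_prob=self.crossover_prob,
                mutation_prob=self.mutation_prob,
                mutation_sigma=self.mutation_sigma,
                tournament_size=self.tournament_size,
                elite_count=self.elite_count,
                seed=self.random_state,
            )
            self.ga_result_ = run_ga(
                config,
                tgcn,
                self.reference_rscu_,
                rules,
                prokaryote=self.prokaryote,
            )
            self.sij_ = self.ga_result_.best_s
        else:
            raise ValueError(
                "sij must be 'optimize', 'otai' or an SijWeights instance"
            )

        evaluator = FitnessEvaluator(
            tgcn,
            self.reference_rscu_,
            rules,
            self.prokaryote,
            free_classes=self._free_classes(),
            partition=partition,
        )
        self.fitness_ = evaluator(
            np.array([self.sij_[c] for c in self._free_classes()])
        )
        self.adaptiveness_ = adaptiveness(tgcn, self.sij_, rules, self.prokaryote)
        self.rules_ = rules
        self.tgcn_ = tgcn
        return self

    def transform(self, X) -> np.ndarray:
        """Per-gene tAI values, in input order."""
        if not hasattr(self, "adaptiveness_"):
            raise ValueError("TRNAAdaptationIndex is not fitted yet")
        genome = as_gene_set(X, self.genetic_code_id)
        return np.array([
            gene_tai(
                count_codons(g, genetic_code_id=self.genetic_code_id),
                self.adaptiveness_,
                exclude_special=self.exclude_special,
            )
            for g in genome
        ])

    def score_genes(self, X) -> dict[str, float]:
        """tAI keyed by gene id (convenience over :meth:`transform`)."""
        genome = as_gene_set(X, self.genetic_code_id)
        return dict(zip(genome.ids(), self.transform(genome)))

    def score(self, X, y) -> float:
        """Spearman correlation between predicted tAI and ``y`` (e.g.,
        measured protein abundance)."""
        return es.spearman(self.transform(X), np.asarray(y, float))


class CodonAdaptationIndex(TransformerMixin, BaseEstimator):
    """Classical CAI: Sharp-Li reference weights, geometric-mean scoring.

    ``fit`` pools the codon counts of the reference genes and derives
    within-family relative weights (zero-count codons get pseudocount 0.5);
    ``transform`` returns the geometric mean weight over each gene's codons
    in multi-codon families.
    """

    def __init__(self, genetic_code_id: int = 1) -> None:
        self.genetic_code_id = genetic_code_id

    def fit(self, X, y=None):
        reference = as_gene_set(X, self.genetic_code_id)
        self.partition_ = cu.build_family_partition(self.genetic_code_id)
        pooled: CodonCountTable = count_codons(
            reference, genetic_code_id=self.genetic_code_id
        )
        self.weights_ = cu.cai_weights(pooled, self.partition_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise ValueError("CodonAdaptationIndex is not fitted yet")
        genome = as_gene_set(X, self.genetic_code_id)
        return np.array([
            cu.cai(
                count_codons(g, genetic_code_id=self.genetic_code_id),
                self.weights_,
            )
            for g in genome
        ])

    def score_genes(self, X) -> dict[str, float]:
        genome = as_gene_set(X, self.genetic_code_id)
        return dict(zip(genome.ids(), self.transform(genome)))
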