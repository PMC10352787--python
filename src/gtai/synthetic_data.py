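"""Synthetic genomes with known translational-selection ground truth.

The generator instantiates exactly the assumption the S_ij inference
exploits: highly expressed genes preferentially use codons adapted to the
intracellular tRNA pool.  Given a tRNA gene-copy table and a true S vector,
the true relative adaptiveness w of every codon is known; "highly expressed"
genes then pick each amino acid's codon with probability proportional to
w^beta (a Boltzmann tilt with selection strength beta), while background
genes pick codons according to a neutral GC-biased mutational weight.  Every
emitted gene is a valid CDS: starts with ATG, ends with a stop, no internal
stops, length a multiple of three.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .sequence_io import (
    CodingSequence,
    GenomeCDSSet,
    SequenceIOError,
    TRNAGeneCopyTable,
    sense_codons,
)
from .tai_core import (
    AdaptivenessMap,
    SijWeights,
    WobbleRuleSet,
    adaptiveness,
    reverse_complement,
)

#: Default true wobble penalties: the literature values of the original tAI
#: parameterization, a realistic operating point for a eukaryote-like genome.
DEFAULT_TRUE_S = SijWeights({"G:U": 0.41, "I:C": 0.28, "I:A": 0.9999, "U:G": 0.68})
DEFAULT_TRUE_S_PROKARYOTE = SijWeights(
    {"G:U": 0.41, "I:C": 0.28, "I:A": 0.9999, "U:G": 0.68, "L:A": 0.89}
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    ``n_high`` strongly selected genes on a background of ``n_background``
    neutral genes (defaults 200/1800: a 10% highly expressed tier).  Gene
    lengths are drawn uniformly from ``gene_length_codons`` (total codons
    including start and stop).  ``beta`` is the selection strength: codon
    choice within an amino acid family is proportional to w_true^beta, so
    beta = 0 collapses to the background model when ``gc_bias`` = 0.5.
    """

    n_high: int = 200
    n_background: int = 1800
    gene_length_codons: int | tuple[int, int] = (100, 400)
    beta: float = 5.0
    gc_bias: float = 0.5
    true_s: SijWeights | None = None
    tgcn_spec: dict[str, int] | None = None
    prokaryote: bool = False
    genetic_code_id: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_high < 1 or self.n_background < 0:
            raise ValueError("gene counts must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 < self.gc_bias < 1.0:
            raise ValueError("gc_bias must be in (0, 1)")
        if self.true_s is None:
            self.true_s = (
                DEFAULT_TRUE_S_PROKARYOTE if self.prokaryote else DEFAULT_TRUE_S
            )

    def length_range(self) -> tuple[int, int]:
        if isinstance(self.gene_length_codons, int):
            return (self.gene_length_codons, self.gene_length_codons)
        lo, hi = self.gene_length_codons
        return (int(lo), int(hi))


@dataclass
class SimulationTruth:
    """Ground-truth record accompanying a simulated genome."""

    true_s: SijWeights
    w_true: dict[str, float]
    tgcn: TRNAGeneCopyTable
    labels: dict[str, str]  # gene id -> "high" | "background"
    beta: float
    seed: int | None = None
    zero_substituted: list[str] = field(default_factory=list)

    def high_ids(self) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == "high"]

    def background_ids(self) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == "background"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_s": self.true_s.as_dict(),
            "w_true": self.w_true,
            "tgcn": dict(self.tgcn.entries),
            "lysidine_count": self.tgcn.lysidine_count,
            "labels": self.labels,
            "beta": self.beta,
            "seed": self.seed,
            "zero_substituted": self.zero_substituted,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _aa_families(genetic_code_id: int) -> dict[str, tuple[str, ...]]:
    """Full amino-acid synonymous families (six-fold families NOT split:
    codon choice in the simulator is per amino acid)."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        if set(codon) <= set("ACGT"):
            fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}


def simulate_tgcn(
    spec: dict[str, int] | None = None,
    seed: int | None = None,
    prokaryote: bool = False,
    genetic_code_id: int = 1,
    true_s: SijWeights | None = None,
    presence_prob: float = 0.7,
    max_copies: int = 10,
) -> TRNAGeneCopyTable:
    """Build or validate a tRNA gene-copy table with full decodability.

    Without ``spec``, each Watson-Crick anticodon of the genetic code is
    present with probability ``presence_prob`` and carries 1..``max_copies``
    gene copies; any amino-acid family left undecodable is repaired by adding
    the Watson-Crick anticodon of its first codon.  An explicit ``spec`` is
    validated instead: a family with no decodable codon (W > 0 under
    ``true_s``) is rejected.
    """
    true_s = true_s or (
        DEFAULT_TRUE_S_PROKARYOTE if prokaryote else DEFAULT_TRUE_S
    )
    rules = WobbleRuleSet(genetic_code_id)
    fams = _aa_families(genetic_code_id)
    if spec is not None:
        table = TRNAGeneCopyTable(dict(spec))
        amap = adaptiveness(table, true_s, rules, prokaryote)
        for aa, codons in fams.items():
            if all(amap.W[c] == 0 for c in codons):
                raise SequenceIOError(
                    f"tGCN spec leaves amino acid {aa} undecodable"
                )
        return table
    rng = np.random.default_rng(seed)
    anticodons = sorted({reverse_complement(c) for c in sense_codons(genetic_code_id)})
    entries: dict[str, int] = {}
    for anticodon in anticodons:
        if rng.random() < presence_prob:
            entries[anticodon] = int(rng.integers(1, max_copies + 1))
    # repair undecodable families so every amino acid can be translated
    for codons in fams.values():
        covered = False
        for c in codons:
            for anticodon, cls in rules.recognizers(c, prokaryote):
                if cls != "L:A" and entries.get(anticodon, 0) > 0:
                    covered = True
        if not covered:
            entries[reverse_complement(codons[0])] = int(
                rng.integers(1, max_copies + 1)
            )
    lysidine = int(rng.integers(1, 4)) if prokaryote else 0
    return TRNAGeneCopyTable(entries, lysidine)


def _codon_sampler(
    fams: dict[str, tuple[str, ...]], probs: dict[str, float]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pack per-amino-acid codon choice into padded matrices for vector
    sampling: (aa order, codon matrix [n_aa, max_fold], cumulative probs)."""
    aas = sorted(fams)
    max_fold = max(len(fams[aa]) for aa in aas)
    codon_mat = np.full((len(aas), max_fold), "NNN", dtype="<U3")
    cum = np.ones((len(aas), max_fold))
    for i, aa in enumerate(aas):
        codons = fams[aa]
        p = np.array([probs[c] for c in codons], float)
        if p.sum() == 0:
            p = np.ones(len(codons))
        p = p / p.sum()
        codon_mat[i, : len(codons)] = codons
        cum[i, : len(codons)] = np.cumsum(p)
        cum[i, len(codons) - 1] = 1.0  # guard against rounding
    return aas, codon_mat, cum


def _mutational_weight(codon: str, gc_bias: float) -> float:
    w = 1.0
    for base in codon:
        w *= gc_bias if base in "GC" else (1.0 - gc_bias)
    return w


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeCDSSet, SimulationTruth]:
    """Generate a labelled synthetic genome and its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    tgcn = simulate_tgcn(
        config.tgcn_spec,
        seed=int(rng.integers(0, 2**31)),
        prokaryote=config.prokaryote,
        genetic_code_id=config.genetic_code_id,
        true_s=config.true_s,
    )
    rules = WobbleRuleSet(config.genetic_code_id)
    amap: AdaptivenessMap = adaptiveness(
        tgcn, config.true_s, rules, config.prokaryote
    )
    fams = _aa_families(config.genetic_code_id)
    high_probs = {c: amap.w[c] ** config.beta for cs in fams.values() for c in cs}
    bg_probs = {
        c: _mutational_weight(c, config.gc_bias)
        for cs in fams.values()
        for c in cs
    }
    table = CodonTable.unambiguous_dna_by_id[config.genetic_code_id]
    stop_list = sorted(table.stop_codons)
    stop_w = np.array([_mutational_weight(s, config.gc_bias) for s in stop_list])
    stop_p = stop_w / stop_w.sum()

    samplers = {
        "high": _codon_sampler(fams, high_probs),
        "background": _codon_sampler(fams, bg_probs),
    }
    lo, hi = config.length_range()
    genes: list[CodingSequence] = []
    labels: dict[str, str] = {}
    plan = [("high", i) for i in range(config.n_high)] + [
        ("background", i) for i in range(config.n_background)
    ]
    for label, i in plan:
        aas, codon_mat, cum = samplers[label]
        n_body = int(rng.integers(lo, hi + 1)) - 2  # minus start and stop
        aa_idx = rng.integers(0, len(aas), n_body)
        u = rng.random(n_body)
        choice = (u[:, None] > cum[aa_idx]).sum(axis=1)
        body = "".join(codon_mat[aa_idx, choice])
        stop = stop_list[int(rng.choice(len(stop_list), p=stop_p))]
        gene_id = f"{label}_{i:05d}"
        genes.append(CodingSequence(gene_id, "ATG" + body + stop))
        labels[gene_id] = label
    genome = GenomeCDSSet(genes, config.genetic_code_id)
    truth = SimulationTruth(
        true_s=config.true_s,
        w_true=dict(amap.w),
        tgcn=tgcn,
        labels=labels,
        beta=config.beta,
        seed=config.seed,
        zero_substituted=list(amap.zero_substituted),
    )
    return genome, truth
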