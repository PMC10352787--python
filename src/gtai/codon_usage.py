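"""Codon usage bias statistics: RSCU, improved ENc, CAI, SCUO, GC content.

All statistics operate on :class:`~gtai.sequence_io.CodonCountTable` objects
and a :class:`FamilyPartition` describing the synonymous-codon families of the
active genetic code.  Six-fold families (Leu, Ser, Arg in the standard code)
are split into a two-fold and a four-fold block sharing their first two
nucleotides, which yields the conventional family-count vector of the standard
code (2 single, 12 two-fold, 1 three-fold, 8 four-fold families; maximum
effective number of codons 61).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .sequence_io import CodonCountTable, GenomeCDSSet, stop_codons


@dataclass(frozen=True)
class CodonFamily:
    """One synonymous-codon family: an amino acid (or six-fold sub-block)."""

    amino_acid: str
    codons: tuple[str, ...]

    @property
    def fold(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class FamilyPartition:
    """Disjoint cover of the sense codons by synonymous families.

    ``Ns`` counts single-codon families; ``K2``/``K3``/``K4`` count the two-,
    three- and four-fold families.  Under the split standard code
    Ns + 2*K2 + 3*K3 + 4*K4 = 61, the ENc ceiling.
    """

    families: tuple[CodonFamily, ...]
    genetic_code_id: int = 1

    @property
    def Ns(self) -> int:
        return sum(1 for f in self.families if f.fold == 1)

    @property
    def K2(self) -> int:
        return sum(1 for f in self.families if f.fold == 2)

    @property
    def K3(self) -> int:
        return sum(1 for f in self.families if f.fold == 3)

    @property
    def K4(self) -> int:
        return sum(1 for f in self.families if f.fold == 4)

    @property
    def max_enc(self) -> int:
        return self.Ns + 2 * self.K2 + 3 * self.K3 + 4 * self.K4

    def multi_codon_families(self) -> tuple[CodonFamily, ...]:
        return tuple(f for f in self.families if f.fold >= 2)

    def family_of(self) -> dict[str, CodonFamily]:
        return {c: f for f in self.families for c in f.codons}


def build_family_partition(
    genetic_code_id: int = 1, split_sixfold: bool = True
) -> FamilyPartition:
    """Group the sense codons of an NCBI translation table into families.

    With ``split_sixfold`` (default), any family spanning more than one
    first-two-nucleotide box is split into per-box blocks, so every family
    fold is in {1, 2, 3, 4}.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code id: {genetic_code_id}") from exc
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        if set(codon) <= set("ACGT"):
            by_aa.setdefault(aa, []).append(codon)
    families: list[CodonFamily] = []
    for aa in sorted(by_aa):
        codons = sorted(by_aa[aa])
        boxes = sorted({c[:2] for c in codons})
        if split_sixfold and len(boxes) > 1:
            for box in boxes:
                members = tuple(c for c in codons if c[:2] == box)
                families.append(CodonFamily(aa, members))
        else:
            families.append(CodonFamily(aa, tuple(codons)))
    part = FamilyPartition(tuple(families), genetic_code_id)
    if split_sixfold and any(f.fold > 4 for f in part.families):
        raise ValueError("family with fold > 4 after six-fold split")
    return part


def rscu(
    counts: CodonCountTable, partition: FamilyPartition
) -> dict[str, float]:
    """Relative synonymous codon usage per codon.

    For each family a with k_a members, RSCU_c = O_c / ((1/k_a) * sum_c O_c):
    the observed count over the expected count were all synonyms used equally.
    Families with zero total counts are undefined and omitted from the result
    (they cannot be ranked downstream).
    """
    values: dict[str, float] = {}
    for family in partition.families:
        total = sum(counts[c] for c in family.codons)
        if total == 0:
            continue
        k = family.fold
        for c in family.codons:
            values[c] = counts[c] / (total / k)
    return values


def family_fcf(family_counts: Sequence[int]) -> float:
    """Pseudocounted codon-family homozygosity F_CF.

    F_CF = sum_i ((n_i + 1) / (n + m))^2 with n the family total and m the
    family size; lies in (0, 1], reaching 1/m under uniform usage with large
    counts and 1 when a single codon dominates.
    """
    m = len(family_counts)
    if m < 2:
        raise ValueError("family homozygosity needs a family of size >= 2")
    n = sum(family_counts)
    return sum(((ni + 1) / (n + m)) ** 2 for ni in family_counts)


def enc(counts: CodonCountTable, partition: FamilyPartition) -> float:
    """Improved effective number of codons of a gene or gene set.

    ENc = Ns + sum_{m in {2,3,4}} K_m * (sum_j n_j) / (sum_j n_j F_CF,j),
    where within each fold class m the sums run over families with counts.
    A fold class with no counts at all contributes its uniform-usage limit
    K_m * m, which preserves the 61 ceiling of the split standard code.
    """
    ks = {2: partition.K2, 3: partition.K3, 4: partition.K4}
    if all(
        sum(counts[c] for c in f.codons) == 0
        for f in partition.multi_codon_families()
    ):
        raise ValueError("all multi-codon families are empty")
    value = float(partition.Ns)
    for m, K_m in ks.items():
        if K_m == 0:
            continue
        num = 0.0
        den = 0.0
        for family in partition.families:
            if family.fold != m:
                continue
            fam_counts = [counts[c] for c in family.codons]
            n_j = sum(fam_counts)
            if n_j == 0:
                continue
            num += n_j
            den += n_j * family_fcf(fam_counts)
        if num == 0.0:
            value += K_m * m  # no data: uniform-usage limit
        else:
            value += K_m * num / den
    return value


def cai_weights(
    reference_counts: CodonCountTable, partition: FamilyPartition
) -> dict[str, float]:
    """Sharp-Li relative adaptiveness weights from reference codon counts.

    Within each multi-codon family, weight_c = count_c / max family count;
    codons unobserved in the reference receive pseudocount 0.5 before the
    ratio.  Single-codon families are excluded (their weight is trivially 1
    and carries no information).
    """
    if reference_counts.total() == 0:
        raise ValueError("empty reference counts")
    weights: dict[str, float] = {}
    for family in partition.multi_codon_families():
        fam = {c: float(reference_counts[c]) for c in family.codons}
        top = max(fam.values())
        if top == 0:
            continue  # family absent from the reference: unscorable
        for c, n in fam.items():
            weights[c] = (n if n > 0 else 0.5) / top
    return weights


def cai(gene_counts: CodonCountTable, weights: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of reference weights over the
    gene's codon occurrences in multi-codon families."""
    log_sum = 0.0
    n = 0
    for codon, count in gene_counts.counts.items():
        w = weights.get(codon)
        if w is None or count == 0:
            continue
        log_sum += count * math.log(w)
        n += count
    if n == 0:
        raise ValueError("gene has no codons scorable by the CAI weights")
    return math.exp(log_sum / n)


def scuo(gene_counts: CodonCountTable, partition: FamilyPartition) -> float:
    """Synonymous codon usage orderliness, an entropy-based index in [0, 1].

    Per multi-codon family i: H_i = -sum_j p_ij log2 p_ij with p_ij the
    within-family codon frequencies, O_i = (log2 m_i - H_i) / log2 m_i; SCUO
    is the count-weighted mean of O_i.  0 means uniform synonymous usage
    (maximum entropy), 1 means a single codon per family (perfect order).
    """
    weighted = 0.0
    total = 0
    for family in partition.multi_codon_families():
        fam_counts = [gene_counts[c] for c in family.codons]
        n_i = sum(fam_counts)
        if n_i == 0:
            continue
        h = -sum(
            (c / n_i) * math.log2(c / n_i) for c in fam_counts if c > 0
        )
        o_i = (math.log2(family.fold) - h) / math.log2(family.fold)
        weighted += n_i * o_i
        total += n_i
    if total == 0:
        raise ValueError("no multi-codon family has counts")
    return weighted / total


def gene_gc_content(gene_seq: str) -> float:
    """(G+C)/(A+C+G+T) of one sequence, as a percentage."""
    acgt = sum(gene_seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    gc = gene_seq.count("G") + gene_seq.count("C")
    return 100.0 * gc / acgt


def gc_content(genes: GenomeCDSSet, pooled: bool = False) -> float:
    """Average GC percentage of a gene set.

    By default the arithmetic mean of per-gene GC percentages (the way
    per-organism averages are usually reported); ``pooled`` instead pools all
    nucleotides before taking the ratio.
    """
    if pooled:
        gc = sum(g.seq.count("G") + g.seq.count("C") for g in genes)
        acgt = sum(sum(g.seq.count(b) for b in "ACGT") for g in genes)
        return 100.0 * gc / acgt
    return float(np.mean([gene_gc_content(g.seq) for g in genes]))
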