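"""Wobble-pairing model, codon adaptiveness (W, w) and the gene-level tAI.

The absolute adaptiveness of codon i is

    W_i = sum_j (1 - S_ij) * tGCN_ij

summed over the anticodons j able to recognize i, where tGCN_ij is the gene
copy number of anticodon j and S_ij in [0, 1] is the coupling-efficiency
penalty of the codon-anticodon interaction class (0 = perfect, 1 = weak).
Watson-Crick pairs are treated as perfect (S = 0) by default; the free
parameters are the wobble classes G:U, I:C (inosine reading C), I:A (inosine
reading A), U:G, and - in prokaryote mode - L:A (lysidine-modified CAT
reading ATA).  Anticodons are written 5'->3' in DNA, wobble base (position
34) first, so the Watson-Crick anticodon of a codon is its reverse
complement.

Each W_i is normalized to the maximum to give the relative adaptiveness w_i,
and the tAI of a gene is the geometric mean of the w of its codons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .sequence_io import CodonCountTable, TRNAGeneCopyTable, sense_codons, stop_codons

WC = "WC"
GU = "G:U"
IC = "I:C"
IA = "I:A"
UG = "U:G"
LA = "L:A"

#: Wobble classes optimized in eukaryote (and archaeal) mode.
FREE_CLASSES_EUKARYOTE: tuple[str, ...] = (GU, IC, IA, UG)
#: Prokaryote mode additionally frees the lysidine:A class.
FREE_CLASSES_PROKARYOTE: tuple[str, ...] = (GU, IC, IA, UG, LA)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SijWeights:
    """Coupling-efficiency penalties per interaction class, each in [0, 1].

    Watson-Crick interactions are pinned at 0 (perfect) unless explicitly
    overridden; missing wobble classes default to 0 as well.
    """

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"S[{cls}]={v} outside [0, 1]")

    def __getitem__(self, cls: str) -> float:
        return self.values.get(cls, 0.0)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SijWeights":
        return cls(json.loads(Path(path).read_text()))


#: Literature S_ij constants of the original tAI parameterization
#: (dos Reis et al. 2004), shipped as an external preset ("otAI mode").
OTAI_SIJ = SijWeights({GU: 0.41, IC: 0.28, IA: 0.9999, UG: 0.68, LA: 0.89})

# Third-base pairing rules: codon third base -> [(anticodon wobble base,
# interaction class)], Watson-Crick first.  Inosine is encoded genomically as
# A at position 34; lysidine is a modified C handled as a special case.
_THIRD_BASE_RULES: dict[str, tuple[tuple[str, str], ...]] = {
    "T": (("A", WC), ("G", GU)),
    "C": (("G", WC), ("A", IC)),
    "A": (("T", WC), ("A", IA)),
    "G": (("C", WC), ("T", UG)),
}


@dataclass(frozen=True)
class WobbleRuleSet:
    """Recognition rules mapping each sense codon to its decoding anticodons.

    ``special_wc_only`` lists codons restricted to their Watson-Crick
    anticodon (Met ATG and Trp TGG, whose families would otherwise credit
    initiator or other non-elongating tRNAs).
    """

    genetic_code_id: int = 1
    special_wc_only: frozenset[str] = frozenset({"ATG", "TGG"})

    def recognizers(
        self, codon: str, prokaryote: bool = False
    ) -> list[tuple[str, str]]:
        """(anticodon, interaction class) pairs able to decode ``codon``.

        The lysidine recognizer of bacterial ATA is reported with anticodon
        CAT and class L:A; its copy number lives in
        ``TRNAGeneCopyTable.lysidine_count``, not the Met CAT entry.
        """
        codon = codon.upper().replace("U", "T")
        if codon in stop_codons(self.genetic_code_id):
            raise ValueError(f"{codon} is a stop codon under code "
                             f"{self.genetic_code_id}")
        wc_anticodon = reverse_complement(codon)
        if codon in self.special_wc_only:
            return [(wc_anticodon, WC)]
        head = wc_anticodon[1:]
        pairs = [(base + head, cls) for base, cls in _THIRD_BASE_RULES[codon[2]]]
        if prokaryote and codon == "ATA":
            pairs.append(("CAT", LA))
        return pairs

    def recognition_table(
        self, prokaryote: bool = False
    ) -> dict[str, list[tuple[str, str]]]:
        return {
            c: self.recognizers(c, prokaryote)
            for c in sense_codons(self.genetic_code_id)
        }


@dataclass
class AdaptivenessMap:
    """Absolute (W) and relative (w) adaptiveness per sense codon.

    Codons with W = 0 (no decoding tRNA gene copies) get their w imputed as
    the geometric mean of the non-zero w values, so the tAI logarithm stays
    defined; those codons are listed in ``zero_substituted``.
    """

    W: dict[str, float]
    w: dict[str, float] = field(default_factory=dict)
    zero_substituted: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["codon\tW\tw\tsubstituted"]
        for codon in sorted(self.W):
            sub = int(codon in self.zero_substituted)
            lines.append(
                f"{codon}\t{self.W[codon]:.6g}\t{self.w.get(codon, float('nan')):.6g}\t{sub}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def absolute_adaptiveness(
    tgcn: TRNAGeneCopyTable,
    s: SijWeights,
    rules: WobbleRuleSet | None = None,
    prokaryote: bool = False,
) -> AdaptivenessMap:
    """Compute W_i = sum_j (1 - S_ij) * tGCN_ij for every sense codon."""
    rules = rules or WobbleRuleSet()
    W: dict[str, float] = {}
    for codon, pairs in rules.recognition_table(prokaryote).items():
        total = 0.0
        for anticodon, cls in pairs:
            copies = tgcn.lysidine_count if cls == LA else tgcn.get(anticodon)
            total += (1.0 - s[cls]) * copies
        W[codon] = total
    return AdaptivenessMap(W)


def relative_adaptiveness(amap: AdaptivenessMap) -> AdaptivenessMap:
    """Fill w = W / max(W), imputing zero-W codons by the geometric mean of
    the non-zero w values."""
    w_max = max(amap.W.values())
    if w_max <= 0:
        raise ValueError("all absolute adaptiveness values are zero")
    w = {c: W / w_max for c, W in amap.W.items() if W > 0}
    geo = math.exp(sum(math.log(v) for v in w.values()) / len(w))
    zero = sorted(c for c, W in amap.W.items() if W == 0)
    for c in zero:
        w[c] = geo
    amap.w = w
    amap.zero_substituted = zero
    return amap


def adaptiveness(
    tgcn: TRNAGeneCopyTable,
    s: SijWeights,
    rules: WobbleRuleSet | None = None,
    prokaryote: bool = False,
) -> AdaptivenessMap:
    """W then w in one call."""
    return relative_adaptiveness(absolute_adaptiveness(tgcn, s, rules, prokaryote))


def gene_tai(
    gene_counts: CodonCountTable,
    amap: AdaptivenessMap | Mapping[str, float],
    exclude_special: bool = False,
) -> float:
    """Gene tAI: exp((1/O_tot) * sum over codon occurrences of log w).

    Stop codons are excluded; Met ATG and Trp TGG occurrences are included
    with their Watson-Crick-only w unless ``exclude_special``.
    """
    w = amap.w if isinstance(amap, AdaptivenessMap) else amap
    excluded = {"ATG", "TGG"} if exclude_special else set()
    log_sum = 0.0
    n = 0
    for codon, count in gene_counts.counts.items():
        if codon in excluded or codon not in w or count == 0:
            continue
        log_sum += count * math.log(w[codon])
        n += count
    if n == 0:
        raise ValueError("gene has no scorable codons")
    return math.exp(log_sum / n)


def recognition_matrix(
    tgcn: TRNAGeneCopyTable,
    rules: WobbleRuleSet | None = None,
    prokaryote: bool = False,
    codons: Iterable[str] | None = None,
) -> tuple[list[str], list[str], np.ndarray]:
    """Copy-number matrix T with W = T @ (1 - S) for fast repeated evaluation.

    Returns (codon order, interaction-class order, T) where
    T[i, k] = total tGCN of anticodons recognizing codon i via class k.
    Used by the genetic-algorithm fitness, which evaluates W for thousands of
    candidate S vectors against one fixed tRNA pool.
    """
    rules = rules or WobbleRuleSet()
    codon_list = list(codons) if codons is not None else list(
        sense_codons(rules.genetic_code_id)
    )
    classes = [WC, GU, IC, IA, UG] + ([LA] if prokaryote else [])
    index = {cls: k for k, cls in enumerate(classes)}
    T = np.zeros((len(codon_list), len(classes)))
    for i, codon in enumerate(codon_list):
        for anticodon, cls in rules.recognizers(codon, prokaryote):
            copies = tgcn.lysidine_count if cls == LA else tgcn.get(anticodon)
            T[i, index[cls]] += copies
    return codon_list, classes, T
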