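"""Independent direct transcriptions of the index formulas, used as oracles.

Everything here is written from the defining equations with a deliberately
different construction from the package implementation (plain dict/loop
arithmetic; anticodon-to-codon traversal for the wobble model) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Data import CodonTable

STANDARD_STOPS = {"TAA", "TAG", "TGA"}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def standard_families(split_sixfold: bool = True) -> list[tuple[str, ...]]:
    """Synonymous families of the standard code, built directly from the
    NCBI table (six-fold families split by first-two-nucleotide box)."""
    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.items():
        if set(codon) <= set("ACGT"):
            by_aa.setdefault(aa, []).append(codon)
    out: list[tuple[str, ...]] = []
    for aa in sorted(by_aa):
        codons = sorted(by_aa[aa])
        if split_sixfold and len({c[:2] for c in codons}) > 1:
            for box in sorted({c[:2] for c in codons}):
                out.append(tuple(c for c in codons if c[:2] == box))
        else:
            out.append(tuple(codons))
    return out


def rscu_oracle(counts: dict[str, int]) -> dict[str, float]:
    """RSCU = O_c / ((1/k) * sum over family), per defining equation."""
    out: dict[str, float] = {}
    for fam in standard_families():
        tot = sum(counts.get(c, 0) for c in fam)
        if tot == 0:
            continue
        k = len(fam)
        for c in fam:
            out[c] = counts.get(c, 0) * k / tot
    return out


def fcf_oracle(ns: list[int]) -> float:
    m = len(ns)
    n = sum(ns)
    return sum(((ni + 1) / (n + m)) ** 2 for ni in ns)


def enc_oracle(counts: dict[str, int]) -> float:
    """ENc = Ns + sum_m K_m * (sum n_j) / (sum n_j F_j), fold by fold."""
    fams = standard_families()
    ns = sum(1 for f in fams if len(f) == 1)
    value = float(ns)
    for m in (2, 3, 4):
        fold_fams = [f for f in fams if len(f) == m]
        k_m = len(fold_fams)
        if k_m == 0:
            continue
        num = den = 0.0
        for fam in fold_fams:
            nj = sum(counts.get(c, 0) for c in fam)
            if nj > 0:
                num += nj
                den += nj * fcf_oracle([counts.get(c, 0) for c in fam])
        value += k_m * (num / den if num else m)
    return value


def cai_weights_oracle(ref_counts: dict[str, int]) -> dict[str, float]:
    out: dict[str, float] = {}
    for fam in standard_families():
        if len(fam) < 2:
            continue
        top = max(ref_counts.get(c, 0) for c in fam)
        if top == 0:
            continue
        for c in fam:
            n = ref_counts.get(c, 0)
            out[c] = (n if n else 0.5) / top
    return out


def cai_oracle(gene_counts: dict[str, int], weights: dict[str, float]) -> float:
    logs = []
    for c, n in gene_counts.items():
        if c in weights:
            logs.extend([math.log(weights[c])] * n)
    return math.exp(sum(logs) / len(logs))


def scuo_oracle(gene_counts: dict[str, int]) -> float:
    num = den = 0.0
    for fam in standard_families():
        m = len(fam)
        if m < 2:
            continue
        ns = [gene_counts.get(c, 0) for c in fam]
        n = sum(ns)
        if n == 0:
            continue
        h = -sum((x / n) * math.log2(x / n) for x in ns if x)
        num += n * (math.log2(m) - h) / math.log2(m)
        den += n
    return num / den


def gene_tai_oracle(seq: str, w: dict[str, float]) -> float:
    """Gene tAI as a geometric mean walked directly over the gene string."""
    logs = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in w and codon not in STANDARD_STOPS:
            logs.append(math.log(w[codon]))
    return math.exp(sum(logs) / len(logs))


def adaptiveness_oracle(
    tgcn: dict[str, int],
    s: dict[str, float],
    lysidine: int = 0,
    prokaryote: bool = False,
) -> dict[str, float]:
    """W by anticodon-to-codon traversal (the reverse of the implementation's
    codon-to-anticodon direction), then max-normalized with geometric-mean
    imputation of zero-W codons."""
    sense = sorted(
        c
        for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
        if c not in STANDARD_STOPS
    )
    W = {c: 0.0 for c in sense}
    wobble_reads = {"G": ("T", "G:U"), "A": ("C", "I:C"), "T": ("G", "U:G")}
    inosine_a = ("A", "I:A")
    for anticodon, copies in tgcn.items():
        wc_codon = revcomp(anticodon)
        if wc_codon in W:
            W[wc_codon] += copies  # Watson-Crick, S = 0
        wobble_base = anticodon[0]
        targets = []
        if wobble_base in wobble_reads:
            third, cls = wobble_reads[wobble_base]
            targets.append((wc_codon[:2] + third, cls))
        if wobble_base == inosine_a[0]:
            targets.append((wc_codon[:2] + "A", "I:A"))
        for codon, cls in targets:
            if codon in W and codon not in ("ATG", "TGG"):
                W[codon] += (1 - s.get(cls, 0.0)) * copies
    # specials: ATG and TGG take only their WC anticodon
    W["ATG"] = tgcn.get("CAT", 0)
    W["TGG"] = tgcn.get("CCA", 0)
    if prokaryote:
        W["ATA"] += (1 - s.get("L:A", 0.0)) * lysidine
    wmax = max(W.values())
    w = {c: v / wmax for c, v in W.items() if v > 0}
    geo = math.exp(sum(map(math.log, w.values())) / len(w))
    for c, v in W.items():
        if v == 0:
            w[c] = geo
    return w


def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson with hand-rolled average ranks."""

    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return np.array(r)

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def williams_oracle(r12: float, r13: float, r23: float, n: int) -> float:
    """The Williams t statistic assembled step by step."""
    det = np.linalg.det(
        np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]], float)
    )
    rbar = (r12 + r13) / 2
    num = (n - 1) * (1 + r23)
    den = 2 * det * (n - 1) / (n - 3) + rbar * rbar * (1 - r23) ** 3
    return (r12 - r13) * math.sqrt(num / den)


def random_count_table(rng: np.random.Generator, max_count: int = 50) -> dict[str, int]:
    """Random sense-codon counts with occasional zeros, standard code."""
    counts = {}
    for fam in standard_families():
        for c in fam:
            counts[c] = int(rng.integers(0, max_count + 1))
    # guarantee at least one multi-codon family observed
    counts["GCT"] = max(counts["GCT"], 1)
    return counts
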