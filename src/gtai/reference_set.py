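"""Reference-set selection by lowest ENc and its pooled RSCU.

Highly expressed genes are under the strongest translational selection and
therefore show the strongest codon usage bias; the lowest-ENc fraction of a
genome is used as a proxy reference set of putatively highly expressed genes,
with no expression data required.
"""

from __future__ import annotations

import math

from .codon_usage import FamilyPartition, enc, rscu
from .sequence_io import CodonCountTable, GenomeCDSSet, count_codons

#: Fraction of the genome taken as the reference set when unspecified.
DEFAULT_REFERENCE_FRACTION = 0.05
#: Floor on reference-set size (when the genome has at least that many genes).
MIN_REFERENCE_GENES = 5


def gene_enc_values(
    genes: GenomeCDSSet, partition: FamilyPartition
) -> dict[str, float]:
    """Per-gene improved ENc, keyed by gene id, in input order."""
    return {
        g.id: enc(count_codons(g, genetic_code_id=genes.genetic_code_id), partition)
        for g in genes
    }


def select_reference(
    genes: GenomeCDSSet,
    fraction: float = DEFAULT_REFERENCE_FRACTION,
    partition: FamilyPartition | None = None,
    enc_values: dict[str, float] | None = None,
) -> GenomeCDSSet:
    """The ceil(fraction * N) genes with the smallest ENc.

    Ties at the cut are broken by input order (earlier index wins), so the
    selection is deterministic for a fixed input.  At least
    :data:`MIN_REFERENCE_GENES` genes are returned when the genome has that
    many.  Precomputed ``enc_values`` may be passed to avoid recomputation.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("reference fraction must be in (0, 1]")
    if partition is None and enc_values is None:
        raise ValueError("either a family partition or precomputed ENc required")
    if enc_values is None:
        enc_values = gene_enc_values(genes, partition)
    n = len(genes)
    k = max(math.ceil(fraction * n), min(MIN_REFERENCE_GENES, n))
    order = sorted(range(n), key=lambda i: (enc_values[genes.genes[i].id], i))
    chosen = sorted(order[:k])
    return GenomeCDSSet([genes.genes[i] for i in chosen], genes.genetic_code_id)


def reference_rscu(
    reference: GenomeCDSSet, partition: FamilyPartition
) -> dict[str, float]:
    """RSCU of the POOLED codon counts of the reference genes.

    Pooling (rather than averaging per-gene RSCU) weights genes by length and
    keeps rare codons estimable; families absent from the pooled counts are
    undefined and omitted.
    """
    pooled: CodonCountTable = count_codons(
        reference, genetic_code_id=reference.genetic_code_id
    )
    return rscu(pooled, partition)
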