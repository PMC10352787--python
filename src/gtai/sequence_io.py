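"""Reading, validating and counting coding sequences and tRNA gene-copy tables.

Coding sequences arrive as multi-record FASTA (one CDS per record); tRNA gene
copy numbers (tGCN) arrive as a delimited table keyed by anticodon, the format
GtRNAdb exports reduce to.  Everything downstream (RSCU, ENc, tAI) consumes
the codon count tables produced here.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

DNA_BASES = frozenset("ACGT")
AMBIGUOUS = frozenset("NRYSWKMBDHV")
VALID_CHARS = DNA_BASES | AMBIGUOUS


class SequenceIOError(ValueError):
    """Raised for unreadable or structurally invalid sequence inputs."""


def stop_codons(genetic_code_id: int = 1) -> frozenset[str]:
    """Stop codons (DNA alphabet) of an NCBI translation table."""
    try:
        table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    except KeyError as exc:
        raise SequenceIOError(f"unknown genetic code id: {genetic_code_id}") from exc
    return frozenset(table.stop_codons)


def sense_codons(genetic_code_id: int = 1) -> tuple[str, ...]:
    """The sense codons of a translation table, in lexicographic order."""
    stops = stop_codons(genetic_code_id)
    return tuple(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in stops
    )


@dataclass(frozen=True)
class CodingSequence:
    """A single validated CDS: identifier plus uppercase DNA sequence."""

    id: str
    seq: str

    @property
    def codon_count(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> Iterator[str]:
        s = self.seq
        for i in range(0, len(s) - len(s) % 3, 3):
            yield s[i : i + 3]


@dataclass
class GenomeCDSSet:
    """An ordered, uniformly validated collection of coding sequences."""

    genes: list[CodingSequence]
    genetic_code_id: int = 1

    def __post_init__(self) -> None:
        if not self.genes:
            raise SequenceIOError("empty gene set")
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise SequenceIOError("duplicate record ids in gene set")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[CodingSequence]:
        return iter(self.genes)

    def ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def subset(self, ids: Iterable[str]) -> "GenomeCDSSet":
        wanted = set(ids)
        return GenomeCDSSet(
            [g for g in self.genes if g.id in wanted], self.genetic_code_id
        )


@dataclass
class FilterSettings:
    """CDS validation thresholds.

    Defaults keep codon statistics meaningful on fragments: at least 30 codons,
    at most 5% ambiguous bases, and no internal stop codons (strict mode).
    """

    min_codons: int = 30
    max_ambiguous_frac: float = 0.05
    strict_internal_stop: bool = True


@dataclass
class FilterReport:
    """Per-reason tallies of records dropped during CDS validation."""

    total_records: int = 0
    passed: int = 0
    bad_length: int = 0
    too_short: int = 0
    too_ambiguous: int = 0
    internal_stop: int = 0
    invalid_chars: int = 0

    @property
    def dropped(self) -> int:
        return self.total_records - self.passed

    def as_dict(self) -> dict[str, int]:
        return {
            "total_records": self.total_records,
            "passed": self.passed,
            "bad_length": self.bad_length,
            "too_short": self.too_short,
            "too_ambiguous": self.too_ambiguous,
            "internal_stop": self.internal_stop,
            "invalid_chars": self.invalid_chars,
        }


def _validate_record(
    rec_id: str, seq: str, filters: FilterSettings, stops: frozenset[str],
    report: FilterReport,
) -> CodingSequence | None:
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= VALID_CHARS:
        report.invalid_chars += 1
        return None
    if len(seq) % 3 != 0:
        report.bad_length += 1
        return None
    n_codons = len(seq) // 3
    if n_codons < filters.min_codons:
        report.too_short += 1
        return None
    ambiguous = sum(1 for b in seq if b not in DNA_BASES)
    if len(seq) > 0 and ambiguous / len(seq) > filters.max_ambiguous_frac:
        report.too_ambiguous += 1
        return None
    if filters.strict_internal_stop:
        # the final codon may be (usually is) a stop; internal ones disqualify
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in stops:
                report.internal_stop += 1
                return None
    report.passed += 1
    return CodingSequence(rec_id, seq)


def read_cds_fasta(
    path: str | Path,
    filters: FilterSettings | None = None,
    genetic_code_id: int = 1,
) -> tuple[GenomeCDSSet, FilterReport]:
    """Read a CDS FASTA, validate each record, and return survivors + report.

    Records failing any filter (length not a multiple of 3, shorter than
    ``min_codons``, ambiguous-base fraction above threshold, internal stop in
    strict mode) are dropped and counted in the :class:`FilterReport`.

    Raises
    ------
    SequenceIOError
        If the file is unreadable, is not FASTA, or zero genes survive.
    """
    filters = filters or FilterSettings()
    path = Path(path)
    if not path.exists():
        raise SequenceIOError(f"no such file: {path}")
    stops = stop_codons(genetic_code_id)
    report = FilterReport()
    genes: list[CodingSequence] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - Bio raises rarely here
        raise SequenceIOError(f"failed to parse FASTA {path}: {exc}") from exc
    for rec in records:
        report.total_records += 1
        gene = _validate_record(rec.id, str(rec.seq), filters, stops, report)
        if gene is not None:
            genes.append(gene)
    if not genes:
        raise SequenceIOError(f"no records in {path} survived CDS filters")
    return GenomeCDSSet(genes, genetic_code_id), report


@dataclass
class CodonCountTable:
    """Per-codon occurrence counts for a gene or a pooled gene set.

    ``skipped`` tallies codons containing ambiguous bases, which are never
    attributed to any codon (they would corrupt RSCU and ENc).
    """

    counts: dict[str, int] = field(default_factory=dict)
    genetic_code_id: int = 1
    skipped: int = 0

    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        if self.genetic_code_id != other.genetic_code_id:
            raise ValueError("cannot add counts under different genetic codes")
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCountTable(dict(merged), self.genetic_code_id,
                               self.skipped + other.skipped)


def count_codons(
    genes: GenomeCDSSet | CodingSequence | Iterable[CodingSequence],
    drop_stops: bool = True,
    genetic_code_id: int | None = None,
) -> CodonCountTable:
    """Tally codon occurrences over one gene or a gene set.

    Codons containing ambiguous bases are skipped and counted separately;
    stop codons are excluded when ``drop_stops`` (the default).
    """
    if isinstance(genes, CodingSequence):
        gene_iter: Iterable[CodingSequence] = [genes]
        code = genetic_code_id or 1
    elif isinstance(genes, GenomeCDSSet):
        gene_iter = genes.genes
        code = genetic_code_id or genes.genetic_code_id
    else:
        gene_iter = list(genes)
        code = genetic_code_id or 1
    stops = stop_codons(code) if drop_stops else frozenset()
    counts: Counter[str] = Counter()
    skipped = 0
    for gene in gene_iter:
        for codon in gene.codons():
            if not set(codon) <= DNA_BASES:
                skipped += 1
            elif codon not in stops:
                counts[codon] += 1
    return CodonCountTable(dict(counts), code, skipped)


@dataclass
class TRNAGeneCopyTable:
    """Anticodon (DNA, 5'->3') -> tRNA gene copy number (tGCN).

    The wobble base (position 34) is the FIRST character of the anticodon;
    an anticodon Watson-Crick pairs the reverse complement codon.
    ``lysidine_count`` carries bacterial Ile2 copies (CAT anticodon whose C34
    is modified to lysidine, decoding ATA) so they are not conflated with the
    initiator/elongator Met tRNA that shares the CAT anticodon.
    """

    entries: dict[str, int]
    lysidine_count: int = 0

    def __post_init__(self) -> None:
        for anticodon, n in self.entries.items():
            if len(anticodon) != 3 or not set(anticodon) <= DNA_BASES:
                raise SequenceIOError(f"malformed anticodon: {anticodon!r}")
            if n < 0:
                raise SequenceIOError(f"negative copy number for {anticodon}")
        if self.lysidine_count < 0:
            raise SequenceIOError("negative lysidine count")
        if not any(v > 0 for v in self.entries.values()) and self.lysidine_count == 0:
            raise SequenceIOError("tGCN table has no positive entries")

    def get(self, anticodon: str) -> int:
        return self.entries.get(anticodon, 0)

    def scaled(self, k: int) -> "TRNAGeneCopyTable":
        return TRNAGeneCopyTable(
            {a: n * k for a, n in self.entries.items()}, self.lysidine_count * k
        )


_ILE2_LABELS = {"ILE2", "ILE-2", "LYSIDINE", "K2C"}


def read_tgcn(path: str | Path, lysidine_count: int | None = None) -> TRNAGeneCopyTable:
    """Parse a delimited anticodon/copy-number table (GtRNAdb-style export).

    Columns: anticodon, count and optionally isotype; the header row is
    auto-detected.  Duplicate anticodon rows are summed.  When an isotype
    column labels bacterial Ile2 rows (``Ile2``), their CAT copies populate
    ``lysidine_count`` instead of the Met CAT entry; without isotype labels,
    CAT copies are treated as Met tRNA unless ``lysidine_count`` is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceIOError(f"no such file: {path}")
    text = path.read_text(encoding="utf-8")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    # header auto-detection: a data row starts with a trinucleotide anticodon
    first = str(df.iloc[0, 0]).strip().upper().replace("U", "T")
    if not (len(first) == 3 and set(first) <= DNA_BASES):
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise SequenceIOError("tGCN table needs anticodon and count columns")
    entries: Counter[str] = Counter()
    lysidine = 0
    for _, row in df.iterrows():
        anticodon = str(row.iloc[0]).strip().upper().replace("U", "T")
        if len(anticodon) != 3 or not set(anticodon) <= DNA_BASES:
            raise SequenceIOError(f"malformed anticodon: {anticodon!r}")
        try:
            n = int(str(row.iloc[1]).strip())
        except ValueError as exc:
            raise SequenceIOError(f"non-integer copy number: {row.iloc[1]!r}") from exc
        if n < 0:
            raise SequenceIOError(f"negative copy number for {anticodon}")
        isotype = ""
        if df.shape[1] >= 3 and not pd.isna(row.iloc[2]):
            isotype = str(row.iloc[2]).strip().upper()
        if anticodon == "CAT" and isotype in _ILE2_LABELS:
            lysidine += n
        else:
            entries[anticodon] += n
    if lysidine_count is not None:
        lysidine = lysidine_count
    return TRNAGeneCopyTable(dict(entries), lysidine)


def write_tgcn(table: TRNAGeneCopyTable, path: str | Path) -> None:
    """Write a tGCN table as TSV (anticodon, count[, isotype]) round-trippable
    by :func:`read_tgcn`."""
    lines = ["anticodon\tcount\tisotype"]
    for anticodon in sorted(table.entries):
        lines.append(f"{anticodon}\t{table.entries[anticodon]}\t")
    if table.lysidine_count:
        lines.append(f"CAT\t{table.lysidine_count}\tIle2")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_gene_scores(
    scores: Mapping[str, float], path: str | Path, score_name: str = "score"
) -> None:
    """Write a two-column TSV of per-gene scores, preserving input order."""
    if not scores:
        raise ValueError("empty score map")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"gene_id\t{score_name}\n")
        for gene_id, value in scores.items():
            fh.write(f"{gene_id}\t{value:.6g}\n")


def read_gene_scores(path: str | Path) -> dict[str, float]:
    """Read a table written by :func:`write_gene_scores`."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_fasta(genes: GenomeCDSSet | Iterable[CodingSequence], path: str | Path) -> None:
    """Write coding sequences as uncompressed FASTA, 70 columns wide."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene in genes:
            fh.write(f">{gene.id}\n")
            for i in range(0, len(gene.seq), 70):
                fh.write(gene.seq[i : i + 70] + "\n")
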