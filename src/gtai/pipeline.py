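"""End-to-end orchestration: FASTA + tGCN in, per-gene tAI + S_ij out.

Thin wrappers over :class:`~gtai.estimators.TRNAAdaptationIndex` that add
file IO, stage-tagged error reporting and a machine-readable run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import evaluation_stats as es
from .estimators import TRNAAdaptationIndex
from .sequence_io import (
    FilterReport,
    FilterSettings,
    read_cds_fasta,
    read_tgcn,
    write_gene_scores,
)

#: Stage names in execution order; exit codes are 10 + stage index.
STAGES = ("read_fasta", "read_tgcn", "reference", "optimize", "score", "write")


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = 10 + STAGES.index(stage)


@dataclass
class GtAIRun:
    """Everything a compute run produces."""

    gene_tai: dict[str, float]
    estimator: TRNAAdaptationIndex
    filter_report: FilterReport
    report: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gene_scores(self.gene_tai, out / "gene_tai.tsv", "tAI")
        self.estimator.sij_.to_json(out / "sij.json")
        if self.estimator.ga_result_ is not None:
            history = self.estimator.ga_result_.history
            lines = ["generation\tbest_fitness"] + [
                f"{i + 1}\t{f:.10g}" for i, f in enumerate(history)
            ]
            (out / "ga_history.tsv").write_text("\n".join(lines) + "\n")
        (out / "report.json").write_text(
            json.dumps(self.report, indent=2) + "\n"
        )


def compute_gtai(
    genome_fasta: str | Path,
    tgcn_path: str | Path,
    *,
    ref_fraction: float = 0.05,
    population_size: int = 60,
    generations: int = 100,
    seed: int | None = None,
    prokaryote: bool = False,
    genetic_code_id: int = 1,
    filters: FilterSettings | None = None,
    sij: str = "optimize",
    out_dir: str | Path | None = None,
) -> GtAIRun:
    """Read -> filter -> ENc -> reference RSCU -> GA -> W/w -> per-gene tAI.

    Deterministic for a fixed seed; any stage failure raises a
    :class:`PipelineError` carrying the stage name and a distinct exit code.
    """
    try:
        genome, filter_report = read_cds_fasta(
            genome_fasta, filters, genetic_code_id
        )
    except Exception as exc:
        raise PipelineError("read_fasta", str(exc)) from exc
    try:
        tgcn = read_tgcn(tgcn_path)
    except Exception as exc:
        raise PipelineError("read_tgcn", str(exc)) from exc

    model = TRNAAdaptationIndex(
        tgcn,
        sij=sij,
        ref_fraction=ref_fraction,
        population_size=population_size,
        generations=generations,
        prokaryote=prokaryote,
        genetic_code_id=genetic_code_id,
        random_state=seed,
    )
    try:
        model.fit(genome)
    except Exception as exc:
        raise PipelineError("optimize", str(exc)) from exc
    try:
        scores = model.score_genes(genome)
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc

    report = {
        "n_genes": len(genome),
        "filter_report": filter_report.as_dict(),
        "reference_ids": model.reference_ids_,
        "best_sij": model.sij_.as_dict(),
        "best_fitness": model.fitness_,
        "fitness_history": (
            model.ga_result_.history if model.ga_result_ else []
        ),
        "config": {
            "ref_fraction": ref_fraction,
            "population_size": population_size,
            "generations": generations,
            "seed": seed,
            "prokaryote": prokaryote,
            "genetic_code_id": genetic_code_id,
            "sij": sij if isinstance(sij, str) else "explicit",
        },
    }
    run = GtAIRun(scores, model, filter_report, report)
    if out_dir is not None:
        try:
            run.write(out_dir)
        except Exception as exc:
            raise PipelineError("write", str(exc)) from exc
    return run


def evaluate(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    abundance: Mapping[str, float] | None = None,
    *,
    subsample_fraction: float | None = None,
    subsample_replicates: int = 1000,
    seed: int | None = None,
) -> dict:
    """Pairwise Spearman comparison of two per-gene score tables.

    With an ``abundance`` table the report adds rho(a, abundance),
    rho(b, abundance) and a Williams' test of whether the two indices
    correlate differently with the shared abundance variable.  Optional
    repeated-subsample correlation distributions guard against reference-set
    inflation of the headline rho.
    """
    shared = [g for g in scores_a if g in scores_b]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared gene ids between score tables")
    a = np.array([scores_a[g] for g in shared])
    b = np.array([scores_b[g] for g in shared])
    report: dict = {"n_shared": len(shared), "rho_ab": es.spearman(a, b)}
    if abundance is not None:
        triple = [g for g in shared if g in abundance]
        if len(triple) < 4:
            raise ValueError("fewer than 4 genes shared with abundance table")
        a3 = np.array([scores_a[g] for g in triple])
        b3 = np.array([scores_b[g] for g in triple])
        y3 = np.array([abundance[g] for g in triple])
        r_ay = es.spearman(a3, y3)
        r_by = es.spearman(b3, y3)
        r_ab = es.spearman(a3, b3)
        wt = es.williams_test(r_ay, r_by, r_ab, len(triple))
        report.update(
            n_abundance=len(triple),
            rho_a_abundance=r_ay,
            rho_b_abundance=r_by,
            williams_t=wt.t,
            williams_p=wt.p,
            williams_df=wt.df,
        )
    if subsample_fraction is not None:
        rhos = es.repeated_subsample_correlation(
            a, b, subsample_fraction, subsample_replicates, seed
        )
        finite = rhos[np.isfinite(rhos)]
        report["subsample"] = {
            "fraction": subsample_fraction,
            "replicates": subsample_replicates,
            "valid": int(finite.size),
            "mean_rho": float(np.mean(finite)),
            "sd_rho": float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0,
        }
    return report
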