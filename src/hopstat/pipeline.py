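"""End-to-end orchestration: expression matrix -> enrichment report.

Runs the full chain for each mutant genotype — control/all-Absent probe
filtering, stage-matched log2 fold change, directional thresholding — then
the cross-genotype target classification, heterochromatin annotation,
contingency tally and exact test, and packs everything into a ReportBundle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .chromatin import (
    ContingencyTable,
    HeterochromatinFlags,
    PeakSet,
    ProbeAnnotation,
    annotate_heterochromatin,
    tally_contingency,
)
from .classification import (
    TargetClassification,
    classify_targets,
    summarize_classification,
    venn_overlap,
)
from .core_io import CONTROL_PREFIX, ExpressionMatrix, Genotype, ReportBundle, filter_probe_sets
from .differential import (
    DEFAULT_CUTOFF_LOG2,
    DEFAULT_PSEUDOCOUNT,
    DirectionalSets,
    call_directional_sets,
    fc_percentile,
    log2_fold_change,
)
from .stats import EnrichmentResult, enrichment_result

__all__ = ["PipelineResult", "compute_directional_sets", "run_pipeline"]

MUTANTS = (Genotype.JAK_GOF, Genotype.JAK_LOF, Genotype.STAT_HET, Genotype.STAT_MATNULL)


@dataclass
class PipelineResult:
    directional: dict[Genotype, DirectionalSets]
    percentile_diagnostics: dict[str, float]
    classification: TargetClassification
    classification_summary: dict
    flags: HeterochromatinFlags
    contingency: ContingencyTable
    fractions: dict[str, dict[str, Fraction]]
    enrichment: EnrichmentResult
    report: ReportBundle


def compute_directional_sets(
    matrix: ExpressionMatrix,
    cutoff_log2: float = DEFAULT_CUTOFF_LOG2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    control_prefix: str = CONTROL_PREFIX,
) -> tuple[dict[Genotype, DirectionalSets], dict[str, float]]:
    """Per-genotype filtering + fold change + thresholding, plus the pooled
    top-decile diagnostics (10th/90th percentile of log2 fold changes)."""
    directional: dict[Genotype, DirectionalSets] = {}
    tables = []
    for g in MUTANTS:
        filtered = filter_probe_sets(matrix, g, control_prefix=control_prefix)
        fc = log2_fold_change(filtered, g, pseudocount=pseudocount)
        tables.append(fc)
        directional[g] = call_directional_sets(fc, cutoff_log2=cutoff_log2)
    diagnostics = {
        "log2fc_p10_pooled": fc_percentile(tables, 10),
        "log2fc_p90_pooled": fc_percentile(tables, 90),
    }
    return directional, diagnostics


def run_pipeline(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    peak_sets: list[PeakSet],
    cutoff_log2: float = DEFAULT_CUTOFF_LOG2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    control_prefix: str = CONTROL_PREFIX,
    mirror: bool = False,
    parameters: dict | None = None,
) -> PipelineResult:
    directional, diagnostics = compute_directional_sets(
        matrix, cutoff_log2=cutoff_log2, pseudocount=pseudocount,
        control_prefix=control_prefix,
    )
    tc = classify_targets(
        directional[Genotype.JAK_GOF],
        directional[Genotype.JAK_LOF],
        directional[Genotype.STAT_HET],
        directional[Genotype.STAT_MATNULL],
        mirror=mirror,
    )
    summary = summarize_classification(tc)
    flags = annotate_heterochromatin(tc, annotation, peak_sets)
    table, fractions = tally_contingency(tc, flags)
    enr = enrichment_result(table)

    het = directional[Genotype.STAT_HET]
    mat = directional[Genotype.STAT_MATNULL]
    venns = [
        venn_overlap(set(mat.up), set(het.up), "STAT_MATNULL.up", "STAT_HET.up"),
        venn_overlap(set(mat.down), set(het.down), "STAT_MATNULL.down", "STAT_HET.down"),
    ]
    report = ReportBundle(
        parameters={
            "cutoff_log2": cutoff_log2,
            "pseudocount": pseudocount,
            "control_prefix": control_prefix,
            "mirror": mirror,
            **diagnostics,
            **(parameters or {}),
        },
        directional_counts={
            g.value: {"up": len(d.up), "down": len(d.down)}
            for g, d in directional.items()
        },
        venn_summaries=[vars(v) for v in venns],
        classification_counts={
            **summary["label_counts"],
        },
        quadrant_counts=summary["quadrant_counts"],
        heterochromatin_fractions={
            group: {key: str(frac) for key, frac in fr.items()}
            for group, fr in fractions.items()
        },
        contingency_table=table.as_list(),
        odds_ratio=enr.odds_ratio,
        p_two_tailed=enr.p_two_tailed,
    )
    report.validate()
    return PipelineResult(
        directional=directional,
        percentile_diagnostics=diagnostics,
        classification=tc,
        classification_summary=summary,
        flags=flags,
        contingency=table,
        fractions=fractions,
        enrichment=enr,
        report=report,
    )
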