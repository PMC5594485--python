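"""Stage-matched fold-change computation and directional thresholding.

Each mutant genotype is compared against wildtype embryos of the same
collection stage: replicate intensities are averaged on the linear scale and
the log2 ratio of the means taken, with a small pseudocount guarding
against zero signal. Probes at or beyond a log2 cutoff (default 1.0, i.e. the
2-fold criterion) form the up- and down-regulated sets that drive all
downstream set logic.

The percentile diagnostic reports where the top decile of up/down log2 fold
changes sits, the check used to justify a plain 2-fold cutoff over a
moderated statistic; it never filters anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MUTANT_STAGE, ExpressionMatrix, Genotype, Stage

__all__ = [
    "FoldChangeTable",
    "DirectionalSets",
    "log2_fold_change",
    "call_directional_sets",
    "fc_percentile",
]

DEFAULT_PSEUDOCOUNT = 1.0  # linear signal units
DEFAULT_CUTOFF_LOG2 = 1.0  # the 2-fold criterion


@dataclass
class FoldChangeTable:
    """Per-probe log2(mutant/WT) fold changes for one mutant genotype."""

    mutant: Genotype
    stage: Stage
    log2fc: pd.Series  # index: probe ids

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc.to_numpy()).all():
            bad = self.log2fc.index[~np.isfinite(self.log2fc.to_numpy())]
            raise ValueError(
                f"non-finite log2 fold change for probe(s) {list(bad[:5])}; "
                "use a positive pseudocount"
            )
        if self.log2fc.index.has_duplicates:
            raise ValueError("one row per probe required")


@dataclass
class DirectionalSets:
    """Up- and down-regulated probe-id sets for one mutant at a cutoff."""

    mutant: Genotype
    up: frozenset[str]
    down: frozenset[str]
    cutoff_log2: float = DEFAULT_CUTOFF_LOG2

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        if self.cutoff_log2 <= 0:
            raise ValueError(f"cutoff_log2 must be positive, got {self.cutoff_log2}")
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"{self.mutant.value}: probe(s) in both up and down sets: "
                f"{sorted(overlap)[:5]}"
            )


def log2_fold_change(
    matrix: ExpressionMatrix,
    mutant: Genotype | str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FoldChangeTable:
    """log2((mean mutant + eps) / (mean WT + eps)) per probe, means on the
    linear scale over replicates, WT stage-matched to the mutant."""
    mutant = Genotype(mutant)
    if mutant is Genotype.WT:
        raise ValueError("fold change is relative to WT; pass a mutant genotype")
    stage = MUTANT_STAGE[mutant]
    mut_ids = matrix.sample_ids(mutant)
    wt_ids = matrix.sample_ids(Genotype.WT, stage)
    if not mut_ids or not wt_ids:
        raise ValueError(
            f"need >=1 {mutant.value} replicate and >=1 stage-matched WT "
            f"({stage.value}) replicate"
        )
    mut_mean = matrix.intensity[mut_ids].mean(axis=1)
    wt_mean = matrix.intensity[wt_ids].mean(axis=1)
    with np.errstate(divide="ignore"):
        lfc = np.log2(mut_mean + pseudocount) - np.log2(wt_mean + pseudocount)
    return FoldChangeTable(mutant=mutant, stage=stage, log2fc=lfc.rename("log2fc"))


def call_directional_sets(
    fc: FoldChangeTable, cutoff_log2: float = DEFAULT_CUTOFF_LOG2
) -> DirectionalSets:
    """Threshold a fold-change table into up/down sets, inclusive boundary."""
    if cutoff_log2 <= 0:
        raise ValueError(f"cutoff_log2 must be positive, got {cutoff_log2}")
    lfc = fc.log2fc
    up = frozenset(lfc.index[lfc >= cutoff_log2])
    down = frozenset(lfc.index[lfc <= -cutoff_log2])
    return DirectionalSets(mutant=fc.mutant, up=up, down=down, cutoff_log2=cutoff_log2)


def fc_percentile(
    tables: FoldChangeTable | list[FoldChangeTable], q: float
) -> float:
    """q-th percentile of log2 fold changes, linear interpolation between
    order statistics (endpoints at min/max).

    Accepts one table or several; several are pooled, matching a diagnostic
    computed "over all probes" across genotypes.
    """
    if isinstance(tables, FoldChangeTable):
        tables = [tables]
    if not 0 < q < 100:
        raise ValueError(f"percentile q must be in (0, 100), got {q}")
    values = np.concatenate([t.log2fc.to_numpy() for t in tables]) if tables else np.array([])
    if values.size == 0:
        raise ValueError("fc_percentile requires at least one probe")
    return float(np.percentile(values, q, method="linear"))
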