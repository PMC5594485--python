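"""Directional set algebra: putative canonical vs non-canonical target calls.

The classification rests on the opposing biology of the two JAK/STAT modes.
In the canonical pathway, JAK gain-of-function and STAT loss-of-function
move target expression in opposite directions (more active STAT, more target
transcription). In the non-canonical pathway, JAK overactivation and STAT
loss both deplete heterochromatin and therefore both DE-repress
heterochromatin-silenced loci: the two perturbations move expression the
same way.

Operationally, the base set is probes upregulated in the JAK
gain-of-function mutant AND downregulated in the JAK loss-of-function
mutant. Within that base, a probe downregulated in a STAT loss-of-function
genotype behaves canonically; one upregulated behaves non-canonically. Two
STAT genotypes supply evidence — the zygotic heterozygote ("embryo"
provenance) and the maternal-null ("maternal" provenance) — and probes where
the two disagree are removed as conflicts. Base-set probes with no
significant STAT direction stay unclassified.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .core_io import Genotype
from .differential import DirectionalSets

__all__ = [
    "Label",
    "VennSummary",
    "ProbeCall",
    "TargetClassification",
    "venn_overlap",
    "classify_targets",
    "summarize_classification",
]


class Label(str, Enum):
    CANONICAL = "canonical"
    NON_CANONICAL = "non_canonical"
    REMOVED_CONFLICT = "removed_conflict"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class VennSummary:
    """Pairwise overlap partition: |A\\B|, |A∩B|, |B\\A|."""

    label_a: str
    label_b: str
    only_a: int
    shared: int
    only_b: int


def venn_overlap(a: set[str], b: set[str], label_a: str = "A", label_b: str = "B") -> VennSummary:
    a, b = set(a), set(b)
    shared = len(a & b)
    return VennSummary(
        label_a=label_a,
        label_b=label_b,
        only_a=len(a) - shared,
        shared=shared,
        only_b=len(b) - shared,
    )


@dataclass(frozen=True)
class ProbeCall:
    """Per-probe outcome: label, evidence provenance and the direction seen
    in each genotype (+1 up, -1 down, 0 neither)."""

    probe_id: str
    label: Label
    provenance: frozenset[str]  # subset of {"embryo", "maternal"}
    directions: tuple[tuple[str, int], ...]


@dataclass
class TargetClassification:
    calls: dict[str, ProbeCall]
    #: Fig. 2-style quadrant counts before conflict removal / deduplication:
    #: base-set probes with STAT evidence, split by genotype and direction.
    quadrant_counts: dict[str, int]

    def probes_with_label(self, label: Label) -> set[str]:
        return {p for p, c in self.calls.items() if c.label is label}


def _direction(probe: str, sets: DirectionalSets) -> int:
    if probe in sets.up:
        return +1
    if probe in sets.down:
        return -1
    return 0


def classify_targets(
    jak_gof: DirectionalSets,
    jak_lof: DirectionalSets,
    stat_het: DirectionalSets,
    stat_matnull: DirectionalSets,
    mirror: bool = False,
) -> TargetClassification:
    """Classify every probe seen in any directional set.

    Base set B = jak_gof.up ∩ jak_lof.down. For p in B, STAT-down is
    canonical evidence and STAT-up non-canonical evidence, independently from
    the heterozygote (embryo) and the maternal-null (maternal). Disagreement
    removes the probe as a conflict; agreement or a single source labels it
    with that provenance; no evidence leaves it unclassified. Probes outside
    B are unclassified.

    With ``mirror=True`` the reversed base jak_gof.down ∩ jak_lof.up is also
    classified, with the STAT evidence polarity flipped (STAT-up = canonical
    evidence there); default off.
    """
    by_geno = {
        Genotype.JAK_GOF: jak_gof,
        Genotype.JAK_LOF: jak_lof,
        Genotype.STAT_HET: stat_het,
        Genotype.STAT_MATNULL: stat_matnull,
    }
    for geno, ds in by_geno.items():
        if ds.mutant is not geno:
            raise ValueError(
                f"directional sets for {geno.value} were built for {ds.mutant.value}"
            )

    universe = set()
    for ds in by_geno.values():
        universe |= ds.up | ds.down

    base = jak_gof.up & jak_lof.down
    bases = [(base, +1)]
    if mirror:
        bases.append(((jak_gof.down & jak_lof.up) - base, -1))

    quadrants = {
        "embryo_canonical": 0,
        "embryo_non_canonical": 0,
        "maternal_canonical": 0,
        "maternal_non_canonical": 0,
    }
    calls: dict[str, ProbeCall] = {}
    for probes, polarity in bases:
        for p in probes:
            dirs = tuple((g.value, _direction(p, ds)) for g, ds in by_geno.items())
            # evidence: -1 -> canonical, +1 -> non_canonical (flipped in mirror base)
            ev = {}
            for source, ds in (("embryo", stat_het), ("maternal", stat_matnull)):
                d = _direction(p, ds) * polarity
                if d == -1:
                    ev[source] = Label.CANONICAL
                elif d == +1:
                    ev[source] = Label.NON_CANONICAL
            if polarity == +1:
                for source, lab in ev.items():
                    quadrants[f"{source}_{lab.value}"] += 1
            if not ev:
                label, prov = Label.UNCLASSIFIED, frozenset()
            elif len(set(ev.values())) > 1:
                label, prov = Label.REMOVED_CONFLICT, frozenset(ev)
            else:
                label, prov = next(iter(ev.values())), frozenset(ev)
            calls[p] = ProbeCall(p, label, prov, dirs)

    for p in universe - set(calls):
        dirs = tuple((g.value, _direction(p, ds)) for g, ds in by_geno.items())
        calls[p] = ProbeCall(p, Label.UNCLASSIFIED, frozenset(), dirs)

    return TargetClassification(calls=calls, quadrant_counts=quadrants)


def summarize_classification(tc: TargetClassification) -> dict:
    """Label counts, quadrant counts and deduplicated unique totals.

    ``unique_totals`` are the post-conflict-removal deduplicated group sizes:
    each probe counts once regardless of whether one or both STAT genotypes
    supplied its evidence.
    """
    label_counts = Counter(c.label.value for c in tc.calls.values())
    prov_counts = Counter(
        (c.label.value, ",".join(sorted(c.provenance)))
        for c in tc.calls.values()
        if c.label in (Label.CANONICAL, Label.NON_CANONICAL)
    )
    summary = {
        "label_counts": {lab.value: label_counts.get(lab.value, 0) for lab in Label},
        "quadrant_counts": dict(tc.quadrant_counts),
        "unique_totals": {
            "canonical": label_counts.get(Label.CANONICAL.value, 0),
            "non_canonical": label_counts.get(Label.NON_CANONICAL.value, 0),
        },
        "provenance_counts": {
            f"{lab}[{prov}]": n for (lab, prov), n in sorted(prov_counts.items())
        },
    }
    total = sum(summary["label_counts"].values())
    assert total == len(tc.calls), "labels must partition the probe universe"
    return summary
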