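"""Genomic-interval machinery for heterochromatin association.

Probe sets map to genomic loci; a probe counts as heterochromatin-associated
when any of its loci overlaps (by >= 1 bp) any enrichment site from any of
the supplied peak sets — HP1a or Su(var)3-9 binding, or H3K9me3 enrichment —
OR when the probe is annotated as a transposable element, TEs being
characteristically heterochromatic. Coordinates are 0-based half-open (BED
convention); abutting intervals do not overlap; strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .classification import Label, TargetClassification

__all__ = [
    "GenomicInterval",
    "ProbeAnnotation",
    "PeakSet",
    "ContingencyTable",
    "HeterochromatinFlags",
    "read_bed",
    "write_bed",
    "read_probe_annotation",
    "write_probe_annotation",
    "overlaps_any",
    "annotate_heterochromatin",
    "tally_contingency",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ProbeAnnotation:
    """Probe -> genomic loci (possibly none) and transposable-element flag."""

    loci: dict[str, list[GenomicInterval]]
    is_te: dict[str, bool]

    def __post_init__(self) -> None:
        for p in self.loci:
            self.is_te.setdefault(p, False)
        for p in self.is_te:
            self.loci.setdefault(p, [])

    @property
    def probe_ids(self) -> set[str]:
        return set(self.loci)


@dataclass
class PeakSet:
    """Named collection of enrichment-site intervals (one factor/dataset)."""

    name: str
    intervals: list[GenomicInterval]


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Parse a BED3+ file; extra columns ignored, track/browser/# lines skipped."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} must be < end {end}"
                )
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            intervals.append(GenomicInterval(chrom, start, end))
    return PeakSet(name=name or path.stem, intervals=intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.name}\n")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """TSV with columns probe_id, chrom, start, end, is_te; several rows per
    probe allowed; empty chrom marks a probe with no locus."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    loci: dict[str, list[GenomicInterval]] = {}
    is_te: dict[str, bool] = {}
    for row in df.itertuples(index=False):
        pid = str(row.probe_id)
        loci.setdefault(pid, [])
        te = bool(row.is_te) if not isinstance(row.is_te, str) else row.is_te.lower() in ("true", "1")
        is_te[pid] = is_te.get(pid, False) or te
        if isinstance(row.chrom, str) and row.chrom:
            loci[pid].append(GenomicInterval(row.chrom, int(row.start), int(row.end)))
    return ProbeAnnotation(loci=loci, is_te=is_te)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    rows = []
    for pid in sorted(ann.loci):
        ivs = ann.loci[pid]
        te = ann.is_te.get(pid, False)
        if not ivs:
            rows.append((pid, "", "", "", te))
        for iv in ivs:
            rows.append((pid, iv.chrom, iv.start, iv.end, te))
    pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "is_te"]
    ).to_csv(path, sep="\t", index=False)


def _build_trees(peak_sets: list[PeakSet]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for ps in peak_sets:
        for iv in ps.intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlaps_any(locus: GenomicInterval, peak_sets: list[PeakSet] | PeakSet) -> bool:
    """True iff some peak in any set shares >= 1 bp with the locus
    (same chromosome, half-open semantics; union over all provided sets).

    Single-query form: a direct scan over the peak intervals. Bulk
    annotation (annotate_heterochromatin) builds interval trees instead.
    """
    if isinstance(peak_sets, PeakSet):
        peak_sets = [peak_sets]
    return any(
        locus.overlaps(iv) for ps in peak_sets for iv in ps.intervals
    )


@dataclass
class HeterochromatinFlags:
    """Per-probe association flags: peak overlap, TE annotation, and their OR."""

    marker_overlap: dict[str, bool]
    te: dict[str, bool]
    n_missing_annotation: int = 0

    def associated(self, probe: str) -> bool:
        return self.marker_overlap.get(probe, False) or self.te.get(probe, False)


def annotate_heterochromatin(
    tc: TargetClassification,
    ann: ProbeAnnotation,
    peak_sets: list[PeakSet],
) -> HeterochromatinFlags:
    """Flag every classified probe for heterochromatin association.

    marker_overlap(p): any locus of p overlaps any peak across all sets
    (union over factors, "HP1a, Su(var)3-9 and/or H3K9me3"). te(p): the
    probe's TE annotation; TE probes count as associated even without a peak
    overlap. Probes absent from the annotation get both flags False and are
    tallied in ``n_missing_annotation``.
    """
    trees = _build_trees(peak_sets)
    marker: dict[str, bool] = {}
    te: dict[str, bool] = {}
    missing = 0
    for probe in tc.calls:
        if probe not in ann.loci and probe not in ann.is_te:
            marker[probe] = False
            te[probe] = False
            missing += 1
            continue
        hit = False
        for locus in ann.loci.get(probe, []):
            tree = trees.get(locus.chrom)
            if tree is not None and tree.overlap(locus.start, locus.end):
                hit = True
                break
        marker[probe] = hit
        te[probe] = ann.is_te.get(probe, False)
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "%d classified probe(s) lack genomic annotation; counted as "
            "not heterochromatin-associated",
            missing,
        )
    return HeterochromatinFlags(marker_overlap=marker, te=te, n_missing_annotation=missing)


@dataclass
class ContingencyTable:
    """2x2 counts: rows (canonical, non_canonical) x columns (associated, not)."""

    canonical_assoc: int
    canonical_not: int
    non_canonical_assoc: int
    non_canonical_not: int

    def __post_init__(self) -> None:
        if min(
            self.canonical_assoc,
            self.canonical_not,
            self.non_canonical_assoc,
            self.non_canonical_not,
        ) < 0:
            raise ValueError("contingency counts must be nonnegative")

    def as_list(self) -> list[list[int]]:
        return [
            [self.canonical_assoc, self.canonical_not],
            [self.non_canonical_assoc, self.non_canonical_not],
        ]


def _group_fractions(
    probes: set[str], flags: HeterochromatinFlags
) -> dict[str, Fraction]:
    n = len(probes)
    marker = sum(flags.marker_overlap.get(p, False) for p in probes)
    te = sum(flags.te.get(p, False) for p in probes)
    assoc = sum(flags.associated(p) for p in probes)
    return {
        "marker_overlap": Fraction(marker, n),
        "te": Fraction(te, n),
        "combined": Fraction(assoc, n),
    }


def tally_contingency(
    tc: TargetClassification, flags: HeterochromatinFlags
) -> tuple[ContingencyTable, dict[str, dict[str, Fraction]]]:
    """Contingency table over the canonical/non-canonical groups plus
    per-group association fractions (marker-only, TE-only, combined) as exact
    rationals. Percent display at 1 decimal is left to the caller; fractions
    here are the exact counts over group size."""
    canonical = tc.probes_with_label(Label.CANONICAL)
    non_canonical = tc.probes_with_label(Label.NON_CANONICAL)
    if not canonical or not non_canonical:
        raise ValueError(
            "both canonical and non-canonical groups must be nonempty "
            f"(got {len(canonical)} and {len(non_canonical)})"
        )
    for p in canonical | non_canonical:
        if p not in flags.marker_overlap:
            raise ValueError(f"no heterochromatin flags for classified probe {p!r}")
    can_assoc = sum(flags.associated(p) for p in canonical)
    non_assoc = sum(flags.associated(p) for p in non_canonical)
    table = ContingencyTable(
        canonical_assoc=can_assoc,
        canonical_not=len(canonical) - can_assoc,
        non_canonical_assoc=non_assoc,
        non_canonical_not=len(non_canonical) - non_assoc,
    )
    fractions = {
        "canonical": _group_fractions(canonical, flags),
        "non_canonical": _group_fractions(non_canonical, flags),
    }
    return table, fractions
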