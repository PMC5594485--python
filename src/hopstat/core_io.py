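"""Domain types and I/O for the expression pipeline.

The raw input is a MAS5-style expression summary: a probe-set x sample grid of
linear-scale signal intensities together with per-cell Present/Marginal/Absent
(P/M/A) detection calls, plus a sample sheet assigning each array to a
genotype, embryo collection stage and replicate number.

Genotypes follow the Drosophila JAK/STAT mutant panel: wildtype (w1118),
JAK gain-of-function (hop[Tum-l]/+), JAK loss-of-function (hop[3]/+), STAT
loss-of-function heterozygote (Stat92E[06346]/+) and the STAT maternal-null
(Stat92E[mat-], germline-clone derived). The maternal-null embryos are
collected at 1-2 h after egg laying and compared against stage-matched
wildtype; all other genotypes are 0-12 h collections with their own wildtype
controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

__all__ = [
    "Genotype",
    "Stage",
    "CONTROL_PREFIX",
    "SampleMetadata",
    "ExpressionMatrix",
    "ReportBundle",
    "read_metadata",
    "read_expression_table",
    "write_expression_table",
    "filter_probe_sets",
    "write_report",
    "read_report",
]

#: Default id prefix marking array control probe sets (Affymetrix convention).
CONTROL_PREFIX = "AFFX"

VALID_CALLS = frozenset({"P", "M", "A"})


class Genotype(str, Enum):
    WT = "WT"
    JAK_GOF = "JAK_GOF"
    JAK_LOF = "JAK_LOF"
    STAT_HET = "STAT_HET"
    STAT_MATNULL = "STAT_MATNULL"


class Stage(str, Enum):
    E0_12 = "E0_12"  # 0-12 h embryo collection
    E1_2 = "E1_2"    # 1-2 h embryo collection (maternal-null design)


#: Stage at which each mutant genotype is collected, hence which wildtype
#: samples serve as its control.
MUTANT_STAGE: dict[Genotype, Stage] = {
    Genotype.JAK_GOF: Stage.E0_12,
    Genotype.JAK_LOF: Stage.E0_12,
    Genotype.STAT_HET: Stage.E0_12,
    Genotype.STAT_MATNULL: Stage.E1_2,
}


@dataclass(frozen=True)
class SampleMetadata:
    """One array sample: id, genotype, collection stage, replicate index."""

    sample_id: str
    genotype: Genotype
    stage: Stage
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be >= 1, "
                f"got {self.replicate}"
            )
        if self.genotype is not Genotype.WT:
            expected = MUTANT_STAGE[self.genotype]
            if self.stage is not expected:
                raise ValueError(
                    f"sample {self.sample_id!r}: genotype {self.genotype.value} "
                    f"is collected at stage {expected.value}, got {self.stage.value}"
                )


def _validate_samples(samples: Sequence[SampleMetadata]) -> None:
    ids = [s.sample_id for s in samples]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
    wt_stages = {s.stage for s in samples if s.genotype is Genotype.WT}
    for s in samples:
        if s.genotype is Genotype.WT:
            continue
        need = MUTANT_STAGE[s.genotype]
        if need not in wt_stages:
            raise ValueError(
                f"genotype {s.genotype.value} requires a stage-matched WT "
                f"control at {need.value}, but no WT/{need.value} sample exists"
            )


@dataclass
class ExpressionMatrix:
    """Probe-set x sample intensities (linear scale) with P/M/A calls.

    ``intensity`` and ``calls`` are DataFrames with identical index (probe
    ids) and columns (sample ids, ordered as in ``samples``).
    """

    intensity: pd.DataFrame
    calls: pd.DataFrame
    samples: list[SampleMetadata]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _validate_samples(self.samples)
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.intensity.columns) != sample_ids:
            raise ValueError("intensity columns do not match sample metadata order")
        if self.intensity.shape != self.calls.shape or not self.intensity.index.equals(
            self.calls.index
        ) or list(self.calls.columns) != sample_ids:
            raise ValueError("intensity and call grids must have identical shape")
        if self.intensity.index.has_duplicates:
            dupes = self.intensity.index[self.intensity.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids: {sorted(map(str, dupes))}")
        if self.intensity.isna().any().any():
            raise ValueError("intensity grid contains missing cells")
        if (self.intensity.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")
        bad = set(self.calls.to_numpy().ravel()) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid detection calls: {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensity.index)

    def sample_ids(
        self, genotype: Genotype | None = None, stage: Stage | None = None
    ) -> list[str]:
        """Sample ids, optionally restricted to a genotype and/or stage."""
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype is not genotype:
                continue
            if stage is not None and s.stage is not stage:
                continue
            out.append(s.sample_id)
        return out

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            intensity=self.intensity.loc[list(probe_ids)].copy(),
            calls=self.calls.loc[list(probe_ids)].copy(),
            samples=list(self.samples),
        )


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a sample sheet (TSV/CSV: sample_id, genotype, stage, replicate)."""
    df = _read_table(path)
    required = {"sample_id", "genotype", "stage", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path}: missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        try:
            geno = Genotype(row["genotype"])
        except ValueError:
            raise ValueError(
                f"metadata {path}: unknown genotype {row['genotype']!r} "
                f"for sample {row['sample_id']!r}"
            ) from None
        try:
            stage = Stage(row["stage"])
        except ValueError:
            raise ValueError(
                f"metadata {path}: unknown stage {row['stage']!r} "
                f"for sample {row['sample_id']!r}"
            ) from None
        samples.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                genotype=geno,
                stage=stage,
                replicate=int(row["replicate"]),
            )
        )
    _validate_samples(samples)
    return samples


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_expression_table(
    path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    """Read a probe x sample expression table plus its sample sheet.

    The expression table has a ``probe_id`` column, one intensity column per
    sample named ``<sample_id>``, and one call column named
    ``<sample_id>_call``. Sample order follows the metadata file.
    """
    samples = read_metadata(metadata_path)
    df = _read_table(path)
    if "probe_id" not in df.columns:
        raise ValueError(f"expression table {path}: missing 'probe_id' column")

    sample_ids = [s.sample_id for s in samples]
    known = set(sample_ids) | {f"{sid}_call" for sid in sample_ids} | {"probe_id"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        stems = sorted({c.removesuffix("_call") for c in unknown})
        raise ValueError(
            f"expression table {path}: sample(s) {stems} not present in metadata"
        )
    for sid in sample_ids:
        for col in (sid, f"{sid}_call"):
            if col not in df.columns:
                raise ValueError(f"expression table {path}: missing column {col!r}")

    probe_ids = df["probe_id"].tolist()
    dupes = sorted({p for p in probe_ids if probe_ids.count(p) > 1})
    if dupes:
        raise ValueError(f"expression table {path}: duplicate probe id(s) {dupes}")

    intensity = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"))
    calls = pd.DataFrame(index=intensity.index)
    for sid in sample_ids:
        try:
            intensity[sid] = pd.to_numeric(df[sid].to_numpy(), errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[sid], errors="coerce")
            rows = df.loc[bad.isna() & df[sid].notna(), "probe_id"].tolist()
            raise ValueError(
                f"expression table {path}: non-numeric intensity in column "
                f"{sid!r}, row(s) {rows}"
            ) from None
        calls[sid] = df[f"{sid}_call"].to_numpy()
    return ExpressionMatrix(intensity=intensity, calls=calls, samples=samples)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    """Write a matrix and its sample sheet in the format read_expression_table reads."""
    path, metadata_path = Path(path), Path(metadata_path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = pd.DataFrame({"probe_id": matrix.probe_ids})
    for s in matrix.samples:
        out[s.sample_id] = matrix.intensity[s.sample_id].to_numpy()
        out[f"{s.sample_id}_call"] = matrix.calls[s.sample_id].to_numpy()
    out.to_csv(path, sep=sep, index=False)

    msep = "," if metadata_path.suffix.lower() == ".csv" else "\t"
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in matrix.samples],
            "genotype": [s.genotype.value for s in matrix.samples],
            "stage": [s.stage.value for s in matrix.samples],
            "replicate": [s.replicate for s in matrix.samples],
        }
    )
    meta.to_csv(metadata_path, sep=msep, index=False)


def filter_probe_sets(
    matrix: ExpressionMatrix,
    mutant: Genotype | str,
    control_prefix: str = CONTROL_PREFIX,
) -> ExpressionMatrix:
    """Remove control probe sets and all-Absent probes for one mutant genotype.

    A probe is dropped when (a) its id starts with ``control_prefix``, or
    (b) its detection call is 'A' in every stage-matched wildtype sample AND
    every sample of ``mutant``. A single Present or Marginal call anywhere in
    those samples retains the probe. Probe order is preserved. The filter for
    a genotype looks only at that genotype's samples and its stage-matched
    wildtype controls, so different genotypes may retain different universes.
    """
    mutant = Genotype(mutant)
    if mutant is Genotype.WT:
        raise ValueError("filter_probe_sets expects a mutant genotype, not WT")
    stage = MUTANT_STAGE[mutant]
    mut_ids = matrix.sample_ids(mutant)
    wt_ids = matrix.sample_ids(Genotype.WT, stage)
    if not mut_ids:
        raise ValueError(f"matrix contains no {mutant.value} samples")
    if not wt_ids:
        raise ValueError(
            f"matrix contains no stage-matched WT ({stage.value}) samples "
            f"for {mutant.value}"
        )
    relevant = matrix.calls[wt_ids + mut_ids]
    all_absent = (relevant == "A").all(axis=1)
    is_control = matrix.intensity.index.str.startswith(control_prefix)
    keep = ~(all_absent.to_numpy() | is_control)
    kept = [p for p, k in zip(matrix.probe_ids, keep) if k]
    if not kept:
        import warnings

        warnings.warn(
            f"filtering for {mutant.value} removed every probe", stacklevel=2
        )
    return matrix.subset_probes(kept)


# ---------------------------------------------------------------------------
# Run report

_REPORT_FIELDS = (
    "parameters",
    "directional_counts",
    "venn_summaries",
    "classification_counts",
    "quadrant_counts",
    "heterochromatin_fractions",
    "contingency_table",
    "odds_ratio",
    "p_two_tailed",
)


@dataclass
class ReportBundle:
    """Structured results of a full pipeline run.

    Fractions are carried as exact rationals internally and serialized as
    "num/den" strings plus floats, so a report round-trips losslessly.
    """

    parameters: dict[str, Any]
    directional_counts: dict[str, dict[str, int]]
    venn_summaries: list[dict[str, Any]]
    classification_counts: dict[str, int]
    quadrant_counts: dict[str, int]
    heterochromatin_fractions: dict[str, dict[str, str]]
    contingency_table: list[list[int]]
    odds_ratio: float
    p_two_tailed: float

    def validate(self) -> None:
        (a, b), (c, d) = self.contingency_table
        if min(a, b, c, d) < 0:
            raise ValueError("contingency table entries must be nonnegative")
        sizes = self.classification_counts
        if "canonical" in sizes and a + b != sizes["canonical"]:
            raise ValueError(
                "contingency row margin does not equal canonical group size"
            )
        if "non_canonical" in sizes and c + d != sizes["non_canonical"]:
            raise ValueError(
                "contingency row margin does not equal non_canonical group size"
            )
        for group, fracs in self.heterochromatin_fractions.items():
            for key, val in fracs.items():
                frac = Fraction(val)
                if not 0 <= frac <= 1:
                    raise ValueError(
                        f"fraction {group}/{key} = {val} outside [0, 1]"
                    )
        if not (0.0 < self.p_two_tailed <= 1.0):
            raise ValueError(f"p-value {self.p_two_tailed} outside (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return {name: getattr(self, name) for name in _REPORT_FIELDS}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ReportBundle":
        missing = [name for name in _REPORT_FIELDS if name not in data]
        if missing:
            raise ValueError(f"report missing required field(s): {missing}")
        return cls(**{name: data[name] for name in _REPORT_FIELDS})


def write_report(bundle: ReportBundle, path: str | Path) -> None:
    """Write a validated ReportBundle as JSON with deterministic key order."""
    bundle.validate()
    with open(path, "w") as fh:
        json.dump(bundle.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> ReportBundle:
    with open(path) as fh:
        bundle = ReportBundle.from_dict(json.load(fh))
    bundle.validate()
    return bundle
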