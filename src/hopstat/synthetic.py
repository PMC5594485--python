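"""Synthetic study generator with planted ground truth.

Emulates the full input bundle of the mutant-panel experiment: a MAS5-style
expression matrix with Present/Absent calls across five genotypes with
stage-matched wildtype controls, a probe -> locus annotation with
transposable-element flags, and heterochromatin peak files — all derived
from a planted truth table so every pipeline stage can be checked against
known answers.

Planted probe classes and their per-genotype direction signatures:

=============  ========  ========  =========  =============
class          JAK_GOF   JAK_LOF   STAT_HET   STAT_MATNULL
=============  ========  ========  =========  =============
canonical      up        down      down       down
non_canonical  up        down      up         up
conflict       up        down      opposite STAT directions
null           —         —         —          —
control        — (id carries the array-control prefix)
all_absent     — (signal forced below the detection threshold)
=============  ========  ========  =========  =============

Intensities are lognormal: per-probe baseline on the log2 scale, plus the
planted effect in mutant samples, plus Gaussian per-replicate noise on the
log2 scale (the standard microarray error model). Detection calls are a
pure intensity threshold; marginal (M) calls can be enabled via a band
above the threshold.

Heterochromatin association is planted per class at configurable rates
(defaults mirror the observed canonical/non-canonical rates, 0.271 and
0.381). Loci are placed in disjoint genome slots so that planted-associated
probes are guaranteed a peak overlap, planted-unassociated probes are
guaranteed none, and decoy peaks in unassigned slots exercise the negative
path of the overlap logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromatin import GenomicInterval, PeakSet, ProbeAnnotation
from .core_io import (
    CONTROL_PREFIX,
    MUTANT_STAGE,
    ExpressionMatrix,
    Genotype,
    SampleMetadata,
    Stage,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_truth",
    "simulate_expression",
    "simulate_annotation_and_peaks",
    "simulate_study",
    "CLASSES",
    "DIRECTION_SIGNATURES",
]

CLASSES = ("canonical", "non_canonical", "conflict", "null", "control", "all_absent")

#: per-class (JAK_GOF, JAK_LOF, STAT_HET, STAT_MATNULL) direction signature;
#: conflict orientation is resolved per probe (see generate_truth).
DIRECTION_SIGNATURES: dict[str, tuple[int, int, int, int]] = {
    "canonical": (1, -1, -1, -1),
    "non_canonical": (1, -1, 1, 1),
    "null": (0, 0, 0, 0),
    "control": (0, 0, 0, 0),
    "all_absent": (0, 0, 0, 0),
}

MUTANTS = (Genotype.JAK_GOF, Genotype.JAK_LOF, Genotype.STAT_HET, Genotype.STAT_MATNULL)

_DEFAULT_PROPORTIONS = {
    "canonical": 0.10,
    "non_canonical": 0.15,
    "conflict": 0.03,
    "null": 0.57,
    "control": 0.05,
    "all_absent": 0.10,
}

# fly-like major chromosome arms, scaled lengths
_DEFAULT_GENOME = {"chr2L": 23_000_000, "chr2R": 25_000_000, "chr3L": 28_000_000}

PEAK_SET_NAMES = ("HP1a", "Su(var)3-9", "H3K9me3")


@dataclass
class SimulationConfig:
    n_probes: int = 2000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    effect_log2: float = 2.0       # planted |log2 fold change|
    noise_sd_log2: float = 0.3     # per-replicate log2-scale noise SD
    replicates: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    absent_call_threshold: float = 16.0  # linear intensity below which call = A
    marginal_band: float = 0.0     # >0 enables M calls in [thr, thr*(1+band))
    het_rate_canonical: float = 0.271
    het_rate_non_canonical: float = 0.381
    het_rate_other: float = 0.10
    te_fraction_of_het: float = 0.06
    genome: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_GENOME))
    locus_length: int = 2000
    slot_length: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        for name in (
            "het_rate_canonical",
            "het_rate_non_canonical",
            "het_rate_other",
            "te_fraction_of_het",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_log2", "absent_call_threshold", "baseline_log2_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.locus_length + 2 >= self.slot_length:
            raise ValueError("slot_length must exceed locus_length + 2")


@dataclass
class TruthTable:
    """Planted per-probe ground truth: class, per-genotype direction,
    heterochromatin association and TE flag."""

    df: pd.DataFrame  # index probe_id; columns: klass, dir_<genotype>..., het, te

    def probes_in_class(self, klass: str) -> set[str]:
        return set(self.df.index[self.df["klass"] == klass])

    def direction(self, probe: str, genotype: Genotype) -> int:
        return int(self.df.loc[probe, f"dir_{genotype.value}"])


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment so counts sum to n_probes exactly."""
    props = {k: config.class_proportions.get(k, 0.0) for k in CLASSES}
    raw = {k: config.n_probes * p for k, p in props.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = config.n_probes - sum(counts.values())
    for k in sorted(CLASSES, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


def generate_truth(config: SimulationConfig) -> TruthTable:
    """Deterministically (given config.seed) plant classes, directions and
    heterochromatin flags for every probe."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config)

    rows = []
    idx = 0
    het_rates = {
        "canonical": config.het_rate_canonical,
        "non_canonical": config.het_rate_non_canonical,
    }
    for klass in CLASSES:
        for j in range(counts[klass]):
            if klass == "control":
                pid = f"{CONTROL_PREFIX}-ctrl-{idx:05d}"
            else:
                pid = f"probe_{idx:05d}"
            if klass == "conflict":
                # alternate orientation deterministically: even j -> STAT_HET
                # down / MATNULL up, odd j -> the reverse
                dirs = (1, -1, -1, 1) if j % 2 == 0 else (1, -1, 1, -1)
            else:
                dirs = DIRECTION_SIGNATURES[klass]
            rate = het_rates.get(klass, config.het_rate_other)
            het = bool(rng.random() < rate)
            te = bool(het and rng.random() < config.te_fraction_of_het)
            rows.append((pid, klass, *dirs, het, te))
            idx += 1
    df = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "klass",
            *(f"dir_{g.value}" for g in MUTANTS),
            "het",
            "te",
        ],
    ).set_index("probe_id")
    return TruthTable(df=df)


def _sample_sheet(config: SimulationConfig) -> list[SampleMetadata]:
    samples = []
    for stage in (Stage.E0_12, Stage.E1_2):
        for r in range(1, config.replicates + 1):
            samples.append(
                SampleMetadata(f"WT_{stage.value}_r{r}", Genotype.WT, stage, r)
            )
    for g in MUTANTS:
        stage = MUTANT_STAGE[g]
        for r in range(1, config.replicates + 1):
            samples.append(SampleMetadata(f"{g.value}_r{r}", g, stage, r))
    return samples


def simulate_expression(truth: TruthTable, config: SimulationConfig) -> ExpressionMatrix:
    """Lognormal intensities with planted effects; threshold detection calls.

    Probes of the ``all_absent`` class are forced below the detection
    threshold in every sample (uniform in (0, threshold/2)), so the
    all-Absent filter has guaranteed work to do.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples = _sample_sheet(config)
    n = len(truth.df)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    # expressed probes sit above the detection floor even after the planted
    # downregulation, so a planted target is never lost to the all-Absent filter
    floor = math.log2(config.absent_call_threshold) + config.effect_log2 + 0.5
    baseline = np.maximum(baseline, floor)

    dirs = {g: truth.df[f"dir_{g.value}"].to_numpy() for g in MUTANTS}
    cols = {}
    for s in samples:
        effect = (
            np.zeros(n)
            if s.genotype is Genotype.WT
            else dirs[s.genotype] * config.effect_log2
        )
        noise = (
            rng.normal(0.0, config.noise_sd_log2, size=n)
            if config.noise_sd_log2 > 0
            else np.zeros(n)
        )
        cols[s.sample_id] = np.exp2(baseline + effect + noise)

    intensity = pd.DataFrame(cols, index=truth.df.index.copy())
    absent_mask = (truth.df["klass"] == "all_absent").to_numpy()
    if absent_mask.any():
        k = int(absent_mask.sum())
        for sid in intensity.columns:
            intensity.loc[absent_mask, sid] = rng.uniform(
                0.0, config.absent_call_threshold / 2.0, size=k
            )

    thr = config.absent_call_threshold
    calls = pd.DataFrame("P", index=intensity.index, columns=intensity.columns)
    calls = calls.mask(intensity < thr, "A")
    if config.marginal_band > 0:
        in_band = (intensity >= thr) & (intensity < thr * (1.0 + config.marginal_band))
        calls = calls.mask(in_band, "M")
    return ExpressionMatrix(intensity=intensity, calls=calls, samples=samples)


def simulate_annotation_and_peaks(
    truth: TruthTable, config: SimulationConfig
) -> tuple[ProbeAnnotation, list[PeakSet]]:
    """Place one locus per probe in disjoint genome slots; plant peaks.

    Probes with planted association and no TE flag get one peak overlapping
    their locus, assigned round-robin across the named peak sets. TE probes
    get the flag and no guaranteed peak. Decoy peaks go in slots assigned to
    no probe so the overlap logic is exercised negatively. Because slots are
    disjoint, a planted-unassociated probe can never accidentally overlap a
    peak.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(truth.df)
    n_decoys = max(20, n // 10)

    slots = []
    for chrom in sorted(config.genome):
        length = config.genome[chrom]
        for start in range(0, length - config.slot_length + 1, config.slot_length):
            slots.append((chrom, start))
    if len(slots) < n + n_decoys:
        raise ValueError(
            f"genome too small: {len(slots)} slots of {config.slot_length} bp "
            f"but {n} probes + {n_decoys} decoy peaks required"
        )
    order = rng.permutation(len(slots))

    loci: dict[str, list[GenomicInterval]] = {}
    is_te: dict[str, bool] = {}
    planted: list[list[GenomicInterval]] = [[] for _ in PEAK_SET_NAMES]
    peak_idx = 0
    margin = 1  # keep >= 1 bp clear of slot edges so slots never touch
    for i, (pid, row) in enumerate(truth.df.iterrows()):
        chrom, slot_start = slots[order[i]]
        room = config.slot_length - config.locus_length - 2 * margin
        offset = int(rng.integers(0, room + 1))
        start = slot_start + margin + offset
        locus = GenomicInterval(chrom, start, start + config.locus_length)
        loci[pid] = [locus]
        is_te[pid] = bool(row["te"])
        if row["het"] and not row["te"]:
            # peak anchored inside the locus: overlap guaranteed
            p_start = start + int(rng.integers(0, config.locus_length // 2))
            p_end = min(p_start + 1000, slot_start + config.slot_length - margin)
            planted[peak_idx % len(PEAK_SET_NAMES)].append(
                GenomicInterval(chrom, p_start, p_end)
            )
            peak_idx += 1
    for j in range(n_decoys):
        chrom, slot_start = slots[order[n + j]]
        p_start = slot_start + margin + int(rng.integers(0, config.slot_length // 2))
        planted[j % len(PEAK_SET_NAMES)].append(
            GenomicInterval(chrom, p_start, p_start + 1000)
        )

    ann = ProbeAnnotation(loci=loci, is_te=is_te)
    peak_sets = [
        PeakSet(name=name, intervals=sorted(ivs))
        for name, ivs in zip(PEAK_SET_NAMES, planted)
    ]
    return ann, peak_sets


def simulate_study(
    config: SimulationConfig | None = None, **overrides
) -> tuple[TruthTable, ExpressionMatrix, ProbeAnnotation, list[PeakSet]]:
    """One-call generation of a complete synthetic study."""
    config = replace(config or SimulationConfig(), **overrides)
    truth = generate_truth(config)
    matrix = simulate_expression(truth, config)
    ann, peaks = simulate_annotation_and_peaks(truth, config)
    return truth, matrix, ann, peaks
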