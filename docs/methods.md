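# Methods

## The classification model

The pipeline infers putative canonical vs non-canonical JAK/STAT
transcriptional targets from direction-of-change concordance across four
mutant genotypes, each compared to stage-matched wildtype:

| genotype       | perturbation                      | collection stage |
|----------------|-----------------------------------|------------------|
| `JAK_GOF`      | JAK gain-of-function (*hop*)      | 0–12 h (`E0_12`) |
| `JAK_LOF`      | JAK loss-of-function heterozygote | 0–12 h           |
| `STAT_HET`     | STAT loss-of-function heterozygote| 0–12 h           |
| `STAT_MATNULL` | STAT maternal-null (germline clones) | 1–2 h (`E1_2`) |

The base requirement is JAK-GOF up AND JAK-LOF down: expression that tracks
pathway activity. Within that base set, a STAT-loss genotype moving the
probe *down* is evidence the target needs STAT transcriptionally
(canonical); moving it *up* is evidence the target is de-repressed when
STAT-maintained heterochromatin is lost (non-canonical). The heterozygote
supplies "embryo" evidence and the maternal-null "maternal" evidence. A
probe whose two STAT sources disagree is removed as a conflict; agreement
or a single source labels it with that provenance; no STAT evidence leaves
it unclassified. Removal precedes the union that yields the deduplicated
unique group totals — this ordering makes the two groups disjoint and
well-defined, which the presentation of per-genotype quadrant counts alone
does not pin down; both the quadrant counts (per STAT source, before
removal) and the deduplicated totals are reported rather than asserting one
reconciliation between them. A mirror base (GOF down ∩ LOF up) with flipped
evidence polarity is available behind a flag and off by default, since only
the stated direction is biologically motivated by the pathway logic.

## Differential expression

Fold changes are computed on MAS5-style linear intensities: replicate means
are taken on the linear scale, then log2 of the mean ratio, with a
pseudocount ε (default 1.0 signal unit, the smallest meaningful MAS5
increment) added to both numerator and denominator so all-zero probes stay
finite; ε = 0 is available for exact arithmetic on constructed inputs.
Averaging before the log matches how fold change of summarized array signal
is conventionally reported. The significance criterion is a pure threshold:
|log2 FC| ≥ cutoff (default 1.0, i.e. 2-fold), inclusive at the boundary so
behaviour at exactly the cutoff is deterministic. No moderated statistic or
multiple-testing correction is applied — the criterion is deliberately the
simple one. The top-decile percentile diagnostic (10th/90th percentile of
log2 fold changes, pooled across genotypes by default, per-genotype via
flag) reports where the bulk of regulation sits relative to the 2-fold
line; it gates nothing.

Probe filtering is per genotype: control probe sets (configurable id
prefix, default `AFFX`, the Affymetrix convention) and probes called `A` in
*every* stage-matched wildtype and mutant sample are dropped. `M`
(marginal) counts as detected — the strictest reading of "all Absent".
Because filtering depends only on the genotype's own samples and its
controls, genotype universes may differ; downstream set algebra operates on
probe identifiers, so this is safe.

## Heterochromatin association and the exact test

Coordinates are 0-based half-open throughout (BED convention): intervals
sharing only a boundary point do not overlap. A probe is
heterochromatin-associated iff any of its annotated loci overlaps ≥ 1 bp
with any enrichment site across all supplied peak sets (union over HP1a,
Su(var)3-9, H3K9me3 factors and datasets) OR the probe maps to a
transposable element — TEs are characteristically heterochromatic and
count as associated with no peak requirement. Probes lacking annotation are
conservatively non-associated and their count is logged. Strand is ignored.

`overlaps_any` answers a single locus query by direct scan; bulk annotation
builds per-chromosome interval trees (the `intervaltree` package). The two
routes are cross-checked against each other and against an all-pairs oracle
in the tests.

The 2×2 table (group × associated) is tested with a two-tailed Fisher exact
test implemented by full hypergeometric enumeration: margins fixed, point
probabilities via log-factorial (`gammaln`) accumulation, p = sum of
probabilities of all tables no more probable than the observed one. This
minimum-likelihood tail convention is what mainstream statistical software
uses; a relative tolerance of 1 + 10⁻⁷ absorbs floating-point ties. The
implementation is validated against an exact integer-arithmetic enumerator
on every table with total ≤ 40, and against `scipy.stats.fisher_exact` on
random tables. The odds ratio is (a·d)/(b·c) with +∞ / 0 conventions for a
single vanishing diagonal product and an error when both vanish.

`recover_count_from_percent` brute-forces the unique integer count whose
percentage of the group size rounds (half away from zero, typical
manuscript rounding) to a printed one-decimal percent, and refuses
inconsistent or ambiguous inputs, listing the candidates in the ambiguous
case. This is what lets printed summary tables be re-checked at the count
level — e.g. a 25.6% marker-overlap subgroup and a 1.6% TE subgroup of 258
sum to 66 + 4 = 70 = 27.1%, not the naive 25.6 + 1.6 = 27.2%.

## Clustering

Profiles (per-genotype log2 fold changes of differentially regulated
probes, or transposed to cluster genotypes) are compared by Pearson
correlation distance d = 1 − r and agglomerated with complete linkage. The
agglomeration is an explicit O(n³) loop so the tie-break is fully
specified: equally distant cluster pairs merge in lexicographic order of
their smallest leaf indices, making output reproducible under reordering.
Complete linkage is monotone, so merge heights never decrease. Output is
the merge table plus leaf order for heatmap consumers; no rendering. The
probe subset clustered is the union of all genotypes' up/down sets — an
interpretation, since "differentially regulated probe sets" does not name a
genotype.

## Synthetic studies

The generator emulates the study conditions end to end. Defaults:

| parameter | default | rationale |
|---|---|---|
| `n_probes` | 2000 | enough probes for stable rate estimates, small enough for fast suites |
| class proportions | canonical .10, non-canonical .15, conflict .03, null .57, control .05, all-absent .10 | minority planted classes over a null majority; every filter path populated |
| `effect_log2` | 2.0 | planted 4-fold effects, comfortably past the 2-fold cutoff |
| `noise_sd_log2` | 0.3 | typical replicate-level log-scale array noise |
| `replicates` | 3 | standard minimal replication for this design |
| baseline log2 | N(8, 1.5), floored | MAS5-scale signal around 256 units |
| `absent_call_threshold` | 16 | detection floor (2⁴ linear units) |
| het rates | canonical 0.271, non-canonical 0.381, others 0.10 | observed group rates; a low background for non-targets |
| `te_fraction_of_het` | 0.06 | TE share of associated probes in both observed groups (≈ 4/70, 9/156) |
| genome | 3 arms, 23/25/28 Mb | fly-like arm lengths |

Intensities are lognormal — per-probe log2 baseline plus the planted
per-genotype effect plus Gaussian log2 noise — the standard multiplicative
microarray error model. Baselines are floored at the detection threshold
plus the planted effect (plus 0.5), so an expressed probe is never lost to
the all-Absent filter merely because its baseline was drawn near the
detection floor; `all_absent`-class probes are instead forced below the
threshold in every sample. Detection calls are a pure intensity threshold
(no `M` by default; a marginal band is available behind a flag). Conflict
probes alternate their STAT orientation deterministically so zero-noise
runs are exactly reproducible.

Loci are placed in disjoint genome slots (10 kb, ≥ 1 bp apart): an
associated non-TE probe gets one peak anchored inside its locus, TE probes
get the flag and no guaranteed peak, and decoy peaks occupy unassigned
slots. Disjointness guarantees planted-unassociated probes never overlap a
peak, so ground truth is exact. The generator is bitwise deterministic
given its seed.

What the generator does **not** emulate: probe-level cross-hybridization,
batch or chip effects, MAS5's actual signal/call computation, correlated
noise between genotypes, multi-locus probes, or realistic genomic
clustering of heterochromatin domains. Passing tests therefore demonstrate
the correctness of the pipeline's logic under a clean generative model, not
robustness to real-array artefacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the end-to-end recovery at
2000 probes × 10 seeds, the power check at 200 Monte-Carlo replicates of
the 258/409 configuration, the exact-test oracle exhaustively to table
total 40, and the overlap oracle at 100 random configurations up to
500 × 500 intervals — sizes chosen to estimate each rate stably while
keeping the default suite fast. Exact rationals (`fractions.Fraction`)
carry group fractions through reports so round-tripping is lossless;
percent display rounds half away from zero at one decimal. Degenerate
inputs fail loudly: zero margins for the exact test, zero-variance profiles
for correlation distance, empty groups for the tally, inconsistent or
ambiguous printed percents for count recovery.

## Known limitations

* The observed quadrant counts (221/371/66/66) and unique totals (258/409)
  of the original arrays are not reproducible without the raw data; the
  pipeline reports these surfaces on any input and the synthetic suite
  validates the rules that generate them, but no equality on the original
  numbers is asserted.
* The per-probe locus annotation is an input; no array-annotation build is
  bundled.
* The Fisher tail convention of the software originally used for the
  published p-value is unknown; agreement is checked at the printed
  three-decimal precision.
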