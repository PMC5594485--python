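"""BED ingestion, half-open interval overlap and heterochromatin tallies."""

from fractions import Fraction

import numpy as np
import pytest

from hopstat import (
    ContingencyTable,
    Genotype,
    GenomicInterval,
    Label,
    PeakSet,
    ProbeAnnotation,
    annotate_heterochromatin,
    classify_targets,
    overlaps_any,
    read_bed,
    read_probe_annotation,
    tally_contingency,
    write_probe_annotation,
)
from hopstat.chromatin import HeterochromatinFlags

from conftest import dirsets


def _tc(canonical=(), non_canonical=()):
    """Classification with prescribed group membership, built from dirsets."""
    can, non = list(canonical), list(non_canonical)
    return classify_targets(
        dirsets(Genotype.JAK_GOF, up=can + non),
        dirsets(Genotype.JAK_LOF, down=can + non),
        dirsets(Genotype.STAT_HET, up=non, down=can),
        dirsets(Genotype.STAT_MATNULL),
    )


class TestReadBed:
    def test_parses_first_three_columns(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=demo\n# comment\nchr2L\t100\t200\tname\t0\t+\n")
        ps = read_bed(p)
        assert ps.intervals == [GenomicInterval("chr2L", 100, 200)]

    def test_inverted_interval_reported_with_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t200\nchr2L\t200\t100\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t1.5e3\t2000\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_bed(p)


class TestOverlapsAny:
    peak = PeakSet("HP1a", [GenomicInterval("chr2L", 150, 300)])

    def test_positive_overlap(self):
        assert overlaps_any(GenomicInterval("chr2L", 100, 200), self.peak)

    def test_half_open_abutment_does_not_overlap(self):
        abut = PeakSet("x", [GenomicInterval("chr2L", 200, 300)])
        assert not overlaps_any(GenomicInterval("chr2L", 100, 200), abut)

    def test_chromosome_mismatch(self):
        other = PeakSet("x", [GenomicInterval("chr3R", 100, 200)])
        assert not overlaps_any(GenomicInterval("chr2L", 100, 200), other)

    def test_union_over_peak_sets(self):
        empty = PeakSet("a", [])
        assert overlaps_any(GenomicInterval("chr2L", 100, 200), [empty, self.peak])

    def test_agrees_with_all_pairs_scan(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n, m = rng.integers(1, 80, size=2)
            loci = [
                GenomicInterval("c", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 5000, n), rng.integers(1, 300, n))
            ]
            peaks = PeakSet("p", [
                GenomicInterval("c", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 5000, m), rng.integers(1, 300, m))
            ])
            for locus in loci:
                brute = any(locus.overlaps(iv) for iv in peaks.intervals)
                assert overlaps_any(locus, peaks) == brute


class TestAnnotateHeterochromatin:
    def test_te_probe_without_locus_is_associated(self):
        tc = _tc(canonical=["p"], non_canonical=["q"])
        ann = ProbeAnnotation(loci={"p": [], "q": []}, is_te={"p": True, "q": False})
        flags = annotate_heterochromatin(tc, ann, [PeakSet("HP1a", [])])
        assert flags.associated("p") and not flags.associated("q")

    def test_peak_overlap_associates(self):
        tc = _tc(canonical=["p"], non_canonical=["q"])
        ann = ProbeAnnotation(
            loci={"p": [GenomicInterval("c", 0, 100)], "q": [GenomicInterval("c", 500, 600)]},
            is_te={},
        )
        flags = annotate_heterochromatin(
            tc, ann, [PeakSet("H3K9me3", [GenomicInterval("c", 50, 120)])]
        )
        assert flags.marker_overlap["p"] and not flags.marker_overlap["q"]

    def test_missing_annotation_counted_and_false(self):
        tc = _tc(canonical=["p"], non_canonical=["q"])
        ann = ProbeAnnotation(loci={"p": []}, is_te={})
        flags = annotate_heterochromatin(tc, ann, [])
        assert flags.n_missing_annotation == 1
        assert not flags.associated("q")

    def test_adding_peaks_is_monotone(self):
        rng = np.random.default_rng(19)
        names = [f"p{i}" for i in range(40)]
        tc = _tc(canonical=names[:20], non_canonical=names[20:])
        ann = ProbeAnnotation(
            loci={
                p: [GenomicInterval("c", int(s), int(s) + 100)]
                for p, s in zip(names, rng.integers(0, 20000, 40))
            },
            is_te={},
        )
        ivs = [
            GenomicInterval("c", int(s), int(s) + 200)
            for s in rng.integers(0, 20000, 15)
        ]
        f1 = annotate_heterochromatin(tc, ann, [PeakSet("a", ivs[:5])])
        f2 = annotate_heterochromatin(tc, ann, [PeakSet("a", ivs[:5]), PeakSet("b", ivs[5:])])
        for p in names:
            assert f2.marker_overlap[p] >= f1.marker_overlap[p]


class TestTallyContingency:
    def _flags(self, assoc: set[str], te: set[str] = frozenset(), universe=()):
        return HeterochromatinFlags(
            marker_overlap={p: p in assoc for p in universe},
            te={p: p in te for p in universe},
        )

    def test_small_enumeration(self):
        tc = _tc(canonical=["c1", "c2"], non_canonical=["n1", "n2"])
        flags = self._flags({"c1", "n1", "n2"}, universe=["c1", "c2", "n1", "n2"])
        table, _ = tally_contingency(tc, flags)
        assert table.as_list() == [[1, 1], [2, 0]]

    def test_headline_percentages_at_one_decimal(self):
        can = [f"c{i}" for i in range(258)]
        non = [f"n{i}" for i in range(409)]
        tc = _tc(canonical=can, non_canonical=non)
        flags = self._flags(set(can[:70]) | set(non[:156]), universe=can + non)
        table, fractions = tally_contingency(tc, flags)
        assert table.as_list() == [[70, 188], [156, 253]]
        assert round(float(fractions["canonical"]["combined"]) * 100, 1) == 27.1
        assert round(float(fractions["non_canonical"]["combined"]) * 100, 1) == 38.1

    def test_all_flags_false_gives_zero_fractions(self):
        tc = _tc(canonical=["c"], non_canonical=["n"])
        flags = self._flags(set(), universe=["c", "n"])
        table, fractions = tally_contingency(tc, flags)
        assert table.as_list() == [[0, 1], [0, 1]]
        assert fractions["canonical"]["combined"] == Fraction(0)

    def test_margins_equal_group_sizes(self):
        tc = _tc(canonical=["c1", "c2", "c3"], non_canonical=["n1", "n2"])
        flags = self._flags({"c1"}, te={"n2"}, universe=["c1", "c2", "c3", "n1", "n2"])
        table, fractions = tally_contingency(tc, flags)
        assert table.canonical_assoc + table.canonical_not == 3
        assert table.non_canonical_assoc + table.non_canonical_not == 2
        # combined >= each component rule
        for group, size in (("canonical", 3), ("non_canonical", 2)):
            fr = fractions[group]
            assert fr["combined"] >= max(fr["marker_overlap"], fr["te"])

    def test_empty_group_rejected(self):
        tc = _tc(canonical=["c"], non_canonical=["n"])
        flags = self._flags(set(), universe=["c"])
        with pytest.raises(ValueError, match="flags"):
            tally_contingency(tc, flags)


def test_probe_annotation_round_trip(tmp_path):
    ann = ProbeAnnotation(
        loci={
            "p1": [GenomicInterval("chr2L", 10, 500), GenomicInterval("chr2R", 5, 60)],
            "p2": [],
        },
        is_te={"p1": False, "p2": True},
    )
    write_probe_annotation(ann, tmp_path / "ann.tsv")
    back = read_probe_annotation(tmp_path / "ann.tsv")
    assert back.loci["p1"] == ann.loci["p1"]
    assert back.loci["p2"] == []
    assert back.is_te == ann.is_te
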