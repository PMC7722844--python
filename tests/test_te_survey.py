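import numpy as np
import pandas as pd
import pytest

from silentscan import synthetic_data as sd
from silentscan import te_survey as ts
from silentscan.read_mapping import AlignmentRecord, build_index
from silentscan.te_survey import SurveyConfig


def _rec(read_id, seq="A" * 100, mapped=True, ref="TE1", pos=0):
    return AlignmentRecord(
        read_id, seq, mapped=mapped,
        reference=ref if mapped else None, position=pos if mapped else None,
    )


def _anchor(read_id, chrom, pos, strain="s1", te="TE1", length=100):
    aln = AlignmentRecord(read_id, "A" * length, mapped=True, reference=chrom, position=pos)
    return ts.AnchoredRead(te, strain, read_id, aln)


def coverage_interval_oracle(intervals, merge_distance):
    """Brute-force per-base coverage: mark covered bases, close gaps up to
    merge_distance, emit maximal runs."""
    if not intervals:
        return []
    end_max = max(e for _, e in intervals)
    cov = np.zeros(end_max + merge_distance + 2, dtype=bool)
    for s, e in intervals:
        cov[s:e] = True
    runs, start = [], None
    gap = 0
    for i, covered in enumerate(cov):
        if covered:
            if start is None:
                start = i
            end = i + 1
            gap = 0
        elif start is not None:
            gap += 1
            if gap > merge_distance:
                runs.append((start, end))
                start = None
    if start is not None:
        runs.append((start, end))
    return runs


class TestClassifyHalfMapped:
    def test_both_mapped_not_emitted(self):
        pairs = [(_rec("p", pos=10), _rec("p", pos=50))]
        assert ts.classify_half_mapped(pairs, "s1") == []

    def test_neither_mapped_not_emitted(self):
        pairs = [(_rec("p", mapped=False), _rec("p", mapped=False))]
        assert ts.classify_half_mapped(pairs, "s1") == []

    def test_half_mapped_emitted_with_anchor(self):
        anchor_seq = "C" * 100
        pairs = [(_rec("p", ref="TOC1like", pos=5), _rec("p", seq=anchor_seq, mapped=False))]
        [hm] = ts.classify_half_mapped(pairs, "UVM11")
        assert hm.te_name == "TOC1like"
        assert hm.anchor_seq == anchor_seq
        assert hm.strain == "UVM11"

    def test_other_orientation(self):
        pairs = [(_rec("p", mapped=False), _rec("p", ref="TE9", pos=3))]
        [hm] = ts.classify_half_mapped(pairs, "s")
        assert hm.te_name == "TE9"

    def test_malformed_pair(self):
        with pytest.raises(ValueError, match="malformed"):
            ts.classify_half_mapped([(_rec("a"), _rec("b", mapped=False))], "s")


class TestAnchorMap:
    def test_empty_stream(self, small_genome):
        idx = build_index({"chr1": small_genome})
        assert ts.anchor_map([], idx) == []

    def test_random_anchor_unmapped(self, small_genome):
        idx = build_index({"chr1": small_genome})
        hm = ts.HalfMappedPair("TE1", "r1", sd.simulate_genome(100, 0.5, seed=77), "s1")
        [a] = ts.anchor_map([hm], idx)
        assert not a.alignment.mapped

    def test_flank_anchor_recovery(self, small_genome, te_library):
        # reads flanking a planted insertion anchor near the planted position
        design = [sd.TruthInsertion("TEalpha", frozenset(["s1"]), "chr1", 10_000, 1000)]
        genomes, _ = sd.plant_te_insertions({"chr1": small_genome}, te_library, design)
        strain_genome = genomes["s1"]["chr1"]
        idx = build_index({"chr1": small_genome})
        half = [
            ts.HalfMappedPair("TEalpha", f"a{i}", strain_genome[9900 - i * 7:10_000 - i * 7], "s1")
            for i in range(20)
        ]
        anchored = ts.anchor_map(half, idx)
        near = [
            a for a in anchored
            if a.alignment.mapped and abs(a.alignment.position - 10_000) <= 300
        ]
        assert len(near) / len(anchored) >= 0.95


class TestCallLoci:
    def test_single_pileup(self):
        anchors = [_anchor(f"r{i}", "chr1", 1000 + 10 * i) for i in range(12)]
        [locus] = ts.call_loci(anchors, SurveyConfig())
        assert (locus.start, locus.end) == (1000, 1210)
        assert locus.pooled_count == 12
        [(start, end)] = coverage_interval_oracle(
            [(a.alignment.position, a.alignment.position + 100) for a in anchors], 200
        )
        assert (locus.start, locus.end) == (start, end)

    def test_nine_reads_no_locus(self):
        anchors = [_anchor(f"r{i}", "chr1", 500) for i in range(9)]
        assert ts.call_loci(anchors, SurveyConfig()) == []

    def test_no_anchors(self):
        assert ts.call_loci([], SurveyConfig()) == []

    def test_merge_distance_respected(self):
        near = [_anchor(f"a{i}", "chr1", 0) for i in range(10)]
        far = [_anchor(f"b{i}", "chr1", 5000) for i in range(10)]
        loci = ts.call_loci(near + far, SurveyConfig(merge_distance=200))
        assert len(loci) == 2
        merged = ts.call_loci(near + far, SurveyConfig(merge_distance=6000))
        assert len(merged) == 1 and merged[0].pooled_count == 20

    def test_duplicate_read_ids_collapse(self):
        anchors = [_anchor("same", "chr1", 100) for _ in range(30)]
        assert ts.call_loci(anchors, SurveyConfig()) == []

    def test_matches_coverage_oracle_random(self, rng):
        anchors = [
            _anchor(f"r{i}", "chr1", int(rng.integers(0, 30_000)))
            for i in range(400)
        ]
        loci = ts.call_loci(anchors, SurveyConfig(min_locus_reads=1))
        oracle = coverage_interval_oracle(
            [(a.alignment.position, a.alignment.position + 100) for a in anchors], 200
        )
        assert [(l.start, l.end) for l in loci] == oracle

    def test_threshold_monotonicity(self, rng):
        anchors = [
            _anchor(f"r{i}", "chr1", int(rng.integers(0, 50_000)))
            for i in range(500)
        ]
        counts = [
            len(ts.call_loci(anchors, SurveyConfig(min_locus_reads=t)))
            for t in (1, 5, 10, 20, 50)
        ]
        assert counts == sorted(counts, reverse=True)


class TestScorePresence:
    STRAINS = ["cw15arg", "Elow47", "UVM4", "UVM11"]

    def _locus(self, counts):
        return ts.TELocus("chr1", 0, 100, dict(zip(self.STRAINS, counts)), frozenset(["TE1"]))

    def test_thresholding(self):
        matrix = ts.score_presence([self._locus((12, 3, 0, 15))], self.STRAINS)
        assert list(matrix.presence.iloc[0]) == [True, False, False, True]

    def test_boundary_inclusive(self):
        matrix = ts.score_presence([self._locus((10, 10, 10, 10))], self.STRAINS)
        assert matrix.presence.iloc[0].all()

    def test_invariant_matches_counts(self, rng):
        loci = [
            self._locus(tuple(int(x) for x in rng.integers(0, 40, size=4)))
            for _ in range(30)
        ]
        loci = [l for l in loci if l.pooled_count >= 10]
        matrix = ts.score_presence(loci, self.STRAINS, SurveyConfig(presence_threshold=10))
        assert (matrix.presence == (matrix.counts >= 10)).all().all()

    def test_presence_threshold_monotone(self):
        locus = self._locus((12, 9, 30, 10))
        low = ts.score_presence([locus], self.STRAINS, SurveyConfig(presence_threshold=10))
        high = ts.score_presence([locus], self.STRAINS, SurveyConfig(presence_threshold=20))
        # raising the threshold never turns absent into present
        assert not (high.presence & ~low.presence).any().any()


class TestFlagDifferential:
    def _counts(self, *rows):
        return pd.DataFrame(list(rows), columns=["a", "b", "c", "d"])

    def test_ratio_twenty_flagged(self):
        flags = ts.flag_differential(self._counts((100, 5, 80, 90)))
        assert flags.iloc[0]

    def test_low_ratio_not_flagged(self):
        flags = ts.flag_differential(self._counts((20, 15, 18, 19)))
        assert not flags.iloc[0]

    def test_zero_min_convention(self):
        flags = ts.flag_differential(self._counts((10, 0, 0, 0), (9, 0, 0, 0)))
        assert flags.iloc[0]       # max reaches presence threshold
        assert not flags.iloc[1]   # max below presence threshold

    def test_boundary_ratio_inclusive(self):
        flags = ts.flag_differential(self._counts((100, 10, 50, 50)))
        assert flags.iloc[0]  # ratio exactly 10 counts ("ratio >= 10")


class TestSummarizeSurvey:
    STRAINS = ["cw15arg", "Elow47", "UVM4", "UVM11"]

    def _presence(self, patterns, te="TE1"):
        presence = pd.DataFrame(patterns, columns=self.STRAINS)
        presence.index = [f"chr1:{i}-{i + 1}" for i in range(len(patterns))]
        tes = pd.Series(te, index=presence.index)
        return presence, tes

    def test_single_all_present(self):
        presence, tes = self._presence([(True, True, True, True)])
        table = ts.summarize_survey(presence, tes, self.STRAINS)
        row = table.loc["TE1"]
        assert row["total"] == 1 and row["all_strains"] == 1
        assert row.drop(["total", "all_strains"]).sum() == 0

    def test_pattern_classes(self):
        presence, tes = self._presence(
            [
                (True, True, True, True),
                (True, False, False, False),
                (False, False, False, True),
                (False, True, True, True),
                (True, True, False, False),  # -> other
            ]
        )
        row = ts.summarize_survey(presence, tes, self.STRAINS).loc["TE1"]
        assert row["all_strains"] == 1
        assert row["cw15arg_only"] == 1
        assert row["UVM11_only"] == 1
        assert row["Elow47+UVM4+UVM11"] == 1
        assert row["other"] == 1
        assert row["total"] == 5

    def test_row_sum_conservation_random(self, rng):
        patterns = []
        while len(patterns) < 60:
            p = tuple(bool(b) for b in rng.integers(0, 2, size=4))
            if any(p):
                patterns.append(p)
        presence, tes = self._presence(patterns)
        table = ts.summarize_survey(presence, tes, self.STRAINS)
        assert (table["total"] == table.drop(columns="total").sum(axis=1)).all()

    def test_zero_present_locus_rejected(self):
        presence, tes = self._presence([(False, False, False, False)])
        with pytest.raises(ValueError, match="zero strains"):
            ts.summarize_survey(presence, tes, self.STRAINS)


class TestSurveyConfig:
    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            SurveyConfig(min_locus_reads=0)
        with pytest.raises(ValueError):
            SurveyConfig(differential_ratio=-1)
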