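"""Evidence filter, eight-way typing, microhomology and prevalence tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromocat.errors import SequenceError, StatisticsError
from chromocat.model import Breakend, CNSegment, GenomeBuild, HEAD, SVCall, TAIL
from chromocat.svclass import (
    EvidenceRule,
    MatchParams,
    annotate_special_regions,
    classify_sv,
    compute_microhomology,
    filter_high_confidence,
    sv_type_prevalence_test,
)


def make_sv(p1, o1, p2, o2, chrom1="chr1", chrom2=None, **kw):
    kw.setdefault("evidence", {"discordant_pairs": 5, "split_reads": 5})
    return SVCall(Breakend(chrom1, p1, o1), Breakend(chrom2 or chrom1, p2, o2), **kw)


def reference_filter(counts, normal, coverage):
    """Independent restatement of the published high-confidence rule."""
    present = [c for c in counts if c >= 1]
    evidence_ok = len(present) >= 2 or (len(present) == 1 and present[0] >= 10)
    return evidence_ok and normal == 0 and coverage <= 1000


class TestEvidenceFilter:
    def test_two_lines_of_evidence_pass(self):
        sv = make_sv(100, HEAD, 200, TAIL,
                     evidence={"discordant_pairs": 4, "split_reads": 3})
        assert filter_high_confidence(sv) == (True, None)

    @pytest.mark.parametrize("reads,expected", [(10, True), (9, False)])
    def test_single_class_needs_ten_reads(self, reads, expected):
        sv = make_sv(100, HEAD, 200, TAIL, evidence={"split_reads": reads})
        assert filter_high_confidence(sv)[0] is expected

    def test_normal_evidence_rejects(self):
        sv = make_sv(100, HEAD, 200, TAIL,
                     evidence={"discordant_pairs": 8, "split_reads": 8},
                     normal_evidence=1)
        assert filter_high_confidence(sv) == (False, "normal-evidence")

    def test_repeat_coverage_rejects(self):
        sv = make_sv(100, HEAD, 200, TAIL,
                     evidence={"discordant_pairs": 8, "split_reads": 8},
                     region_coverage=1500)
        assert filter_high_confidence(sv) == (False, "repeat-coverage")

    def test_exhaustive_truth_table(self):
        """Full sweep over class subsets x counts x normal x coverage."""
        for counts in itertools.product([0, 1, 9, 10, 11], repeat=3):
            for normal in (0, 1):
                for coverage in (60, 1001):
                    sv = make_sv(100, HEAD, 200, TAIL,
                                 evidence={"discordant_pairs": counts[0],
                                           "split_reads": counts[1],
                                           "soft_clip": counts[2]},
                                 normal_evidence=normal, region_coverage=coverage)
                    assert filter_high_confidence(sv)[0] == reference_filter(
                        counts, normal, coverage), (counts, normal, coverage)

    @settings(max_examples=200, derandomize=True)
    @given(
        counts=st.tuples(*[st.integers(0, 15)] * 3),
        extra=st.tuples(st.integers(0, 2), st.integers(0, 5)),
        normal=st.integers(0, 2),
        coverage=st.floats(0, 2000),
    )
    def test_monotone_in_supporting_reads(self, counts, extra, normal, coverage):
        """Adding supporting reads never flips pass -> fail; adding normal
        evidence never flips fail -> pass."""
        cls, added = extra
        base = dict(zip(("discordant_pairs", "split_reads", "soft_clip"), counts))
        sv = make_sv(100, HEAD, 200, TAIL, evidence=base,
                     normal_evidence=normal, region_coverage=coverage)
        more = dict(base)
        more[list(more)[cls]] += added
        sv_more = make_sv(100, HEAD, 200, TAIL, evidence=more,
                          normal_evidence=normal, region_coverage=coverage)
        if filter_high_confidence(sv)[0]:
            assert filter_high_confidence(sv_more)[0]
        sv_normal = make_sv(100, HEAD, 200, TAIL, evidence=base,
                            normal_evidence=normal + 1, region_coverage=coverage)
        if not filter_high_confidence(sv)[0]:
            assert not filter_high_confidence(sv_normal)[0]


def seg(start, end, cn, state, chrom="chr1"):
    maf = {"loss": 1.0, "neutral": 0.5, "gain": 0.67, "amplified": 0.86, "cn_loh": 1.0}[state]
    if cn == 0:
        maf = None
    return CNSegment(chrom, start, end, cn, major_allele_fraction=maf, state=state)


class TestClassifySv:
    """The decision table, enumerated context-by-context.

    Expected labels come from a hand-built table over orientation pairs x
    CN contexts (boundary-matched loss, boundary-matched gain, overlapping
    gain, amplified containment, CN step, empty segments).
    """

    LOSS_MATCHED = [seg(0, 1_000_000, 2, "neutral"),
                    seg(1_000_000, 2_000_000, 1, "loss"),
                    seg(2_000_000, 3_000_000, 2, "neutral")]
    GAIN_MATCHED = [seg(0, 1_000_000, 2, "neutral"),
                    seg(1_000_000, 2_000_000, 4, "gain"),
                    seg(2_000_000, 3_000_000, 2, "neutral")]
    AMPLIFIED = [seg(0, 1_000_000, 2, "neutral"),
                 seg(1_000_000, 2_000_000, 8, "amplified"),
                 seg(2_000_000, 3_000_000, 2, "neutral")]
    FLAT = [seg(0, 3_000_000, 2, "neutral")]

    CASES = [
        # (breakend1, orient1, breakend2, orient2, segments, expected)
        (1_000_000, HEAD, 2_000_000, TAIL, LOSS_MATCHED, "deletion"),
        (1_020_000, HEAD, 1_980_000, TAIL, LOSS_MATCHED, "deletion"),   # within 30 kb
        (1_040_000, HEAD, 2_000_000, TAIL, LOSS_MATCHED, "intrachromosomal"),  # 40 kb off
        (1_000_000, HEAD, 2_000_000, TAIL, GAIN_MATCHED, "intrachromosomal"),  # wrong state
        (1_000_000, HEAD, 2_000_000, TAIL, FLAT, "intrachromosomal"),
        (1_000_000, TAIL, 2_000_000, HEAD, GAIN_MATCHED, "tandem_duplication"),
        (1_200_000, TAIL, 2_500_000, HEAD, GAIN_MATCHED, "duplication"),  # overlap, unmatched
        (1_000_000, TAIL, 2_000_000, HEAD, LOSS_MATCHED, "intrachromosomal"),
        (1_000_000, TAIL, 2_000_000, HEAD, FLAT, "intrachromosomal"),
        # same-orientation family
        (995_000, HEAD, 1_000_000 + 4_000, HEAD, GAIN_MATCHED, "foldback_inversion"),
        (1_500_000, HEAD, 1_505_000, HEAD, AMPLIFIED, "amplified_inversion"),
        (1_500_000, TAIL, 1_505_000, TAIL, AMPLIFIED, "amplified_inversion"),
        (1_500_000, HEAD, 1_505_000, HEAD, FLAT, "inversion"),
        (200_000, HEAD, 2_700_000, HEAD, AMPLIFIED, "inversion"),  # long span, outside amp
        (1_200_000, TAIL, 1_800_000, TAIL, GAIN_MATCHED, "inversion"),  # span > foldback max
    ]

    @pytest.mark.parametrize("p1,o1,p2,o2,segments,expected", CASES)
    def test_decision_table(self, p1, o1, p2, o2, segments, expected):
        assert classify_sv(make_sv(p1, o1, p2, o2), segments) == expected

    def test_translocation_is_definitional(self):
        sv = make_sv(100, HEAD, 200, TAIL, chrom1="chr1", chrom2="chr5")
        assert classify_sv(sv, self.LOSS_MATCHED) == "translocation"

    def test_empty_segments_orientation_only(self):
        assert classify_sv(make_sv(100, HEAD, 5_000, HEAD), []) == "inversion"
        assert classify_sv(make_sv(100, HEAD, 5_000, TAIL), []) == "intrachromosomal"

    def test_exhaustive_orientation_by_context_grid(self):
        """Every orientation pair against every context yields a label from
        the expected family (determinism + totality)."""
        contexts = [self.LOSS_MATCHED, self.GAIN_MATCHED, self.AMPLIFIED, self.FLAT, []]
        for o1, o2 in itertools.product((HEAD, TAIL), repeat=2):
            for ctx in contexts:
                sv = make_sv(1_000_000, o1, 2_000_000, o2)
                first = classify_sv(sv, ctx)
                assert first == classify_sv(sv, ctx)  # deterministic
                if o1 == o2:
                    assert first in ("inversion", "foldback_inversion", "amplified_inversion")
                else:
                    assert first in ("deletion", "duplication", "tandem_duplication",
                                     "intrachromosomal")


class TestSpecialRegions:
    def test_near_telomere_window(self, genome):
        sv = make_sv(50_000, HEAD, 120_000_000, TAIL)
        assert annotate_special_regions(sv, genome).near_telomere

    def test_window_boundary_exclusive(self, genome):
        bare = GenomeBuild(("chr1",), {"chr1": 200_000_000})
        sv = make_sv(100_001, HEAD, 120_000_000, TAIL)
        out = annotate_special_regions(sv, bare)
        assert not out.near_telomere and not out.near_centromere

    def test_near_centromere(self, genome):
        # centromere chr1 spans 90-92 Mb; breakend 50 kb before it
        sv = make_sv(89_950_000, HEAD, 120_000_000, TAIL)
        assert annotate_special_regions(sv, genome).near_centromere


class TestMicrohomology:
    @pytest.mark.parametrize("left,right,expected", [
        ("GGACGT", "ACGTTT", 4),
        ("AAAA", "CCCC", 0),
        ("ACGTACGTAC", "ACGTACGTAC", 10),
    ])
    def test_examples(self, left, right, expected):
        assert compute_microhomology(left, right, max_check=10) == expected

    def test_non_acgt_raises(self):
        with pytest.raises(SequenceError):
            compute_microhomology("ACGN", "ACGT", 4)

    @settings(max_examples=200, derandomize=True)
    @given(left=st.text("ACGT", min_size=1, max_size=15),
           right=st.text("ACGT", min_size=1, max_size=15),
           max_check=st.integers(1, 15))
    def test_matches_quadratic_oracle(self, left, right, max_check):
        best = 0
        for L in range(1, min(max_check, len(left), len(right)) + 1):
            if all(left[len(left) - L + i] == right[i] for i in range(L)):
                best = L
        assert compute_microhomology(left, right, max_check) == best


class TestPrevalenceTest:
    def frac(self, inversion):
        rest = (1 - inversion) / 7
        from chromocat.model import SV_TYPES
        return {t: (inversion if t == "inversion" else rest) for t in SV_TYPES}

    def test_identical_groups_p_one(self):
        group = [self.frac(0.4), self.frac(0.5), self.frac(0.45)]
        res = sv_type_prevalence_test(group, group)
        assert res["inversion"]["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["inversion"]["p"] == pytest.approx(1.0)

    def test_separated_groups_significant_and_matches_welch_formula(self):
        a = [self.frac(x) for x in (0.4, 0.5, 0.45)]
        b = [self.frac(x) for x in (0.1, 0.12, 0.08)]
        res = sv_type_prevalence_test(a, b)["inversion"]
        assert res["p"] < 0.05
        # independent Welch computation from the textbook formula
        xa = np.array([0.4, 0.5, 0.45]); xb = np.array([0.1, 0.12, 0.08])
        va, vb = xa.var(ddof=1) / 3, xb.var(ddof=1) / 3
        t = (xa.mean() - xb.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
        from scipy import stats as ss
        p = 2 * ss.t.sf(abs(t), df)
        assert res["t"] == pytest.approx(t)
        assert res["p"] == pytest.approx(p)

    def test_single_sample_group_raises(self):
        with pytest.raises(StatisticsError):
            sv_type_prevalence_test([self.frac(0.4)], [self.frac(0.1), self.frac(0.2)])

    def test_zero_variance_equal_means_flagged(self):
        group = [self.frac(0.4), self.frac(0.4)]
        res = sv_type_prevalence_test(group, group)
        assert res["inversion"]["degenerate"]
        assert math.isnan(res["inversion"]["p"])
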