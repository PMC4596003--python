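"""CN states, clustering statistics, and the chromothripsis/BFB detectors."""

import numpy as np
import pytest
from scipy import stats as ss

from chromocat.catastrophe import (
    BFBCriteria,
    assess_chromosome,
    breaks_per_mb,
    classify_cn_state,
    classify_segments,
    count_state_switches,
    detect_bfb,
    detect_chromothripsis,
    detect_chromothripsis_array_only,
    heterozygosity_retained,
    ks_clustering_test,
    random_joins_test,
    subtype_genome,
)
from chromocat.errors import CoordinateError, ValidationError
from chromocat.model import Breakend, CNSegment, GenomeBuild, HEAD, SVCall, TAIL
from chromocat.simulate import (
    BFBSim,
    ChromothripsisSim,
    simulate_bfb_chrom,
    simulate_chromothripsis_chrom,
)
from chromocat.svclass import classify_sv_calls


def segs_from_cns(cns, maf=0.67, chrom="chr1", size=1_000_000):
    out = []
    for i, cn in enumerate(cns):
        m = maf if cn > 0 else None
        out.append(CNSegment(chrom, i * size, (i + 1) * size, cn, major_allele_fraction=m))
    return out


class TestCnState:
    @pytest.mark.parametrize("cn,maf,expected", [
        (7, 0.6, "amplified"),
        (6, 0.9, "amplified"),
        (2, 1.0, "cn_loh"),
        (2, 0.9, "cn_loh"),
        (2, 0.5, "neutral"),
        (2, None, "neutral"),
        (0, None, "loss"),
        (1, 1.0, "loss"),
        (3, 0.67, "gain"),
        (5, 0.6, "gain"),
    ])
    def test_state_partition(self, cn, maf, expected):
        assert classify_cn_state(cn, maf) == expected

    def test_invalid_maf_raises(self):
        with pytest.raises(ValidationError):
            classify_cn_state(2, 0.2)

    def test_classify_segments_sets_state(self):
        per_chrom = {"chr1": segs_from_cns([1, 2, 7])}
        classify_segments(per_chrom)
        assert [s.state for s in per_chrom["chr1"]] == ["loss", "neutral", "amplified"]


class TestSwitchCounting:
    def test_oscillating_profile(self):
        segs = segs_from_cns([2, 3, 2, 3, 2, 3, 2, 3, 2, 3, 2])
        assert count_state_switches(segs) == (10, 2)

    def test_single_segment(self):
        assert count_state_switches(segs_from_cns([2])) == (0, 1)

    def test_empty(self):
        assert count_state_switches([]) == (0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_profiles_match_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cns = list(rng.integers(0, 5, size=rng.integers(1, 30)))
        segs = segs_from_cns(cns)
        switches, distinct = count_state_switches(segs)
        assert switches == sum(cns[i] != cns[i + 1] for i in range(len(cns) - 1))
        assert distinct == len(set(cns))


class TestHeterozygosity:
    def test_retained_heterozygous(self):
        segs = segs_from_cns([2, 3, 2, 3], maf=0.67)
        assert heterozygosity_retained(segs) is True

    def test_one_loh_retained_segment_fails(self):
        segs = segs_from_cns([2, 3, 2])
        segs[1].major_allele_fraction = 1.0
        assert heterozygosity_retained(segs) is False

    def test_missing_maf_indeterminate(self):
        segs = [CNSegment("chr1", 0, 10, 3), CNSegment("chr1", 10, 20, 2)]
        assert heterozygosity_retained(segs) is None

    def test_lost_segments_exempt(self):
        segs = segs_from_cns([1, 3, 1, 3], maf=0.67)
        for s in segs:
            if s.total_cn == 1:
                s.major_allele_fraction = 1.0
        assert heterozygosity_retained(segs) is True


class TestBreakRates:
    def make_svs(self, n, chrom="chr1", genome=None):
        svs = []
        for i in range(n):
            svs.append(SVCall(Breakend(chrom, 1000 + 2 * i, HEAD),
                              Breakend(chrom, 2000 + 2 * i, TAIL),
                              evidence={"split_reads": 10}))
        return svs

    def test_rate_arithmetic(self):
        genome = GenomeBuild(("chrA",), {"chrA": 100_000_000})
        rates, genome_rate = breaks_per_mb(self.make_svs(50, "chrA"), genome)
        assert rates["chrA"] == pytest.approx(1.0)  # 100 breakends / 100 Mb
        assert genome_rate == pytest.approx(1.0)

    def test_translocation_counts_on_both_chromosomes(self):
        genome = GenomeBuild(("chrA", "chrB"), {"chrA": 1_000_000, "chrB": 1_000_000})
        sv = SVCall(Breakend("chrA", 10, HEAD), Breakend("chrB", 20, TAIL),
                    evidence={"split_reads": 10})
        rates, _ = breaks_per_mb([sv], genome)
        assert rates["chrA"] == pytest.approx(1.0)
        assert rates["chrB"] == pytest.approx(1.0)

    def test_no_svs_zero_rates(self):
        genome = GenomeBuild(("chrA",), {"chrA": 1_000_000})
        rates, genome_rate = breaks_per_mb([], genome)
        assert rates["chrA"] == 0.0 and genome_rate == 0.0


class TestKsClustering:
    def test_tight_cluster_highly_significant(self):
        positions = list(range(0, 1_000_000, 10_000))  # first 1% of 100 Mb
        p, small = ks_clustering_test(positions, 100_000_000)
        assert not small and p < 1e-3

    def test_uniform_quantiles_fit_well(self):
        n, L = 50, 1_000_000
        positions = [int((i - 0.5) / n * L) for i in range(1, n + 1)]
        p, _ = ks_clustering_test(positions, L)
        assert p > 0.99

    def test_small_n_returns_flag(self):
        assert ks_clustering_test([1, 2, 3], 1000) == (1.0, True)

    def test_position_out_of_range_raises(self):
        with pytest.raises(CoordinateError):
            ks_clustering_test([10, 2000], 1000)

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(1000):
            positions = rng.integers(0, 1_000_000, size=30)
            p, _ = ks_clustering_test(positions, 1_000_000)
            pvals.append(p)
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.03 <= frac <= 0.07


class TestRandomJoins:
    def sv(self, o1, o2):
        return SVCall(Breakend("chr1", 100, o1), Breakend("chr1", 200, o2),
                      evidence={"split_reads": 10})

    def test_balanced_counts_p_one(self):
        svs = ([self.sv(HEAD, TAIL)] * 10 + [self.sv(TAIL, HEAD)] * 10
               + [self.sv(HEAD, HEAD)] * 10 + [self.sv(TAIL, TAIL)] * 10)
        assert random_joins_test(svs) == pytest.approx(1.0)

    def test_extreme_skew_matches_chi_square_formula(self):
        svs = [self.sv(HEAD, TAIL)] * 40
        p = random_joins_test(svs)
        # chi2 statistic by hand: 3*(0-10)^2/10 + (40-10)^2/10 = 120, df 3
        assert p == pytest.approx(float(ss.chi2.sf(120.0, 3)))
        assert p < 1e-3

    def test_too_few_joins_indeterminate(self):
        assert random_joins_test([self.sv(HEAD, TAIL)] * 7) is None

    def test_matches_reference_implementation_on_random_draws(self, rng):
        orients = [HEAD, TAIL]
        for _ in range(20):
            counts = rng.multinomial(40, [0.25] * 4)
            svs = []
            for (o1, o2), c in zip([(0, 1), (1, 0), (0, 0), (1, 1)], counts):
                svs += [self.sv(orients[o1], orients[o2])] * int(c)
            assert random_joins_test(svs) == pytest.approx(
                float(ss.chisquare(counts).pvalue))


class TestChromothripsisDetector:
    def simulated_positive(self, seed=3):
        rng = np.random.default_rng(seed)
        segs, svs = simulate_chromothripsis_chrom("chr1", 100_000_000,
                                                  ChromothripsisSim(), rng)
        classify_segments({"chr1": segs})
        return segs, svs

    def test_simulated_chromothripsis_positive(self):
        segs, svs = self.simulated_positive()
        verdict, flags, info = detect_chromothripsis(segs, svs, 100_000_000)
        assert verdict is True
        assert all(flags.values())
        assert info["n_switches"] >= 10 and info["distinct_states"] in (2, 3)

    def test_simulated_bfb_is_negative(self):
        rng = np.random.default_rng(5)
        segs, svs = simulate_bfb_chrom("chr1", 100_000_000, BFBSim(), rng)
        classify_segments({"chr1": segs})
        verdict, flags, _ = detect_chromothripsis(segs, svs, 100_000_000)
        assert verdict is False
        assert flags["cn_oscillation"] is False       # 2 switches only
        assert flags["random_joins"] is False          # fold-backs are one-sided

    def test_four_distinct_states_negative(self):
        segs, svs = self.simulated_positive()
        segs = [s for s in segs]
        # push two retained segments to new CN levels -> 4 distinct states
        retained = [s for s in segs if s.total_cn == 3]
        retained[0].total_cn = 5
        retained[1].total_cn = 4
        verdict, flags, _ = detect_chromothripsis(segs, svs, 100_000_000)
        assert flags["two_three_states"] is False and verdict is False

    def test_indeterminate_heterozygosity_propagates(self):
        segs, svs = self.simulated_positive()
        for s in segs:
            s.major_allele_fraction = None
        verdict, flags, _ = detect_chromothripsis(segs, svs, 100_000_000)
        assert verdict is None and flags["het_retained"] is None

    def test_mirror_reflection_invariance(self):
        length = 100_000_000
        segs, svs = self.simulated_positive(seed=9)
        v1, f1, _ = detect_chromothripsis(segs, svs, length)
        m_segs = [CNSegment(s.chrom, length - s.end, length - s.start, s.total_cn,
                            s.major_allele_fraction, state=s.state)
                  for s in reversed(segs)]
        flip = {HEAD: TAIL, TAIL: HEAD}
        m_svs = []
        for sv in svs:
            b1 = Breakend(sv.bnd1.chrom, length - sv.bnd2.pos, flip[sv.bnd2.orient])
            b2 = Breakend(sv.bnd2.chrom, length - sv.bnd1.pos, flip[sv.bnd1.orient])
            m_svs.append(SVCall(b1, b2, evidence=sv.evidence))
        v2, f2, _ = detect_chromothripsis(m_segs, m_svs, length)
        assert v1 == v2 and f1 == f2


class TestArrayOnlyDetector:
    def test_ten_switch_retained_positive(self):
        segs = segs_from_cns([2, 3] * 5 + [2], maf=0.67)
        assert detect_chromothripsis_array_only(segs) is True

    def test_nine_switches_negative(self):
        segs = segs_from_cns([2, 3] * 5, maf=0.67)  # 9 switches
        assert count_state_switches(segs)[0] == 9
        assert detect_chromothripsis_array_only(segs) is False

    def test_loh_in_retained_segments_negative(self):
        segs = segs_from_cns([2, 3] * 5 + [2], maf=1.0)
        assert detect_chromothripsis_array_only(segs) is False


class TestBfbDetector:
    def typed(self, segs, svs):
        classify_segments({"chr1": segs})
        return classify_sv_calls(svs, {"chr1": segs})

    def test_simulated_bfb_positive(self):
        rng = np.random.default_rng(1)
        segs, svs = simulate_bfb_chrom("chr1", 100_000_000, BFBSim(), rng)
        svs = self.typed(segs, svs)
        positive, flags = detect_bfb(segs, svs)
        assert positive and all(flags.values())

    def test_no_inversions_negative(self):
        rng = np.random.default_rng(1)
        segs, svs = simulate_bfb_chrom("chr1", 100_000_000, BFBSim(n_foldbacks=0), rng)
        svs = self.typed(segs, svs)
        positive, flags = detect_bfb(segs, svs)
        assert not positive and not flags["inversions_in_amplicon"]

    def test_no_telomeric_loss_negative(self):
        rng = np.random.default_rng(1)
        segs, svs = simulate_bfb_chrom("chr1", 100_000_000, BFBSim(lost_telomeric_bp=0), rng)
        svs = self.typed(segs, svs)
        positive, flags = detect_bfb(segs, svs)
        assert not positive and not flags["telomeric_loss"]

    def test_gain_neighbour_not_amplified_negative(self):
        rng = np.random.default_rng(1)
        segs, svs = simulate_bfb_chrom("chr1", 100_000_000, BFBSim(amplicon_cn=3), rng)
        svs = self.typed(segs, svs)
        positive, flags = detect_bfb(segs, svs)
        assert not positive and not flags["adjacent_amplicon"]

    def test_q_arm_loss_detected_by_mirror(self):
        rng = np.random.default_rng(1)
        length = 100_000_000
        segs, svs = simulate_bfb_chrom("chr1", length, BFBSim(), rng)
        m_segs = [CNSegment(s.chrom, length - s.end, length - s.start, s.total_cn,
                            s.major_allele_fraction) for s in reversed(segs)]
        flip = {HEAD: TAIL, TAIL: HEAD}
        m_svs = [SVCall(Breakend(sv.bnd1.chrom, length - sv.bnd2.pos, flip[sv.bnd2.orient]),
                        Breakend(sv.bnd2.chrom, length - sv.bnd1.pos, flip[sv.bnd1.orient]),
                        evidence=sv.evidence) for sv in svs]
        m_svs = self.typed(m_segs, m_svs)
        positive, _ = detect_bfb(m_segs, m_svs)
        assert positive


class TestSubtype:
    def test_many_svs_unstable(self):
        assert subtype_genome(776, {"chr1": 1.0}, 1.0) == "unstable"

    def test_even_distribution_scattered(self):
        assert subtype_genome(300, {"chr1": 1.2, "chr2": 0.9}, 1.0,
                              {"chr1": 120, "chr2": 90}) == "scattered"

    def test_concentrated_chromosome_complex_localized(self):
        assert subtype_genome(300, {"chr1": 4.0, "chr2": 0.8}, 1.0,
                              {"chr1": 400, "chr2": 80}) == "complex_localized"

    def test_three_x_needs_minimum_breakends(self):
        assert subtype_genome(10, {"chr1": 4.0, "chr2": 0.8}, 1.0,
                              {"chr1": 4, "chr2": 80}) == "scattered"


def test_verdict_booleans_equal_flag_conjunction():
    genome = GenomeBuild.synthetic(2, 100_000_000)
    rng = np.random.default_rng(21)
    segs, svs = simulate_chromothripsis_chrom("chr1", 100_000_000, ChromothripsisSim(), rng)
    classify_segments({"chr1": segs})
    svs = classify_sv_calls(svs, {"chr1": segs})
    verdict = assess_chromosome("chr1", segs, svs, genome)
    assert verdict.chromothripsis == all(bool(v) for v in verdict.chromothripsis_flags.values())
    assert verdict.bfb == all(verdict.bfb_flags.values())
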