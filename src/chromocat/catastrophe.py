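"""Chromosome-scale catastrophe detection.

Copy-number states follow the array-based convention: loss (CN 0-1),
neutral (CN 2, heterozygous), copy-neutral LOH (CN 2, single parental
allele), gain (CN 3-5), amplified (CN >= 6).

A chromosome is called chromothriptic when its breakpoints are clustered
(one-sample Kolmogorov-Smirnov test against uniform, P < 0.001), its CN
profile oscillates (>= 10 switches between 2-3 distinct CN levels) with
heterozygosity retained in the retained segments, and its join orientations
are consistent with random joining (chi-square on the four orientation
pairs).  Breakage-fusion-bridge is called from terminal telomeric loss
adjacent to a highly amplified region harbouring inversion-family
rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import CoordinateError, ValidationError
from .model import HEAD, TAIL, GenomeBuild, group_svs_by_chrom, intrachromosomal_svs

INVERSION_FAMILY = ("inversion", "foldback_inversion", "amplified_inversion")


@dataclass(frozen=True)
class CNStateThresholds:
    """Boundaries of the five CN state labels."""

    loss_max_cn: int = 1
    neutral_cn: int = 2
    gain_min_cn: int = 3
    amplified_min_cn: int = 6
    loh_min_maf: float = 0.9


@dataclass(frozen=True)
class ChromothripsisCriteria:
    min_switches: int = 10
    min_distinct_states: int = 2
    max_distinct_states: int = 3
    het_retention_required: bool = True
    clustering_alpha: float = 0.001
    random_join_alpha: float = 0.001
    min_joins_for_randomness: int = 8
    min_breakends_for_clustering: int = 5


@dataclass(frozen=True)
class BFBCriteria:
    min_telomeric_loss_bp: int = 1_000_000
    amplified_min_cn: int = 6
    min_inversions: int = 2
    adjacency_window_bp: int = 1_000_000


@dataclass
class ChromosomeVerdict:
    """Per-chromosome catastrophe assessment with per-criterion flags.

    The composite booleans equal the conjunction of their flags; a flag of
    None means indeterminate (insufficient data), which propagates to an
    indeterminate (None) composite rather than a negative.
    """

    chrom: str
    breaks_per_mb: float
    n_breakends: int
    clustering_p: Optional[float]
    n_switches: int
    distinct_states: int
    het_retained: Optional[bool]
    random_join_p: Optional[float]
    chromothripsis: Optional[bool] = None
    chromothripsis_flags: Dict[str, Optional[bool]] = field(default_factory=dict)
    bfb: bool = False
    bfb_flags: Dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CN state logic

def classify_cn_state(total_cn: int, major_allele_fraction: Optional[float],
                      thresholds: CNStateThresholds = CNStateThresholds()) -> str:
    """State label for one (total CN, major allele fraction) pair."""
    if total_cn < 0:
        raise ValidationError("total_cn must be >= 0")
    maf = major_allele_fraction
    if maf is not None and not (0.5 <= maf <= 1.0):
        raise ValidationError(f"major_allele_fraction {maf} outside [0.5, 1.0]")
    if total_cn <= thresholds.loss_max_cn:
        return "loss"
    if total_cn == thresholds.neutral_cn:
        if maf is not None and maf >= thresholds.loh_min_maf:
            return "cn_loh"
        return "neutral"
    if total_cn >= thresholds.amplified_min_cn:
        return "amplified"
    return "gain"


def classify_segments(per_chrom: dict, thresholds: CNStateThresholds = CNStateThresholds()) -> dict:
    """Set ``state`` on every segment (in place); returns the mapping."""
    for segments in per_chrom.values():
        for seg in segments:
            seg.state = classify_cn_state(seg.total_cn, seg.major_allele_fraction, thresholds)
    return per_chrom


def count_state_switches(segments: Sequence) -> Tuple[int, int]:
    """(adjacent pairs with unequal total CN, number of distinct CN levels)."""
    if not segments:
        return 0, 0
    cns = [s.total_cn for s in segments]
    switches = sum(1 for a, b in zip(cns, cns[1:]) if a != b)
    return switches, len(set(cns))


def heterozygosity_retained(segments: Sequence,
                            thresholds: CNStateThresholds = CNStateThresholds()) -> Optional[bool]:
    """True iff every segment at the modal higher CN level is heterozygous
    (major allele fraction < loh_min_maf); segments at the chromosome's
    lowest CN level ("lost") are exempt.  Returns None (indeterminate) when
    the relevant segments carry no allele-fraction data."""
    if not segments:
        return None
    levels = sorted({s.total_cn for s in segments})
    higher = [s for s in segments if s.total_cn > levels[0]] or list(segments)
    counts: Dict[int, int] = {}
    for s in higher:
        counts[s.total_cn] = counts.get(s.total_cn, 0) + 1
    modal = max(counts, key=lambda cn: (counts[cn], cn))
    at_modal = [s for s in higher if s.total_cn == modal]
    mafs = [s.major_allele_fraction for s in at_modal]
    if any(m is None for m in mafs):
        return None
    return all(m < thresholds.loh_min_maf for m in mafs)


# ---------------------------------------------------------------------------
# Breakpoint density and clustering

def breaks_per_mb(svs: Sequence, genome: GenomeBuild) -> Tuple[Dict[str, float], float]:
    """Per-chromosome and genome-wide double-strand-break rates.

    Each breakend counts once toward its own chromosome, so a translocation
    contributes to two chromosomes.
    """
    positions = group_svs_by_chrom(svs)
    rates = {}
    total_breakends = 0
    for chrom in genome.chrom_names:
        n = len(positions.get(chrom, []))
        total_breakends += n
        rates[chrom] = n / (genome.chrom_lengths[chrom] / 1e6)
    genome_rate = total_breakends / (genome.total_length() / 1e6)
    return rates, genome_rate


def ks_clustering_test(positions: Sequence[int], chrom_length: int,
                       min_n: int = 5) -> Tuple[float, bool]:
    """One-sample KS test of breakend positions against Uniform(0, length).

    Returns ``(p_value, small_n)``; with fewer than ``min_n`` positions the
    test is not informative and ``(1.0, True)`` is returned.
    """
    arr = np.asarray(positions, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() >= chrom_length):
        raise CoordinateError("breakend position outside [0, chrom_length)")
    if arr.size < min_n:
        return 1.0, True
    res = stats.kstest(arr / chrom_length, "uniform")
    return float(res.pvalue), False


def random_joins_test(svs: Sequence, min_n: int = 8) -> Optional[float]:
    """Chi-square goodness-of-fit of join orientation pairs vs uniform.

    The four categories are (head,tail), (tail,head), (head,head),
    (tail,tail); df = 3.  A high p-value is consistent with random joining.
    Returns None (indeterminate) for fewer than ``min_n`` joins.
    """
    pairs = [(HEAD, TAIL), (TAIL, HEAD), (HEAD, HEAD), (TAIL, TAIL)]
    counts = {p: 0 for p in pairs}
    for sv in svs:
        counts[sv.orientation_pair] += 1
    n = sum(counts.values())
    if n < min_n:
        return None
    res = stats.chisquare(list(counts.values()))
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Detectors

def detect_chromothripsis(segments: Sequence, svs: Sequence, chrom_length: int,
                          criteria: ChromothripsisCriteria = ChromothripsisCriteria(),
                          breakend_positions: Optional[Sequence[int]] = None,
                          ) -> Tuple[Optional[bool], Dict[str, Optional[bool]], dict]:
    """Full (WGS) chromothripsis test for one chromosome.

    Positive iff breakpoints are clustered (KS p < clustering_alpha), the CN
    profile has >= min_switches switches across 2-3 distinct levels,
    heterozygosity is retained, and join orientations are consistent with
    randomness (chi-square p >= random_join_alpha).  Indeterminate
    heterozygosity gives an indeterminate verdict (None); an indeterminate
    join-randomness test (too few joins) counts as criterion-not-met, since
    the criterion requires affirmative evidence of random joining.

    Returns ``(verdict, flags, stats)``.
    """
    if breakend_positions is None:
        breakend_positions = []
        for sv in svs:
            for bnd in (sv.bnd1, sv.bnd2):
                breakend_positions.append(bnd.pos)
    joins = [sv for sv in svs if not sv.is_interchromosomal]

    clustering_p, small_n = ks_clustering_test(
        breakend_positions, chrom_length, criteria.min_breakends_for_clustering)
    n_switches, distinct = count_state_switches(segments)
    het = heterozygosity_retained(segments)
    join_p = random_joins_test(joins, criteria.min_joins_for_randomness)

    flags: Dict[str, Optional[bool]] = {
        "clustered_breakpoints": (clustering_p < criteria.clustering_alpha) and not small_n,
        "cn_oscillation": n_switches >= criteria.min_switches,
        "two_three_states": criteria.min_distinct_states <= distinct <= criteria.max_distinct_states,
        "het_retained": het if criteria.het_retention_required else True,
        "random_joins": (join_p is not None and join_p >= criteria.random_join_alpha),
    }
    if flags["het_retained"] is None:
        verdict: Optional[bool] = None
    else:
        verdict = all(bool(v) for v in flags.values())
    info = {"clustering_p": clustering_p, "n_switches": n_switches,
            "distinct_states": distinct, "het_retained": het, "random_join_p": join_p}
    return verdict, flags, info


def detect_chromothripsis_array_only(segments: Sequence,
                                     criteria: ChromothripsisCriteria = ChromothripsisCriteria(),
                                     ) -> Optional[bool]:
    """Array-screen chromothripsis test: CN oscillation (>= 10 switches over
    2-3 levels) with retained heterozygosity; no SV input."""
    n_switches, distinct = count_state_switches(segments)
    het = heterozygosity_retained(segments)
    if het is None:
        return None
    return (n_switches >= criteria.min_switches
            and criteria.min_distinct_states <= distinct <= criteria.max_distinct_states
            and het)


def _terminal_loss_run(segments: Sequence, from_start: bool) -> Tuple[int, int]:
    """(run_start, run_end) extent of the terminal run of loss-state segments;
    (0, 0)-like empty when the terminal segment is not a loss."""
    ordered = segments if from_start else list(reversed(segments))
    run = []
    for seg in ordered:
        if seg.state == "loss":
            run.append(seg)
        else:
            break
    if not run:
        return 0, 0
    return (run[0].start, run[-1].end) if from_start else (run[-1].start, run[0].end)


def detect_bfb(segments: Sequence, svs: Sequence,
               criteria: BFBCriteria = BFBCriteria()) -> Tuple[bool, Dict[str, bool]]:
    """Breakage-fusion-bridge test for one chromosome.

    Positive iff a terminal (p- or q-side) run of loss-state segments spans
    >= min_telomeric_loss_bp, an amplified segment (CN >= amplified_min_cn)
    begins within adjacency_window_bp of that run, and >= min_inversions
    inversion-family rearrangements have both breakends inside the amplified
    region (contiguous amplified segments merged).  SVs must be typed.
    """
    flags = {"telomeric_loss": False, "adjacent_amplicon": False, "inversions_in_amplicon": False}
    amp_region = None
    for from_start in (True, False):
        run_start, run_end = _terminal_loss_run(segments, from_start)
        if run_end - run_start < criteria.min_telomeric_loss_bp:
            continue
        flags["telomeric_loss"] = True
        boundary = run_end if from_start else run_start
        for seg in segments:
            if seg.total_cn < criteria.amplified_min_cn:
                continue
            edge = seg.start if from_start else seg.end
            if abs(edge - boundary) <= criteria.adjacency_window_bp:
                # merge contiguous amplified neighbours into one region
                amp_segs = [seg]
                idx = segments.index(seg)
                for nxt in segments[idx + 1:]:
                    if nxt.start == amp_segs[-1].end and nxt.total_cn >= criteria.amplified_min_cn:
                        amp_segs.append(nxt)
                    else:
                        break
                for prv in reversed(segments[:idx]):
                    if prv.end == amp_segs[0].start and prv.total_cn >= criteria.amplified_min_cn:
                        amp_segs.insert(0, prv)
                    else:
                        break
                amp_region = (amp_segs[0].start, amp_segs[-1].end)
                flags["adjacent_amplicon"] = True
                break
        if amp_region is not None:
            break
    if amp_region is not None:
        lo, hi = amp_region
        n_inv = sum(
            1 for sv in svs
            if sv.sv_type in INVERSION_FAMILY
            and not sv.is_interchromosomal
            and lo <= sv.bnd1.pos < hi and lo <= sv.bnd2.pos < hi
        )
        flags["inversions_in_amplicon"] = n_inv >= criteria.min_inversions
    return all(flags.values()), flags


# ---------------------------------------------------------------------------
# Per-chromosome assessment and genome subtyping

def assess_chromosome(chrom: str, segments: Sequence, svs: Sequence, genome: GenomeBuild,
                      ct_criteria: ChromothripsisCriteria = ChromothripsisCriteria(),
                      bfb_criteria: BFBCriteria = BFBCriteria()) -> ChromosomeVerdict:
    """Run both detectors on one chromosome of one sample.

    ``svs`` is the sample's full (typed, filtered) call set; breakends landing
    on ``chrom`` are selected here.
    """
    length = genome.length(chrom)
    positions = group_svs_by_chrom(svs).get(chrom, [])
    local = [sv for sv in svs if chrom in (sv.bnd1.chrom, sv.bnd2.chrom)]
    joins = intrachromosomal_svs(svs, chrom)

    verdict, ct_flags, info = detect_chromothripsis(
        segments, joins, length, ct_criteria, breakend_positions=positions)
    bfb, bfb_flags = detect_bfb(segments, joins, bfb_criteria)
    return ChromosomeVerdict(
        chrom=chrom,
        breaks_per_mb=len(positions) / (length / 1e6),
        n_breakends=len(positions),
        clustering_p=info["clustering_p"],
        n_switches=info["n_switches"],
        distinct_states=info["distinct_states"],
        het_retained=info["het_retained"],
        random_join_p=info["random_join_p"],
        chromothripsis=verdict,
        chromothripsis_flags=ct_flags,
        bfb=bfb,
        bfb_flags=bfb_flags,
    )


def subtype_genome(n_high_confidence_svs: int, chrom_rates: Dict[str, float],
                   genome_rate: float, chrom_breakends: Optional[Dict[str, int]] = None,
                   unstable_min_svs: int = 450, localized_fold: float = 3.0,
                   min_breakends: int = 5) -> str:
    """Genome subtype: unstable (>= 450 SVs), complex_localized (some
    chromosome with >= 3x the genome-wide break rate and >= 5 breakends),
    else scattered."""
    if n_high_confidence_svs >= unstable_min_svs:
        return "unstable"
    for chrom, rate in chrom_rates.items():
        enough = True
        if chrom_breakends is not None:
            enough = chrom_breakends.get(chrom, 0) >= min_breakends
        if genome_rate > 0 and enough and rate >= localized_fold * genome_rate:
            return "complex_localized"
    return "scattered"
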