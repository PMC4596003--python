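"""Synthetic tumor-cohort generator with known truth labels.

Every detector in the package is exercised against genomes produced here:
chromothriptic chromosomes (copy-number oscillation between 2-3 integer
states inside a localized shattered region, random join orientations,
retained heterozygosity), breakage-fusion-bridge chromosomes (terminal
telomeric loss next to a highly amplified, fold-back-rich region), kataegis
foci on a sparse mutation background, circular double-minute amplicons,
scattered background rearrangements, and telomeric/random read mixtures.

Distributional choices are package-level conventions (the phenomena are
described in the literature qualitatively, not generatively); see
docs/methods.md for what the generator does and does not emulate.

Stochastic constructions that must satisfy hard detector-facing thresholds
(>= 10 CN switches, non-extreme join orientations) are redrawn up to a
fixed budget and then fail loudly rather than silently emitting negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .catastrophe import random_joins_test
from .errors import ParameterError
from .model import (
    HEAD,
    TAIL,
    Breakend,
    CNSegment,
    GenomeBuild,
    SampleBundle,
    SomaticSNV,
    SVCall,
    TelomereStats,
)
from .mutations import trinucleotide_class
from .telomere import count_telomeric_reads

log = logging.getLogger(__name__)

RETRY_BUDGET = 100
_ORIENT_PAIRS = [(HEAD, TAIL), (TAIL, HEAD), (HEAD, HEAD), (TAIL, TAIL)]
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChromothripsisSim:
    n_fragments: int = 30
    cn_states: Tuple[int, ...] = (2, 3)
    p_retain: float = 0.5
    #: fraction of the chromosome occupied by the shattered region; the
    #: event is localized, which is what the breakpoint-clustering test sees
    region_fraction: float = 0.1


@dataclass(frozen=True)
class BFBSim:
    lost_telomeric_bp: int = 5_000_000
    amplicon_bp: int = 4_000_000
    amplicon_cn: int = 8
    n_foldbacks: int = 20


@dataclass(frozen=True)
class KataegisSim:
    n_foci: int = 3
    mutations_per_focus: int = 8
    focus_span_bp: int = 4_000
    background_rate_per_mb: float = 1.0


@dataclass(frozen=True)
class DMSim:
    k_fragments: int = 6
    fragment_cn: int = 12
    total_length_bp: int = 2_500_000
    n_chromosomes: int = 1


@dataclass(frozen=True)
class TelomereSim:
    read_length: int = 100
    n_reads: int = 10_000
    tumor_fraction: float = 0.01
    normal_fraction: float = 0.02
    tumor_coverage: float = 74.0
    normal_coverage: float = 39.0


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of one synthetic tumor sample."""

    seed: int = 0
    n_chromosomes: int = 22
    chrom_length_bp: int = 100_000_000
    n_chromothripsis_chroms: int = 1
    n_bfb_chroms: int = 1
    n_dm_events: int = 1
    chromothripsis: ChromothripsisSim = ChromothripsisSim()
    bfb: BFBSim = BFBSim()
    kataegis: KataegisSim = KataegisSim()
    dm: DMSim = DMSim()
    background_sv_rate_per_mb: float = 0.05
    telomere: TelomereSim = TelomereSim()

    def __post_init__(self):
        if len(set(self.chromothripsis.cn_states)) not in (2, 3):
            raise ParameterError("cn_states must hold 2 or 3 distinct values")
        if any(c < 0 for c in self.chromothripsis.cn_states):
            raise ParameterError("cn_states must be non-negative")


@dataclass
class TruthLabels:
    """Ground truth emitted alongside a simulated bundle."""

    chrom_labels: Dict[str, str] = field(default_factory=dict)  # none/chromothripsis/bfb/both
    kataegis_foci: List[dict] = field(default_factory=list)
    dm_fragments: List[dict] = field(default_factory=list)
    telomere_tumor_fraction: float = 0.0
    telomere_normal_fraction: float = 0.0

    def to_dict(self):
        return asdict(self)


# ---------------------------------------------------------------------------
# evidence helpers

def _passing_evidence(rng) -> dict:
    return {
        "discordant_pairs": 3 + int(rng.poisson(8)),
        "split_reads": 1 + int(rng.poisson(4)),
        "soft_clip": int(rng.poisson(2)),
    }


def _make_sv(rng, chrom1, pos1, o1, chrom2, pos2, o2, passing=True, name=".") -> SVCall:
    if passing:
        evidence, normal, cov = _passing_evidence(rng), 0, float(rng.uniform(30, 100))
    else:
        mode = rng.integers(3)
        if mode == 0:  # single weak class
            evidence, normal, cov = {"split_reads": int(rng.integers(1, 10))}, 0, 60.0
        elif mode == 1:  # evidence in the matched normal
            evidence, normal, cov = _passing_evidence(rng), 1 + int(rng.poisson(2)), 60.0
        else:  # high-coverage repeat
            evidence, normal, cov = _passing_evidence(rng), 0, float(rng.uniform(1001, 3000))
    return SVCall(Breakend(chrom1, int(pos1), o1), Breakend(chrom2, int(pos2), o2),
                  evidence=evidence, normal_evidence=normal, region_coverage=cov, name=name)


def _neutral_cover(chrom, start, end) -> List[CNSegment]:
    if start >= end:
        return []
    return [CNSegment(chrom, start, end, 2, major_allele_fraction=0.5)]


def _het_maf(cn: int) -> Optional[float]:
    """Major-allele fraction of the most balanced allelic split at a CN."""
    if cn == 0:
        return None
    return max(0.5, float(np.ceil(cn / 2) / cn))


# ---------------------------------------------------------------------------
# chromothripsis

def simulate_chromothripsis_chrom(chrom: str, chrom_length: int,
                                  params: ChromothripsisSim, rng
                                  ) -> Tuple[List[CNSegment], List[SVCall]]:
    """One shattered chromosome: localized CN oscillation plus random joins.

    The shattered region (``region_fraction`` of the chromosome, random
    location) is partitioned into ``n_fragments`` intervals; each is
    independently retained (higher CN state, heterozygous) or lost (lowest
    state, LOH) with ``p_retain``.  Consecutive retained fragments are
    joined by rearrangements with orientations uniform over the four
    head/tail pairs.  Redraws (budget 100) until the profile shows >= 10
    switches and the join orientations are not chi-square-extreme.
    """
    if params.n_fragments < 12:
        raise ParameterError("chromothripsis needs n_fragments >= 12 to admit 10 switches")
    if not (0.0 < params.p_retain < 1.0):
        raise ParameterError("p_retain must be in (0, 1) exclusive")
    states = sorted(set(params.cn_states))
    low, high_states = states[0], states[1:]
    span = int(params.region_fraction * chrom_length)
    if span < params.n_fragments * 1000:
        raise ParameterError("shattered region too small for the fragment count")

    for _ in range(RETRY_BUDGET):
        region_start = int(rng.integers(0, chrom_length - span + 1))
        cuts = np.sort(rng.choice(np.arange(1, span // 1000), size=params.n_fragments - 1,
                                  replace=False)) * 1000
        bounds = np.concatenate([[0], cuts, [span]]) + region_start
        retained_mask = rng.random(params.n_fragments) < params.p_retain
        if not (2 <= retained_mask.sum() <= params.n_fragments - 2):
            continue

        segments: List[CNSegment] = []
        segments += _neutral_cover(chrom, 0, int(bounds[0]))
        retained_frags = []
        for i in range(params.n_fragments):
            start, end = int(bounds[i]), int(bounds[i + 1])
            if retained_mask[i]:
                cn = int(high_states[rng.integers(len(high_states))])
                segments.append(CNSegment(chrom, start, end, cn,
                                          major_allele_fraction=_het_maf(cn)))
                retained_frags.append((start, end))
            else:
                maf = 1.0 if low > 0 else None
                segments.append(CNSegment(chrom, start, end, low,
                                          major_allele_fraction=maf))
        segments += _neutral_cover(chrom, int(bounds[-1]), chrom_length)

        cns = [s.total_cn for s in segments]
        n_switches = sum(1 for a, b in zip(cns, cns[1:]) if a != b)
        if n_switches < 10:
            continue

        svs = []
        for (a_start, a_end), (b_start, b_end) in zip(retained_frags, retained_frags[1:]):
            o1, o2 = _ORIENT_PAIRS[rng.integers(4)]
            svs.append(_make_sv(rng, chrom, a_end, o1, chrom, b_start, o2, passing=True))
        join_p = random_joins_test(svs)
        if join_p is None or join_p < 0.01:
            continue  # clear-margin positives must not look orientation-skewed
        return segments, svs
    raise ParameterError(
        f"could not generate a {params.n_fragments}-fragment chromothriptic "
        f"chromosome within {RETRY_BUDGET} redraws")


# ---------------------------------------------------------------------------
# breakage-fusion-bridge

def simulate_bfb_chrom(chrom: str, chrom_length: int, params: BFBSim, rng
                       ) -> Tuple[List[CNSegment], List[SVCall]]:
    """One BFB chromosome: terminal telomeric loss, adjacent amplicon,
    fold-back inversions confined to the amplicon."""
    if params.lost_telomeric_bp + params.amplicon_bp >= chrom_length:
        raise ParameterError("telomeric loss + amplicon exceed the chromosome")
    if 0 < params.amplicon_cn < 6:
        log.warning("amplicon_cn %d below the amplified threshold (6): "
                    "generating a negative control", params.amplicon_cn)
    segments: List[CNSegment] = []
    amp_start = params.lost_telomeric_bp
    amp_end = amp_start + params.amplicon_bp
    if params.lost_telomeric_bp > 0:
        segments.append(CNSegment(chrom, 0, params.lost_telomeric_bp, 1,
                                  major_allele_fraction=1.0))
    maf = min(0.99, (params.amplicon_cn - 1) / params.amplicon_cn) if params.amplicon_cn > 0 else None
    segments.append(CNSegment(chrom, amp_start, amp_end, params.amplicon_cn,
                              major_allele_fraction=maf if params.amplicon_cn else None))
    segments += _neutral_cover(chrom, amp_end, chrom_length)

    svs = []
    margin = 50_000
    for _ in range(params.n_foldbacks):
        p1 = int(rng.integers(amp_start + margin, amp_end - margin - 30_000))
        p2 = p1 + int(rng.integers(100, 30_000))
        orient = HEAD if rng.random() < 0.5 else TAIL
        svs.append(_make_sv(rng, chrom, p1, orient, chrom, p2, orient, passing=True))
    return segments, svs


# ---------------------------------------------------------------------------
# kataegis

def _random_snv(rng, chrom, pos) -> SomaticSNV:
    ref = str(_BASES[rng.integers(4)])
    alt = str(_BASES[rng.integers(4)])
    while alt == ref:
        alt = str(_BASES[rng.integers(4)])
    c5, c3 = str(_BASES[rng.integers(4)]), str(_BASES[rng.integers(4)])
    snv = SomaticSNV(chrom, int(pos), ref, alt, context5=c5, context3=c3)
    snv.class96 = trinucleotide_class(ref, alt, c5, c3)
    return snv


def _kataegis_snv(rng, chrom, pos) -> SomaticSNV:
    alt = "T" if rng.random() < 0.5 else "G"  # C>T or C>G
    c5, c3 = str(_BASES[rng.integers(4)]), str(_BASES[rng.integers(4)])
    snv = SomaticSNV(chrom, int(pos), "C", alt, context5=c5, context3=c3)
    snv.class96 = trinucleotide_class("C", alt, c5, c3)
    return snv


def simulate_kataegis_snvs(params: KataegisSim, rng, genome: GenomeBuild
                           ) -> Tuple[List[SomaticSNV], List[dict]]:
    """Sparse genome-wide background plus planted hypermutation foci.

    Returns ``(snvs, truth_foci)``; each truth focus records its chromosome,
    planted interval and mutation count.  Foci are redrawn when they fall
    within 1 Mb of an existing focus (budget 100 per focus).
    """
    m = params.mutations_per_focus
    if params.n_foci > 0:
        if m < 2:
            raise ParameterError("a focus needs at least 2 mutations")
        if params.focus_span_bp / (m - 1) > 1000:
            raise ParameterError("focus span too wide for a <= 1 kb mean spacing")
        bg_spacing = 1e6 / params.background_rate_per_mb if params.background_rate_per_mb else np.inf
        if bg_spacing < 100 * params.focus_span_bp / (m - 1):
            raise ParameterError("background too dense relative to focus spacing")

    snvs: List[SomaticSNV] = []
    chroms = list(genome.chrom_names)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    n_bg = int(rng.poisson(params.background_rate_per_mb * lengths.sum() / 1e6))
    for _ in range(n_bg):
        ci = int(rng.choice(len(chroms), p=weights))
        pos = int(rng.integers(0, lengths[ci]))
        snvs.append(_random_snv(rng, chroms[ci], pos))

    truth: List[dict] = []
    placed: List[Tuple[str, int, int]] = []
    for _ in range(params.n_foci):
        for _attempt in range(RETRY_BUDGET):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            start = int(rng.integers(0, int(lengths[ci]) - params.focus_span_bp))
            clash = any(c == chrom and abs(start - s) < 1_000_000 for c, s, _ in placed)
            if not clash:
                break
        else:
            raise ParameterError(f"could not place a focus within {RETRY_BUDGET} redraws")
        offsets = np.sort(rng.choice(params.focus_span_bp, size=m, replace=False))
        positions = [start + int(o) for o in offsets]
        for pos in positions:
            snvs.append(_kataegis_snv(rng, chrom, pos))
        placed.append((chrom, start, start + params.focus_span_bp))
        truth.append({"chrom": chrom, "start": positions[0], "end": positions[-1],
                      "n_mutations": m})
    snvs.sort(key=lambda s: (chroms.index(s.chrom), s.pos))
    return snvs, truth


# ---------------------------------------------------------------------------
# telomere reads

def simulate_telomere_reads(n_reads: int, read_length: int, telomere_fraction: float,
                            rng) -> Tuple[List[str], float]:
    """Mixture of full-length tandem telomeric repeats and i.i.d. random reads.

    Returns ``(reads, truth_fraction)``.  ``read_length`` must be >= 18 so a
    read can contain the triple repeat.
    """
    if read_length < 18:
        raise ParameterError("read_length must be >= 18 to contain the x3 motif")
    if not (0.0 <= telomere_fraction <= 1.0):
        raise ParameterError("telomere_fraction must be in [0, 1]")
    reads: List[str] = []
    is_tel = rng.random(n_reads) < telomere_fraction
    n_random = int((~is_tel).sum())
    random_mat = _BASES[rng.integers(0, 4, size=(n_random, read_length))]
    random_iter = iter("".join(row) for row in random_mat)
    for tel in is_tel:
        if tel:
            motif = "TTAGGG" if rng.random() < 0.5 else "CCCTAA"
            phase = int(rng.integers(6))
            tandem = motif * (read_length // 6 + 2)
            reads.append(tandem[phase:phase + read_length])
        else:
            reads.append(next(random_iter))
    return reads, telomere_fraction


# ---------------------------------------------------------------------------
# double minutes

def simulate_dm(chroms: Sequence[str], chrom_length: int, params: DMSim, rng
                ) -> Tuple[Dict[str, List[CNSegment]], List[SVCall], List[dict]]:
    """A circular amplicon: k amplified fragments joined in a cycle.

    Fragments are placed in disjoint zones of the host chromosome(s); the
    cycle visits them in a random order with random per-fragment
    orientations, and the joining rearrangements carry breakends at the
    fragment ends whose orientations encode the traversal.

    Returns ``(cn_segments_per_chrom, svs, truth_fragments)``.
    """
    k = params.k_fragments
    if k < 1:
        raise ParameterError("a cycle needs at least one fragment")
    # fragment lengths: random split of the total, each >= 5% of the mean
    raw = rng.dirichlet(np.ones(k) * 5.0)
    lengths = np.maximum((raw * params.total_length_bp).astype(int), 50_000)

    host = [chroms[i % len(chroms)] for i in range(k)]
    frags = []
    margin = 2_000_000
    zone = (chrom_length - 2 * margin) // max(1, (k + len(chroms) - 1) // len(chroms))
    per_chrom_count: Dict[str, int] = {}
    for i in range(k):
        c = host[i]
        slot = per_chrom_count.get(c, 0)
        per_chrom_count[c] = slot + 1
        lo = margin + slot * zone
        start = int(rng.integers(lo, lo + zone - int(lengths[i]) - 1))
        frags.append({"chrom": c, "start": start, "end": start + int(lengths[i]),
                      "total_cn": params.fragment_cn})

    per_chrom: Dict[str, List[CNSegment]] = {}
    for c in dict.fromkeys(host):
        own = sorted((f for f in frags if f["chrom"] == c), key=lambda f: f["start"])
        segs: List[CNSegment] = []
        cursor = 0
        for f in own:
            segs += _neutral_cover(c, cursor, f["start"])
            segs.append(CNSegment(c, f["start"], f["end"], f["total_cn"],
                                  major_allele_fraction=0.7))
            cursor = f["end"]
        segs += _neutral_cover(c, cursor, chrom_length)
        per_chrom[c] = segs

    order = list(rng.permutation(k))
    orients = ["+" if rng.random() < 0.5 else "-" for _ in range(k)]
    svs = []
    for i in range(k):
        a, b = frags[order[i]], frags[order[(i + 1) % k]]
        oa, ob = orients[i], orients[(i + 1) % k]
        # exit port of a, entry port of b; right port -> head at end,
        # left port -> tail at start
        pos1, o1 = (a["end"], HEAD) if oa == "+" else (a["start"], TAIL)
        pos2, o2 = (b["start"], TAIL) if ob == "+" else (b["end"], HEAD)
        svs.append(_make_sv(rng, a["chrom"], pos1, o1, b["chrom"], pos2, o2,
                            passing=True, name=f"dm_join_{i}"))
    return per_chrom, svs, frags


# ---------------------------------------------------------------------------
# whole-sample assembly

def simulate_background_svs(genome: GenomeBuild, rate_per_mb: float, rng,
                            p_pass: float = 0.95) -> List[SVCall]:
    """Scattered rearrangements placed uniformly per bp across the genome;
    ~``p_pass`` of them carry filter-passing evidence."""
    chroms = list(genome.chrom_names)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    n = int(rng.poisson(rate_per_mb * lengths.sum() / 1e6))
    svs = []
    for i in range(n):
        passing = bool(rng.random() < p_pass)
        o1, o2 = _ORIENT_PAIRS[rng.integers(4)]
        if rng.random() < 0.8:  # intrachromosomal
            ci = int(rng.choice(len(chroms), p=weights))
            a, b = sorted(rng.integers(0, lengths[ci], size=2))
            if a == b:
                b = min(int(lengths[ci]) - 1, a + 1)
            sv = _make_sv(rng, chroms[ci], a, o1, chroms[ci], b, o2,
                          passing=passing, name=f"bg_{i}")
        else:
            ci, cj = rng.choice(len(chroms), size=2, replace=False, p=weights)
            sv = _make_sv(rng, chroms[int(ci)], int(rng.integers(0, lengths[int(ci)])), o1,
                          chroms[int(cj)], int(rng.integers(0, lengths[int(cj)])), o2,
                          passing=passing, name=f"bg_{i}")
        svs.append(sv.canonicalized(genome))
    return svs


def simulate_sample(params: SimulationParams, sample_id: str = "synthetic"
                    ) -> Tuple[SampleBundle, TruthLabels]:
    """Assemble one full sample bundle plus its truth labels.

    Deterministic given ``params`` (including the seed).  Event chromosomes
    (chromothripsis, BFB, double minute) are drawn without replacement; all
    remaining chromosomes are copy-neutral with background rearrangements
    only.
    """
    rng = np.random.default_rng(params.seed)
    genome = GenomeBuild.synthetic(params.n_chromosomes, params.chrom_length_bp)
    chroms = list(genome.chrom_names)

    n_events = params.n_chromothripsis_chroms + params.n_bfb_chroms + (
        params.n_dm_events * params.dm.n_chromosomes)
    if n_events > len(chroms):
        raise ParameterError("more event chromosomes requested than chromosomes simulated")
    picked = list(rng.choice(len(chroms), size=n_events, replace=False))
    ct_chroms = [chroms[int(i)] for i in picked[:params.n_chromothripsis_chroms]]
    bfb_chroms = [chroms[int(i)] for i in
                  picked[params.n_chromothripsis_chroms:
                         params.n_chromothripsis_chroms + params.n_bfb_chroms]]
    dm_chroms = [chroms[int(i)] for i in
                 picked[params.n_chromothripsis_chroms + params.n_bfb_chroms:]]

    truth = TruthLabels(chrom_labels={c: "none" for c in chroms})
    cn_segments: Dict[str, List[CNSegment]] = {}
    svs: List[SVCall] = []

    for chrom in bfb_chroms:
        segs, chrom_svs = simulate_bfb_chrom(
            chrom, genome.chrom_lengths[chrom], params.bfb, rng)
        cn_segments[chrom] = segs
        svs += [sv.canonicalized(genome) for sv in chrom_svs]
        truth.chrom_labels[chrom] = "bfb"

    if params.n_dm_events and dm_chroms:
        dm_cn, dm_svs, dm_frags = simulate_dm(
            dm_chroms, params.chrom_length_bp, params.dm, rng)
        cn_segments.update(dm_cn)
        svs += [sv.canonicalized(genome) for sv in dm_svs]
        truth.dm_fragments = dm_frags

    for chrom in chroms:
        if chrom not in cn_segments:
            cn_segments[chrom] = _neutral_cover(chrom, 0, genome.chrom_lengths[chrom])

    # Chromothriptic chromosomes and background rearrangements are drawn
    # jointly: clear-margin truth means every shattered chromosome must be
    # unambiguously clustered (KS p <= 1e-4) and orientation-balanced
    # (chi-square p >= 0.01) on the combined join set the detector will
    # actually see, so draws eroding either margin are redrawn together
    # (same retry-until-criterion policy as the per-chromosome generators).
    from .catastrophe import ks_clustering_test
    for _ in range(RETRY_BUDGET):
        ct_segments: Dict[str, List[CNSegment]] = {}
        ct_svs: List[SVCall] = []
        for chrom in ct_chroms:
            segs, chrom_svs = simulate_chromothripsis_chrom(
                chrom, genome.chrom_lengths[chrom], params.chromothripsis, rng)
            ct_segments[chrom] = segs
            ct_svs += [sv.canonicalized(genome) for sv in chrom_svs]
        background = simulate_background_svs(genome, params.background_sv_rate_per_mb, rng)
        combined = svs + ct_svs + background
        ok = True
        for chrom in ct_chroms:
            positions = [bnd.pos for sv in combined
                         for bnd in (sv.bnd1, sv.bnd2) if bnd.chrom == chrom]
            p, small_n = ks_clustering_test(positions, genome.chrom_lengths[chrom])
            joins = [sv for sv in combined
                     if sv.bnd1.chrom == chrom and sv.bnd2.chrom == chrom]
            join_p = random_joins_test(joins)
            if small_n or p > 1e-4 or join_p is None or join_p < 0.01:
                ok = False
                break
        if ok:
            cn_segments.update(ct_segments)
            for chrom in ct_chroms:
                truth.chrom_labels[chrom] = "chromothripsis"
            svs += ct_svs + background
            break
    else:
        raise ParameterError(
            f"could not draw shattered chromosomes with clear clustering and "
            f"join-orientation margins within {RETRY_BUDGET} redraws")

    snvs, kat_truth = simulate_kataegis_snvs(params.kataegis, rng, genome)
    truth.kataegis_foci = kat_truth

    tel = params.telomere
    tumor_reads, truth.telomere_tumor_fraction = simulate_telomere_reads(
        tel.n_reads, tel.read_length, tel.tumor_fraction, rng)
    normal_reads, truth.telomere_normal_fraction = simulate_telomere_reads(
        tel.n_reads, tel.read_length, tel.normal_fraction, rng)
    tumor_count = count_telomeric_reads(tumor_reads, tel.tumor_coverage)
    normal_count = count_telomeric_reads(normal_reads, tel.normal_coverage)

    bundle = SampleBundle(
        sample_id=sample_id,
        genome=genome,
        snvs=snvs,
        svs=svs,
        cn_segments=cn_segments,
        telomere_stats=TelomereStats(
            tumor_count=tumor_count.n_telomeric_reads,
            tumor_mean_coverage=tel.tumor_coverage,
            normal_count=normal_count.n_telomeric_reads,
            normal_mean_coverage=tel.normal_coverage,
        ),
    )
    bundle.validate()
    return bundle, truth
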