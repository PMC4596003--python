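"""Mutation-spectrum and localized-hypermutation (kataegis) analysis.

Substitutions are pyrimidine-normalized into six classes
(C>A, C>G, C>T, T>A, T>C, T>G); combined with the 5' and 3' flanking bases
this gives the standard 96-context classification.

Kataegis is called from intermutation distances (IMD, bp between
consecutive mutations on a chromosome): the log10(IMD) series is segmented
by exact penalized least-squares piecewise-constant fitting (penalty
``gamma`` per changepoint, minimum segment length ``kmin``), and a segment
qualifies as a focus when it covers six or more consecutive mutations with
an arithmetic mean raw IMD of at most 1,000 bp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, OrderingError, SequenceError, ValidationError
from .model import COMPLEMENT, NUCLEOTIDES, GenomeBuild, SomaticSNV

log = logging.getLogger(__name__)

#: pyrimidine-normalized substitution classes, fixed display order
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_SUB_INDEX = {("C", "A"): 0, ("C", "G"): 1, ("C", "T"): 2,
              ("T", "A"): 3, ("T", "C"): 4, ("T", "G"): 5}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class KataegisParams:
    """Tunable thresholds of the kataegis caller.

    ``pcf_gamma`` is the per-changepoint penalty applied to the log10(IMD)
    series (the segmentation's "c" parameter); ``numerous_threshold`` splits
    the per-sample burden labels occasional/numerous.
    """

    pcf_gamma: float = 25.0
    pcf_kmin: int = 2
    min_focus_mutations: int = 6
    max_mean_imd_bp: float = 1000.0
    numerous_threshold: int = 10


@dataclass
class KataegisFocus:
    chrom: str
    start: int
    end: int
    n_mutations: int
    mean_imd: float
    strand_classes: Dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# 96-context classification

def trinucleotide_class(ref: str, alt: str, base5: str, base3: str) -> int:
    """96-context class index for a substitution with its flanking bases.

    Purine-reference substitutions are reverse-complemented (ref, alt and
    flanks swapped and complemented) before indexing.  The index is
    ``16*sub_class + 4*idx(5') + idx(3')`` with substitution classes ordered
    C>A, C>G, C>T, T>A, T>C, T>G and bases ordered A, C, G, T.
    """
    for b in (ref, alt, base5, base3):
        if b not in NUCLEOTIDES:
            raise SequenceError(f"invalid base {b!r}")
    if ref == alt:
        raise ValidationError("ref equals alt")
    if ref in ("A", "G"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        base5, base3 = COMPLEMENT[base3], COMPLEMENT[base5]
    return 16 * _SUB_INDEX[(ref, alt)] + 4 * _BASE_INDEX[base5] + _BASE_INDEX[base3]


def class96_label(index: int) -> str:
    """Human-readable label, e.g. ``A[C>T]G``."""
    sub = SUB_CLASSES[index // 16]
    b5 = NUCLEOTIDES[(index % 16) // 4]
    b3 = NUCLEOTIDES[index % 4]
    return f"{b5}[{sub}]{b3}"


CLASS96_LABELS = tuple(class96_label(i) for i in range(96))


def annotate_class96(snv: SomaticSNV) -> SomaticSNV:
    if snv.context5 is None or snv.context3 is None:
        raise AnnotationError(f"SNV at {snv.chrom}:{snv.pos} lacks trinucleotide context")
    snv.class96 = trinucleotide_class(snv.ref_base, snv.alt_base, snv.context5, snv.context3)
    return snv


def substitution_class(snv: SomaticSNV) -> str:
    """Pyrimidine-normalized class label (e.g. 'C>T') of one SNV."""
    ref, alt = snv.ref_base, snv.alt_base
    if ref in ("A", "G"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum_matrix(samples: Dict[str, Sequence[SomaticSNV]]) -> pd.DataFrame:
    """96 x n_samples count matrix (rows in fixed class order).

    Every SNV must be context-annotated (``class96`` set, or flanks present
    so the class can be computed); column sums equal per-sample SNV counts.
    """
    counts = {}
    for sample_id, snvs in samples.items():
        col = np.zeros(96, dtype=int)
        for snv in snvs:
            c = snv.class96
            if c is None:
                if snv.context5 is None or snv.context3 is None:
                    raise AnnotationError(
                        f"sample {sample_id}: SNV at {snv.chrom}:{snv.pos} unannotated")
                c = trinucleotide_class(snv.ref_base, snv.alt_base, snv.context5, snv.context3)
            col[c] += 1
        counts[sample_id] = col
    return pd.DataFrame(counts, index=list(CLASS96_LABELS))


def write_spectrum_tsv(path, matrix: pd.DataFrame):
    matrix.rename_axis("context").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Intermutation distances

def intermutation_distances(positions: Sequence[int]) -> List[int]:
    """Distances between consecutive sorted positions on one chromosome.

    The input must be non-decreasing (:class:`OrderingError` otherwise);
    duplicate positions are collapsed to one (logged).  Fewer than two
    distinct positions give an empty list.
    """
    prev = None
    distinct = []
    n_dups = 0
    for p in positions:
        if prev is not None and p < prev:
            raise OrderingError("positions must be sorted before IMD computation")
        if p == prev:
            n_dups += 1
        else:
            distinct.append(p)
        prev = p
    if n_dups:
        log.info("collapsed %d duplicate mutation position(s)", n_dups)
    return [b - a for a, b in zip(distinct, distinct[1:])]


# ---------------------------------------------------------------------------
# Exact piecewise-constant fitting

def pcf_segment(values: Sequence[float], gamma: float = 25.0, kmin: int = 2):
    """Exact penalized least-squares segmentation of a 1-D series.

    Minimizes ``sum of within-segment squared deviations + gamma * (n_segments
    - 1)`` over all segmentations with every segment length >= ``kmin``,
    by dynamic programming in O(n^2).  Ties (within a small numerical
    tolerance) break toward fewer segments, then toward earlier boundaries.

    Returns ``(segments, flagged)`` where ``segments`` is a list of
    ``(start, end, mean)`` half-open index ranges and ``flagged`` is True
    when ``kmin > n`` forced a single segment.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        raise ValidationError("pcf_segment needs a non-empty series")
    if gamma <= 0 or kmin < 1:
        raise ValidationError("gamma must be > 0 and kmin >= 1")
    if kmin > n:
        return [(0, n, float(x.mean()))], True

    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    INF = float("inf")
    best_cost = np.full(n + 1, INF)   # best_cost[j]: optimum for x[:j]
    best_nseg = np.zeros(n + 1, dtype=int)
    prev_cut = np.zeros(n + 1, dtype=int)
    best_cost[0] = 0.0

    for j in range(kmin, n + 1):
        # i is the start of the last segment; i == 0 is the first segment
        # (no changepoint penalty), otherwise the prefix x[:i] must itself
        # be segmentable (best_cost[i] finite)
        cand = np.concatenate([[0], np.arange(kmin, j - kmin + 1)]).astype(int)
        feasible = np.isfinite(best_cost[cand])
        cand = cand[feasible]
        if cand.size == 0:
            continue
        s = s1[j] - s1[cand]
        sse = np.maximum(0.0, (s2[j] - s2[cand]) - s * s / (j - cand))
        cost = best_cost[cand] + sse + np.where(cand > 0, gamma, 0.0)
        cmin = cost.min()
        tol = 1e-9 * (1.0 + abs(cmin))
        tied = np.flatnonzero(cost <= cmin + tol)
        # ties break toward fewer segments, then earlier last boundary
        order = sorted(tied, key=lambda k: (best_nseg[cand[k]] + 1, cand[k]))
        k = order[0]
        best_cost[j] = cost[k]
        best_nseg[j] = best_nseg[cand[k]] + 1
        prev_cut[j] = cand[k]
    cuts = []
    j = n
    while j > 0:
        cuts.append((int(prev_cut[j]), int(j)))
        j = int(prev_cut[j])
    segments = [(i, j, float(x[i:j].mean())) for i, j in reversed(cuts)]
    return segments, False


def pcf_cost(values: Sequence[float], segments, gamma: float) -> float:
    """Objective value of a segmentation (used for oracle comparison)."""
    x = np.asarray(values, dtype=float)
    total = 0.0
    for i, j, _ in segments:
        seg = x[i:j]
        total += float(((seg - seg.mean()) ** 2).sum())
    return total + gamma * (len(segments) - 1)


# ---------------------------------------------------------------------------
# Kataegis calling

def call_kataegis(snvs: Sequence[SomaticSNV], genome: GenomeBuild,
                  params: KataegisParams = KataegisParams()) -> List[KataegisFocus]:
    """Identify kataegis foci in one sample.

    All mutations are ordered by chromosomal position genome-wide (one
    series per sample); IMDs of the de-duplicated positions are computed on
    the concatenated coordinate; log10(IMD) is segmented with exact PCF.  A
    segment covering ``m`` IMD values spans ``m + 1`` consecutive mutations
    and is reported as a focus iff ``m + 1 >= min_focus_mutations`` and the
    arithmetic mean of the raw IMDs is <= ``max_mean_imd_bp``.
    """
    for snv in snvs:
        genome.check_position(snv.chrom, snv.pos, "SNV")

    # one per-sample series: mutations ordered by chromosomal position
    # genome-wide, IMDs taken between consecutive mutations on the
    # concatenated coordinate (cross-chromosome distances are huge, so a
    # qualifying <= 1 kb segment can never straddle a boundary)
    offsets: Dict[str, int] = {}
    running = 0
    for chrom in genome.chrom_names:
        offsets[chrom] = running
        running += genome.chrom_lengths[chrom]

    ordered = sorted(snvs, key=lambda s: offsets[s.chrom] + s.pos)
    distinct: List[SomaticSNV] = []
    seen = set()
    n_dups = 0
    for m in ordered:
        key = (m.chrom, m.pos)
        if key in seen:
            n_dups += 1
            continue
        seen.add(key)
        distinct.append(m)
    if n_dups:
        log.info("collapsed %d duplicate mutation position(s)", n_dups)

    positions = [offsets[m.chrom] + m.pos for m in distinct]
    imds = [b - a for a, b in zip(positions, positions[1:])]
    if not imds:
        return []
    log_imds = np.log10(np.asarray(imds, dtype=float))
    segments, _ = pcf_segment(log_imds, params.pcf_gamma, params.pcf_kmin)

    foci: List[KataegisFocus] = []
    for i, j, _mean in segments:
        run = _longest_qualifying_run(
            imds, i, j, params.min_focus_mutations - 1, params.max_mean_imd_bp)
        if run is None:
            continue
        a, b = run  # IMD index window -> mutations a .. b inclusive
        members = distinct[a:b + 1]
        chroms = {snv.chrom for snv in members}
        if len(chroms) != 1:  # unreachable for sub-kb spacing; guard anyway
            continue
        classes: Dict[str, int] = {}
        for snv in members:
            classes[substitution_class(snv)] = classes.get(substitution_class(snv), 0) + 1
        foci.append(KataegisFocus(
            chrom=members[0].chrom,
            start=members[0].pos,
            end=members[-1].pos,
            n_mutations=b - a + 1,
            mean_imd=sum(imds[a:b]) / (b - a),
            strand_classes=classes,
        ))
    return foci


def _longest_qualifying_run(imds, i, j, min_imds, max_mean):
    """Longest window of >= ``min_imds`` consecutive IMDs within segment
    [i, j) with arithmetic mean <= ``max_mean``; earliest window on ties.

    A segment "contains six or more consecutive mutations with an average
    intermutation distance <= 1,000 bp" exactly when such a window exists.
    Returns ``(a, b)`` with the run covering mutations a..b, or None.
    Search is O(m log m) via prefix sums of (imd - max_mean).
    """
    seg = np.asarray(imds[i:j], dtype=float) - max_mean
    m = len(seg)
    if m < min_imds:
        return None
    prefix = np.concatenate([[0.0], np.cumsum(seg)])  # window sum = P[b] - P[a]
    # Q[a] = max(P[0..a]) is non-decreasing: binary search for the smallest
    # a whose prefix can dominate P[b], giving the longest window ending at b
    Q = np.maximum.accumulate(prefix)
    best = None
    for b in range(min_imds, m + 1):
        limit = b - min_imds  # latest admissible window start
        # smallest a with Q[a] >= P[b]; minimality forces P[a] = Q[a],
        # so a itself starts a window with sum <= 0
        a = int(np.searchsorted(Q[:limit + 1], prefix[b] - 1e-9))
        if a <= limit and (best is None or b - a > best[1] - best[0]):
            best = (a, b)
    if best is None:
        return None
    return i + best[0], i + best[1]


def kataegis_burden(n_foci: int, params: KataegisParams = KataegisParams()) -> str:
    """Per-sample burden label: none / occasional (<10 foci) / numerous (>=10)."""
    if n_foci < 0:
        raise ValidationError("focus count must be >= 0")
    if n_foci == 0:
        return "none"
    return "numerous" if n_foci >= params.numerous_threshold else "occasional"


def rainfall_table(snvs: Sequence[SomaticSNV], genome: GenomeBuild) -> pd.DataFrame:
    """Per-mutation table (chrom, pos, imd, class) for rainfall plots;
    the first mutation of each chromosome has no IMD (NaN)."""
    rows = []
    by_chrom: Dict[str, List[SomaticSNV]] = {}
    for snv in snvs:
        by_chrom.setdefault(snv.chrom, []).append(snv)
    for chrom in genome.chrom_names:
        muts = sorted(by_chrom.get(chrom, []), key=lambda s: s.pos)
        prev = None
        for m in muts:
            rows.append({
                "chrom": chrom,
                "pos": m.pos,
                "imd": (m.pos - prev) if prev is not None else float("nan"),
                "class": substitution_class(m),
            })
            prev = m.pos
    return pd.DataFrame(rows, columns=["chrom", "pos", "imd", "class"])
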