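"""Structural-variant confidence filtering and eight-way classification.

A call is high-confidence when it is supported by at least two independent
evidence classes (discordant read pairs, split reads, soft clipping), or by
a single class with >= 10 supporting reads, has no supporting evidence in
the matched normal, and does not sit in a high-coverage (>1000x) repeat
region.

Typing integrates the read-pair orientation of the junction with
allele-specific copy-number segments: breakends matched to segment
boundaries within +/- 30 kb refine orientation-only labels into
deletion / tandem-duplication / fold-back calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import SequenceError, StatisticsError
from .model import (
    EVIDENCE_CLASSES,
    HEAD,
    NUCLEOTIDES,
    SV_TYPES,
    TAIL,
    GenomeBuild,
    SVCall,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceRule:
    """Thresholds of the high-confidence call filter."""

    min_evidence_classes: int = 2
    min_reads_single_class: int = 10
    max_normal_evidence: int = 0
    max_repeat_coverage: float = 1000.0


@dataclass(frozen=True)
class MatchParams:
    """Windows used when matching breakends to CN boundaries and landmarks."""

    cn_boundary_window_bp: int = 30_000
    special_region_window_bp: int = 100_000
    foldback_max_span_bp: int = 30_000


def filter_high_confidence(sv: SVCall, rule: EvidenceRule = EvidenceRule()) -> Tuple[bool, Optional[str]]:
    """Apply the high-confidence evidence filter.

    Returns ``(passed, reject_reason)``; the reason names the first failed
    clause (``evidence``, ``normal-evidence`` or ``repeat-coverage``).
    """
    counts = [sv.evidence.get(c, 0) for c in EVIDENCE_CLASSES]
    n_classes = sum(1 for c in counts if c >= 1)
    strong_single = n_classes == 1 and max(counts) >= rule.min_reads_single_class
    if not (n_classes >= rule.min_evidence_classes or strong_single):
        return False, "evidence"
    if sv.normal_evidence > rule.max_normal_evidence:
        return False, "normal-evidence"
    if sv.region_coverage > rule.max_repeat_coverage:
        return False, "repeat-coverage"
    return True, None


def filter_sv_calls(svs: Sequence[SVCall], rule: EvidenceRule = EvidenceRule()):
    """Split calls into (passing, reject-reason counts)."""
    passing, reasons = [], {}
    for sv in svs:
        ok, reason = filter_high_confidence(sv, rule)
        if ok:
            passing.append(sv)
        else:
            reasons[reason] = reasons.get(reason, 0) + 1
    return passing, reasons


# ---------------------------------------------------------------------------
# Eight-way typing

def _boundaries_match(seg, sv, window):
    """Both segment boundaries within the window of the two ordered breakends."""
    return (abs(seg.start - sv.bnd1.pos) <= window
            and abs(seg.end - sv.bnd2.pos) <= window)


def _overlaps_span(seg, sv):
    return seg.start < sv.bnd2.pos and seg.end > sv.bnd1.pos


def _contains(seg, pos):
    return seg.start <= pos < seg.end


def _cn_step_near(segments, pos, window):
    """A boundary between two consecutive segments with unequal total CN
    within +/- window of pos."""
    for a, b in zip(segments, segments[1:]):
        if a.end == b.start and a.total_cn != b.total_cn and abs(a.end - pos) <= window:
            return True
    return False


def classify_sv(sv: SVCall, segments: Sequence, params: MatchParams = MatchParams()) -> str:
    """Assign one of the eight rearrangement type labels.

    ``segments`` are the state-classified CN segments of the SV's chromosome
    (ignored for translocations).  The decision table is first-match-wins:

    1. different chromosomes -> translocation;
    2. (head, tail) deletion-type join whose breakends boundary-match a
       loss segment (+/- 30 kb each) -> deletion;
    3. (tail, head) duplication-type join boundary-matching a gain/amplified
       segment -> tandem_duplication; overlapping such a segment without the
       boundary match -> duplication;
    4. same-orientation join: span <= foldback_max_span with a CN step near
       either breakend -> foldback_inversion; both breakends inside
       amplified segments -> amplified_inversion; else -> inversion;
    5. anything else -> intrachromosomal.
    """
    if sv.is_interchromosomal:
        return "translocation"
    window = params.cn_boundary_window_bp
    o = sv.orientation_pair
    if o == (HEAD, TAIL):
        for seg in segments:
            if seg.state == "loss" and _boundaries_match(seg, sv, window):
                return "deletion"
    elif o == (TAIL, HEAD):
        gainlike = [s for s in segments if s.state in ("gain", "amplified")]
        for seg in gainlike:
            if _boundaries_match(seg, sv, window):
                return "tandem_duplication"
        for seg in gainlike:
            if _overlaps_span(seg, sv):
                return "duplication"
    else:  # (head, head) or (tail, tail)
        span = sv.bnd2.pos - sv.bnd1.pos
        if span <= params.foldback_max_span_bp and (
            _cn_step_near(segments, sv.bnd1.pos, window)
            or _cn_step_near(segments, sv.bnd2.pos, window)
        ):
            return "foldback_inversion"
        amp = [s for s in segments if s.state == "amplified"]
        if any(_contains(s, sv.bnd1.pos) for s in amp) and any(
            _contains(s, sv.bnd2.pos) for s in amp
        ):
            return "amplified_inversion"
        return "inversion"
    return "intrachromosomal"


def classify_sv_calls(svs: Sequence[SVCall], cn_segments: dict,
                      params: MatchParams = MatchParams()) -> List[SVCall]:
    """Type every call in place of its chromosome's segments; returns new calls."""
    out = []
    for sv in svs:
        segs = cn_segments.get(sv.bnd1.chrom, []) if not sv.is_interchromosomal else []
        out.append(replace(sv, sv_type=classify_sv(sv, segs, params)))
    return out


_warned_no_centromere = set()


def annotate_special_regions(sv: SVCall, genome: GenomeBuild,
                             params: MatchParams = MatchParams()) -> SVCall:
    """Flag breakends within 100 kb of a telomere (chromosome end) or of the
    centromere interval; near_centromere is False (logged once) when the
    build has no centromere table."""
    window = params.special_region_window_bp
    near_tel = False
    near_cen = False
    for bnd in (sv.bnd1, sv.bnd2):
        length = genome.length(bnd.chrom)
        if bnd.pos <= window or (length - 1 - bnd.pos) <= window:
            near_tel = True
        cen = (genome.centromeres or {}).get(bnd.chrom)
        if cen is None:
            if bnd.chrom not in _warned_no_centromere:
                log.info("no centromere interval for %s; near_centromere left False", bnd.chrom)
                _warned_no_centromere.add(bnd.chrom)
            continue
        if cen[0] - window <= bnd.pos < cen[1] + window:
            near_cen = True
    return replace(sv, near_telomere=near_tel, near_centromere=near_cen)


# ---------------------------------------------------------------------------
# Microhomology

def compute_microhomology(left_flank: str, right_flank: str, max_check: int = 20) -> int:
    """Longest L <= max_check with the last L bases of ``left_flank`` equal
    to the first L bases of ``right_flank`` (junction microhomology)."""
    left = left_flank.upper()
    right = right_flank.upper()
    for seq in (left, right):
        if any(b not in NUCLEOTIDES for b in seq):
            raise SequenceError(f"non-ACGT character in flank {seq!r}")
    limit = min(max_check, len(left), len(right))
    for L in range(limit, 0, -1):
        if left[-L:] == right[:L]:
            return L
    return 0


# ---------------------------------------------------------------------------
# Per-type prevalence comparison between sample groups

def sv_type_fractions(svs: Sequence[SVCall]) -> dict:
    """Fraction of calls per type (types must be assigned)."""
    n = len(svs)
    counts = {t: 0 for t in SV_TYPES}
    for sv in svs:
        counts[sv.sv_type] += 1
    return {t: (c / n if n else 0.0) for t, c in counts.items()}


def sv_type_prevalence_test(group_a: Sequence[dict], group_b: Sequence[dict]) -> dict:
    """Welch two-sample t-test per SV type on per-sample type fractions.

    ``group_a``/``group_b`` are lists of per-sample fraction dicts (as from
    :func:`sv_type_fractions`).  Returns ``{type: {"t":, "p":, "degenerate":}}``;
    a type where one group has zero variance and the group means are equal is
    flagged degenerate with NaN p.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise StatisticsError("each group needs at least 2 samples")
    out = {}
    for t in SV_TYPES:
        a = np.array([frac.get(t, 0.0) for frac in group_a])
        b = np.array([frac.get(t, 0.0) for frac in group_b])
        degenerate = (a.var(ddof=1) == 0 or b.var(ddof=1) == 0) and math.isclose(
            a.mean(), b.mean())
        if degenerate:
            out[t] = {"t": 0.0, "p": float("nan"), "degenerate": True}
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        out[t] = {"t": float(res.statistic), "p": float(res.pvalue), "degenerate": False}
    return out
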