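"""Per-sample orchestration and cohort aggregation.

Stage order: evidence filter -> SV typing -> CN state classification ->
break-rate and clustering statistics -> per-chromosome chromothripsis/BFB
verdicts -> genome subtyping -> kataegis -> telomere ratio -> amplicon
cycles.  Every threshold lives in one :class:`PipelineConfig` so a run is
reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import amplicon as amplicon_mod
from .catastrophe import (
    BFBCriteria,
    ChromothripsisCriteria,
    CNStateThresholds,
    assess_chromosome,
    breaks_per_mb,
    classify_segments,
    subtype_genome,
)
from .errors import AggregationError
from .model import SampleBundle, group_svs_by_chrom
from .mutations import KataegisParams, call_kataegis, kataegis_burden
from .svclass import (
    EvidenceRule,
    MatchParams,
    annotate_special_regions,
    classify_sv_calls,
    filter_sv_calls,
    sv_type_fractions,
)
from .telomere import TelomereCount, telomere_ratio

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage's parameters in one place (defaults are the published
    thresholds: >= 450 SVs unstable, 10 switches, CN >= 6 amplified,
    <= 1,000 bp mean IMD, PCF gamma 25 / kmin 2, +/- 30 kb CN matching,
    100 kb landmark windows, > 1000x repeat coverage, >= 10 single-class
    reads, 3x break-rate rule, P < 0.001 clustering)."""

    evidence: EvidenceRule = EvidenceRule()
    matching: MatchParams = MatchParams()
    cn_thresholds: CNStateThresholds = CNStateThresholds()
    chromothripsis: ChromothripsisCriteria = ChromothripsisCriteria()
    bfb: BFBCriteria = BFBCriteria()
    kataegis: KataegisParams = KataegisParams()
    unstable_min_svs: int = 450
    localized_fold: float = 3.0
    amplicon_max_fragments: int = 12


@dataclass
class SampleReport:
    sample_id: str
    subtype: str
    n_svs_total: int
    n_svs_high_confidence: int
    reject_reasons: Dict[str, int]
    n_snvs: int
    sv_type_counts: Dict[str, int]
    genome_break_rate: float
    verdicts: list
    chromothripsis_chroms: List[str]
    bfb_chroms: List[str]
    kataegis_foci: list
    kataegis_burden: str
    telomere_ratio: Optional[float]
    amplicon_cycles: list
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["verdicts"] = [dataclasses.asdict(v) for v in self.verdicts]
        out["kataegis_foci"] = [dataclasses.asdict(f) for f in self.kataegis_foci]
        out["amplicon_cycles"] = [amplicon_mod.score_amplicon(c) for c in self.amplicon_cycles]
        return out


def run_sample(bundle: SampleBundle, config: PipelineConfig = PipelineConfig()) -> SampleReport:
    """Run the full analysis on one validated sample bundle."""
    bundle.validate()
    genome = bundle.genome

    passing, reasons = filter_sv_calls(bundle.svs, config.evidence)
    log.info("%s: %d/%d SVs pass the high-confidence filter (rejects: %s)",
             bundle.sample_id, len(passing), len(bundle.svs), reasons or "none")

    segments = classify_segments(bundle.cn_segments, config.cn_thresholds)
    typed = classify_sv_calls(passing, segments, config.matching)
    typed = [annotate_special_regions(sv, genome, config.matching) for sv in typed]

    chrom_rates, genome_rate = breaks_per_mb(typed, genome)
    breakends = {c: len(p) for c, p in group_svs_by_chrom(typed).items()}

    verdicts = [
        assess_chromosome(chrom, segments.get(chrom, []), typed, genome,
                          config.chromothripsis, config.bfb)
        for chrom in genome.chrom_names
    ]
    subtype = subtype_genome(len(typed), chrom_rates, genome_rate, breakends,
                             config.unstable_min_svs, config.localized_fold)

    foci = call_kataegis(bundle.snvs, genome, config.kataegis)

    ratio = None
    if bundle.telomere_stats is not None:
        ts = bundle.telomere_stats
        tumor = TelomereCount(ts.tumor_count, 0, ts.tumor_mean_coverage)
        normal = TelomereCount(ts.normal_count, 0, ts.normal_mean_coverage)
        ratio = telomere_ratio(tumor, normal)

    amplified = [seg for segs in segments.values() for seg in segs if seg.state == "amplified"]
    graph = amplicon_mod.build_breakpoint_graph(
        amplified, typed, config.matching.cn_boundary_window_bp)
    cycles = amplicon_mod.find_circular_amplicons(graph, config.amplicon_max_fragments)

    counts: Dict[str, int] = {}
    for sv in typed:
        counts[sv.sv_type] = counts.get(sv.sv_type, 0) + 1

    return SampleReport(
        sample_id=bundle.sample_id,
        subtype=subtype,
        n_svs_total=len(bundle.svs),
        n_svs_high_confidence=len(typed),
        reject_reasons=reasons,
        n_snvs=len(bundle.snvs),
        sv_type_counts=counts,
        genome_break_rate=genome_rate,
        verdicts=verdicts,
        chromothripsis_chroms=[v.chrom for v in verdicts if v.chromothripsis],
        bfb_chroms=[v.chrom for v in verdicts if v.bfb],
        kataegis_foci=foci,
        kataegis_burden=kataegis_burden(len(foci), config.kataegis),
        telomere_ratio=ratio,
        amplicon_cycles=cycles,
    )


@dataclass
class CohortSummary:
    n_samples: int
    n_chromothripsis_positive: int
    fraction_chromothripsis_positive: float
    n_bfb_positive: int
    subtype_counts: Dict[str, int]
    kataegis_burden_counts: Dict[str, int]

    def to_dict(self):
        return dataclasses.asdict(self)


def aggregate_cohort(reports: List[SampleReport]) -> CohortSummary:
    """Tabulate per-sample reports into cohort-level counts and fractions."""
    if not reports:
        raise AggregationError("cohort aggregation needs at least one report")
    ids = [r.sample_id for r in reports]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise AggregationError(f"duplicate sample id(s): {dup}")
    n = len(reports)
    n_ct = sum(1 for r in reports if r.chromothripsis_chroms)
    n_bfb = sum(1 for r in reports if r.bfb_chroms)
    subtype_counts: Dict[str, int] = {}
    burden_counts: Dict[str, int] = {}
    for r in reports:
        subtype_counts[r.subtype] = subtype_counts.get(r.subtype, 0) + 1
        burden_counts[r.kataegis_burden] = burden_counts.get(r.kataegis_burden, 0) + 1
    return CohortSummary(
        n_samples=n,
        n_chromothripsis_positive=n_ct,
        fraction_chromothripsis_positive=n_ct / n,
        n_bfb_positive=n_bfb,
        subtype_counts=subtype_counts,
        kataegis_burden_counts=burden_counts,
    )
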