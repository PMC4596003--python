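"""Core domain types shared by every analysis stage.

Coordinate convention: all positions are 0-based and intervals half-open
inside the package.  1-based conventions (VCF, inclusive TSV) exist only at
the I/O boundary (see :mod:`chromocat.io`).

Breakend orientation convention: ``head`` means the sequence retained through
the junction lies at coordinates <= pos (the junction continues from the
lower-coordinate side); ``tail`` means the retained sequence lies at
coordinates >= pos.  Under this convention a deletion-type junction is
(head, tail) on its ordered breakends and a tandem-duplication-type junction
is (tail, head); BEDPE strands map '+' -> head, '-' -> tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import CoordinateError, ValidationError

HEAD = "head"
TAIL = "tail"
ORIENTATIONS = (HEAD, TAIL)

#: the eight rearrangement type labels
SV_TYPES = (
    "deletion",
    "duplication",
    "tandem_duplication",
    "foldback_inversion",
    "amplified_inversion",
    "inversion",
    "intrachromosomal",
    "translocation",
)

#: copy-number state labels
CN_STATES = ("loss", "neutral", "cn_loh", "gain", "amplified")

EVIDENCE_CLASSES = ("discordant_pairs", "split_reads", "soft_clip")

NUCLEOTIDES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome name/length table with optional centromere intervals.

    Only coordinates are carried — no sequence.  ``centromeres`` maps a
    chromosome name to a half-open (start, end) interval in bp.
    """

    chrom_names: tuple
    chrom_lengths: Mapping
    centromeres: Optional[Mapping] = None

    def __post_init__(self):
        for name in self.chrom_names:
            length = self.chrom_lengths.get(name)
            if length is None or length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive or missing length")
        if self.centromeres:
            for name, (start, end) in self.centromeres.items():
                if name not in self.chrom_lengths:
                    raise ValidationError(f"centromere on unknown chromosome {name!r}")
                if not (0 <= start < end <= self.chrom_lengths[name]):
                    raise ValidationError(
                        f"centromere interval ({start}, {end}) outside chromosome {name!r}"
                    )

    def __contains__(self, chrom):
        return chrom in self.chrom_lengths

    def length(self, chrom):
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise CoordinateError(f"chromosome {chrom!r} absent from genome build") from None

    def chrom_index(self, chrom):
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise CoordinateError(f"chromosome {chrom!r} absent from genome build") from None

    def total_length(self):
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    def check_position(self, chrom, pos, context=""):
        length = self.length(chrom)
        if not (0 <= pos < length):
            raise CoordinateError(
                f"position {chrom}:{pos} outside [0, {length}){' in ' + context if context else ''}"
            )

    @classmethod
    def synthetic(cls, n_chromosomes=22, chrom_length_bp=100_000_000, centromere_fraction=0.5):
        """A uniform toy genome (chr1..chrN) used by the simulator."""
        names = tuple(f"chr{i}" for i in range(1, n_chromosomes + 1))
        lengths = {n: int(chrom_length_bp) for n in names}
        mid = int(chrom_length_bp * centromere_fraction)
        cen = {n: (mid - 500_000, mid + 500_000) for n in names}
        return cls(names, lengths, cen)


@dataclass
class SomaticSNV:
    """One somatic single-base substitution.

    ``context5``/``context3`` are the reference bases immediately 5' and 3'
    of the mutated base; ``class96`` is the pyrimidine-normalized
    96-context class index (set by annotation, optional until then).
    """

    chrom: str
    pos: int  # 0-based internal
    ref_base: str
    alt_base: str
    context5: Optional[str] = None
    context3: Optional[str] = None
    class96: Optional[int] = None

    def __post_init__(self):
        if self.ref_base not in NUCLEOTIDES or self.alt_base not in NUCLEOTIDES:
            raise ValidationError(f"SNV bases must be A/C/G/T, got {self.ref_base}>{self.alt_base}")
        if self.ref_base == self.alt_base:
            raise ValidationError(f"SNV ref equals alt ({self.ref_base}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class Breakend:
    """One oriented side of a rearrangement junction (see module docstring)."""

    chrom: str
    pos: int
    orient: str

    def __post_init__(self):
        if self.orient not in ORIENTATIONS:
            raise ValidationError(f"orientation must be head/tail, got {self.orient!r}")


@dataclass
class SVCall:
    """A somatic rearrangement: two oriented breakends plus call evidence.

    ``evidence`` holds per-class supporting read counts
    (discordant_pairs / split_reads / soft_clip); ``normal_evidence`` is the
    supporting read count in the matched normal; ``region_coverage`` the
    fold-coverage at the breakends (repeat-region proxy).
    """

    bnd1: Breakend
    bnd2: Breakend
    evidence: dict = field(default_factory=dict)
    normal_evidence: int = 0
    region_coverage: float = 0.0
    sv_type: Optional[str] = None
    microhomology_len: Optional[int] = None
    near_centromere: bool = False
    near_telomere: bool = False
    name: str = "."

    def __post_init__(self):
        for cls_name, count in self.evidence.items():
            if cls_name not in EVIDENCE_CLASSES:
                raise ValidationError(f"unknown evidence class {cls_name!r}")
            if count < 0:
                raise ValidationError(f"negative evidence count for {cls_name}")
        if self.normal_evidence < 0:
            raise ValidationError("negative normal_evidence")
        if self.sv_type is not None and self.sv_type not in SV_TYPES:
            raise ValidationError(f"unknown sv_type {self.sv_type!r}")

    @property
    def is_interchromosomal(self):
        return self.bnd1.chrom != self.bnd2.chrom

    @property
    def orientation_pair(self):
        return (self.bnd1.orient, self.bnd2.orient)

    def canonicalized(self, genome: GenomeBuild) -> "SVCall":
        """Return an equivalent call with bnd1 <= bnd2 in genome order."""
        k1 = (genome.chrom_index(self.bnd1.chrom), self.bnd1.pos)
        k2 = (genome.chrom_index(self.bnd2.chrom), self.bnd2.pos)
        if k1 <= k2:
            return self
        return replace(self, bnd1=self.bnd2, bnd2=self.bnd1)


@dataclass
class CNSegment:
    """Allele-specific copy-number segment (half-open internal coordinates).

    ``major_allele_fraction`` is in [0.5, 1.0]; it is undefined (None) when
    ``total_cn`` is 0.  ``state`` is one of :data:`CN_STATES` once classified.
    """

    chrom: str
    start: int
    end: int
    total_cn: int
    major_allele_fraction: Optional[float] = None
    mean_baf: Optional[float] = None
    mean_logr: Optional[float] = None
    state: Optional[str] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"segment {self.chrom}:{self.start}-{self.end} has start >= end")
        if self.total_cn < 0:
            raise ValidationError(f"negative total_cn at {self.chrom}:{self.start}")
        maf = self.major_allele_fraction
        if maf is not None and not (0.5 <= maf <= 1.0):
            raise ValidationError(f"major_allele_fraction {maf} outside [0.5, 1.0]")
        if self.state is not None and self.state not in CN_STATES:
            raise ValidationError(f"unknown CN state {self.state!r}")

    @property
    def length(self):
        return self.end - self.start


@dataclass
class TelomereStats:
    tumor_count: int
    tumor_mean_coverage: float
    normal_count: int
    normal_mean_coverage: float


@dataclass
class SampleBundle:
    """All per-sample inputs the pipeline consumes."""

    sample_id: str
    genome: GenomeBuild
    snvs: list = field(default_factory=list)
    svs: list = field(default_factory=list)
    cn_segments: dict = field(default_factory=dict)  # chrom -> sorted [CNSegment]
    telomere_stats: Optional[TelomereStats] = None

    def validate(self):
        """Check all coordinates against the genome and segment sortedness."""
        for snv in self.snvs:
            self.genome.check_position(snv.chrom, snv.pos, "SNV")
        for sv in self.svs:
            self.genome.check_position(sv.bnd1.chrom, sv.bnd1.pos, "SV breakend 1")
            self.genome.check_position(sv.bnd2.chrom, sv.bnd2.pos, "SV breakend 2")
        for chrom, segments in self.cn_segments.items():
            validate_segments(segments, self.genome, chrom)
        return self


def validate_segments(segments: Sequence, genome: Optional[GenomeBuild] = None, chrom=None):
    """Assert per-chromosome segments are sorted and non-overlapping."""
    prev = None
    for seg in segments:
        if chrom is not None and seg.chrom != chrom:
            raise ValidationError(f"segment on {seg.chrom} filed under {chrom}")
        if genome is not None:
            length = genome.length(seg.chrom)
            if not (0 <= seg.start < seg.end <= length):
                raise CoordinateError(
                    f"segment {seg.chrom}:{seg.start}-{seg.end} outside [0, {length})"
                )
        if prev is not None:
            if seg.start < prev.end:
                raise ValidationError(
                    f"segments overlap or are unsorted: {prev.chrom}:{prev.start}-{prev.end} "
                    f"and {seg.chrom}:{seg.start}-{seg.end}"
                )
        prev = seg
    return segments


def group_svs_by_chrom(svs: Iterable) -> dict:
    """Map chromosome -> breakend positions landing on it (translocations
    contribute one breakend to each partner chromosome)."""
    out = {}
    for sv in svs:
        out.setdefault(sv.bnd1.chrom, []).append(sv.bnd1.pos)
        out.setdefault(sv.bnd2.chrom, []).append(sv.bnd2.pos)
    return out


def intrachromosomal_svs(svs: Iterable, chrom: str) -> list:
    return [sv for sv in svs if sv.bnd1.chrom == chrom and sv.bnd2.chrom == chrom]
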