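"""Telomere content estimation from sequencing reads.

A read is telomeric when it contains three contiguous copies of the
telomeric repeat on either strand — ``TTAGGG x 3`` or ``CCCTAA x 3`` — as a
substring.  Counts are normalized to the genome-wide mean base coverage,
and the tumour/normal ratio of normalized counts summarizes somatic
telomere change (ratio < 1: shortening).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

from .errors import ValidationError

TELOMERE_MOTIF_FWD = "TTAGGG" * 3
TELOMERE_MOTIF_REV = "CCCTAA" * 3


@dataclass
class TelomereCount:
    """Telomeric read count with its coverage normalization."""

    n_telomeric_reads: int
    n_total_reads: int
    mean_coverage: float

    def __post_init__(self):
        if self.n_telomeric_reads < 0 or self.n_total_reads < 0:
            raise ValidationError("read counts must be >= 0")
        if self.mean_coverage <= 0:
            raise ValidationError("mean_coverage must be > 0")

    @property
    def normalized(self) -> float:
        return self.n_telomeric_reads / self.mean_coverage


def is_telomeric_read(seq: str) -> bool:
    s = seq.upper()
    return TELOMERE_MOTIF_FWD in s or TELOMERE_MOTIF_REV in s


def count_telomeric_reads(reads: Iterable[str], mean_coverage: float = 1.0) -> TelomereCount:
    """Count reads containing a triple telomeric repeat.

    A read counts at most once however many motifs it contains; N bases
    break matches.  An empty stream gives zero counts.
    """
    n_tel = 0
    n_total = 0
    for seq in reads:
        n_total += 1
        if is_telomeric_read(seq):
            n_tel += 1
    return TelomereCount(n_tel, n_total, mean_coverage)


def telomere_ratio(tumor: TelomereCount, normal: TelomereCount) -> Optional[float]:
    """Tumour/normal ratio of coverage-normalized telomeric read counts.

    Returns None (undefined) when the normal has zero telomeric reads.
    """
    if normal.n_telomeric_reads == 0:
        return None
    return tumor.normalized / normal.normalized
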