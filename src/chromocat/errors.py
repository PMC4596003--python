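"""Exception hierarchy for input validation and format handling."""


class ChromocatError(Exception):
    """Base class for all package-specific errors."""


class FileFormatError(ChromocatError):
    """A file does not conform to its declared format (VCF/BEDPE/TSV/FASTQ)."""


class CoordinateError(ChromocatError):
    """A record refers to a chromosome or position outside the genome build."""


class ValidationError(ChromocatError):
    """An in-memory object violates a structural invariant."""


class OrderingError(ChromocatError):
    """Input that must be position-sorted is not."""


class ParameterError(ChromocatError):
    """Simulation or analysis parameters are inconsistent or infeasible."""


class SequenceError(ChromocatError):
    """A nucleotide string contains characters outside A/C/G/T."""


class StatisticsError(ChromocatError):
    """A statistical test was invoked on insufficient input."""


class AnnotationError(ChromocatError):
    """A record is missing an annotation required by the operation."""


class AggregationError(ChromocatError):
    """Cohort-level aggregation received inconsistent per-sample reports."""
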