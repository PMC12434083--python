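"""Exception hierarchy shared across the pipeline.

Each error class maps to a distinct CLI exit code (see :mod:`isopull.cli`),
so batch callers can distinguish malformed inputs from statistical failures.
"""


class IsopullError(Exception):
    """Base class for all package errors."""

    exit_code = 7


class InvalidDesignError(IsopullError):
    """Empty factor set or non-positive replicate count in the sample design."""

    exit_code = 2


class SchemaError(IsopullError):
    """A mapped column is missing from an input table."""

    exit_code = 3


class EmptyInputError(IsopullError):
    """An input file contains no usable rows/records."""

    exit_code = 3


class FormatError(IsopullError):
    """Malformed input record (duplicate accession, empty sequence, ...)."""

    exit_code = 3


class DomainError(IsopullError):
    """A scalar argument is outside its mathematical domain."""

    exit_code = 3


class NormalizationError(IsopullError):
    """A run has no QC-passing peptides to derive a normalization factor from."""

    exit_code = 4


class TuningError(IsopullError):
    """The bait never survives the filter grid, even at its loosest point."""

    exit_code = 5


class HyperparameterError(IsopullError):
    """Too few usable variances to fit the variance-shrinkage prior."""

    exit_code = 6


class ConfigError(IsopullError):
    """Inconsistent run configuration (e.g. accession missing from the FASTA)."""

    exit_code = 7
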