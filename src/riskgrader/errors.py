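"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: validation errors exit 2, I/O errors
exit 3 and computation errors exit 4.
"""


class RiskgraderError(Exception):
    """Base class for all errors raised by this package."""

    stage: str = "riskgrader"


class ValidationError(RiskgraderError):
    """Invalid configuration, specification or input contract violation."""


class SpecValidationError(ValidationError):
    """A cohort specification violates one of its invariants."""


class VcfFormatError(ValidationError):
    """A VCF record violates the biallelic/GT contract of the reader."""

    stage = "variant_io"


class PhenotypeError(ValidationError):
    """The phenotype table is inconsistent with the genotyped samples."""

    stage = "variant_io"


class DegenerateTableError(RiskgraderError):
    """A 2x2 allele table with an empty group margin; no test is defined."""

    stage = "association"


class FitError(RiskgraderError):
    """The risk-model fit received inadmissible input."""

    stage = "risk_model"


class ComputationError(RiskgraderError):
    """A downstream computation could not be carried out."""
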