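"""Named error types raised across the package."""


class MetaGRSError(Exception):
    """Base class for package errors."""


class ValidationError(MetaGRSError):
    """Input failed a structural or range check."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input table."""


class DuplicateVariantError(ValidationError):
    """A variant id occurs more than once in a table."""


class AlleleError(ValidationError):
    """An allele field is not a single A/C/G/T base, or alleles coincide."""


class MonomorphicVariantError(MetaGRSError):
    """A variant has no dosage variation where variation is required."""


class ConvergenceError(MetaGRSError):
    """An iterative fit failed to converge or diverged."""


class OverlapError(MetaGRSError):
    """No usable variant overlap between weights and genotypes."""
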