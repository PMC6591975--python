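"""Exception hierarchy shared across the package."""


class HeliscanError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlphabetError(HeliscanError, ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class EmptyInputError(HeliscanError, ValueError):
    """An operation received no sequence records / no data rows."""


class FastaFormatError(HeliscanError, ValueError):
    """Malformed FASTA input (e.g. duplicate record ids)."""


class DomainError(HeliscanError, ValueError):
    """A numeric argument is outside the operation's domain."""


class DegenerateModelError(HeliscanError, ValueError):
    """A statistical model cannot be fitted (singular covariance etc.)."""


class SchemaError(HeliscanError, ValueError):
    """Tabular input is missing a required column."""


class CapacityError(HeliscanError, ValueError):
    """A synthetic-genome spec asks for more planted material than fits."""


class ConstraintError(HeliscanError, ValueError):
    """Requested marginal counts of a synthetic matrix are infeasible."""
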