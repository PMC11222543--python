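"""Exception hierarchy.

Every error raised by this package derives from :class:`SangeraseError` so
callers can catch pipeline failures without masking programming errors.
"""


class SangeraseError(Exception):
    """Base class for all package errors."""


class TraceParseError(SangeraseError):
    """Chromatogram file is missing a required ABIF tag or is corrupt."""


class EmptyReadError(SangeraseError):
    """Chromatogram contains no called bases."""


class SchemaError(SangeraseError):
    """A tabular input is missing required columns."""


class ValidationError(SangeraseError):
    """A tabular input contains values outside the allowed domain."""


class UncallableSiteError(SangeraseError):
    """All four channel intensities are zero; no genotype can be called."""


class MendelianInconsistencyError(SangeraseError):
    """Offspring heterozygote does not carry the homozygous maternal allele."""

    def __init__(self, site_id: str, maternal_allele: str, offspring_alleles):
        self.site_id = site_id
        self.maternal_allele = maternal_allele
        self.offspring_alleles = frozenset(offspring_alleles)
        super().__init__(
            f"site {site_id!r}: maternal allele {maternal_allele!r} absent from "
            f"offspring heterozygote {sorted(self.offspring_alleles)}"
        )


class TranscriptNotDetectedError(SangeraseError):
    """Both parental-allele cDNA intensities are zero (rendered as 'n.d.')."""


class GeneLookupError(SangeraseError):
    """Requested gene id absent from the annotation."""


class AmbiguityError(SangeraseError):
    """An identifier that must be unique occurs more than once."""


class RepeatMaskerParseError(SangeraseError):
    """Malformed RepeatMasker .out line (carries the 1-based line number)."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class ParameterError(SangeraseError):
    """An operation parameter is outside its valid range."""


class NoInformativeSitesError(SangeraseError):
    """The trio dataset contains no informative mother-offspring site."""
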