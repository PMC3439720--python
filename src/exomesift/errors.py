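"""Exception hierarchy shared across the package.

All exomesift errors derive from :class:`ExomeSiftError` so callers (and the
CLI) can distinguish data/config problems from programming errors.
"""


class ExomeSiftError(Exception):
    """Base class for all package errors."""


class InvalidAlleleError(ExomeSiftError, ValueError):
    """Allele string contains characters outside A/C/G/T or is empty."""


class NullVariantError(ExomeSiftError, ValueError):
    """Reference and alternate alleles describe no change."""


class UnsupportedVariantError(ExomeSiftError, ValueError):
    """Variant is neither an SNV nor a simple insertion/deletion."""


class SchemaError(ExomeSiftError):
    """Input table is missing a mandatory column or has a bad layout."""


class RowError(ExomeSiftError):
    """Too many unparseable rows in an input table."""


class FormatError(ExomeSiftError):
    """File layout not recognised (catalogue / manifest loaders)."""


class SampleNotFoundError(ExomeSiftError, KeyError):
    """Requested sample column absent from a multi-sample VCF."""


class ConfigError(ExomeSiftError, ValueError):
    """Invalid filter recipe, individual selection or simulator config."""


class OutOfCaptureError(ExomeSiftError, ValueError):
    """Position falls outside the captured exome window (exons +/- 20 bp)."""


class InvalidCodonPairError(ExomeSiftError, ValueError):
    """Codon pair does not differ at exactly one position."""


class WrongTypeError(ExomeSiftError, TypeError):
    """Operation applied to the wrong variant type (e.g. indel op on SNV)."""


class StoreError(ExomeSiftError):
    """Embedded database problems (schema version mismatch, duplicates)."""
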