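"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` to exit code 3; everything else is an ordinary crash.
"""


class MirtasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MirtasError):
    """Bad or missing configuration: unknown columns, element kinds, paths."""


class DataError(MirtasError):
    """Input data inconsistent with its own metadata (e.g. allele mismatch)."""


class GenerationError(MirtasError):
    """A synthetic fixture could not be constructed as requested."""


class PanelLookupError(KeyError, MirtasError):
    """An rsID was not found in the haplotype panel."""
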