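"""Exception taxonomy.

All errors derive from :class:`AxoquantError` so callers can catch the
package's failures with one handler; the subclasses map onto the distinct
failure modes the pipeline distinguishes (and onto CLI exit codes).
"""


class AxoquantError(Exception):
    """Base class for all axoquant errors."""


class ParameterError(AxoquantError, ValueError):
    """A filter or simulator parameter is outside its valid range."""


class InputError(AxoquantError, ValueError):
    """An input image or record collection is structurally invalid."""


class DomainError(AxoquantError, ValueError):
    """A value lies outside the mathematical domain of a statistic (e.g. log of 0)."""


class ReferenceValidityError(AxoquantError, ValueError):
    """Reference statistics violate the ordering the normalization requires."""


class ConfigurationError(AxoquantError, ValueError):
    """A run configuration is incomplete or inconsistent with the input tree."""
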