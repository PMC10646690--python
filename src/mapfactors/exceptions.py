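"""Exception hierarchy for mapfactors.

All errors derive from :class:`MapFactorsError` so callers can catch the
package's failures with a single except clause; each also derives from the
closest builtin (ValueError/KeyError) for drop-in compatibility.
"""


class MapFactorsError(Exception):
    """Base class for all mapfactors errors."""


class InvalidParameterError(MapFactorsError, ValueError):
    """A parameter is outside its documented domain."""


class InsufficientDataError(MapFactorsError, ValueError):
    """Too few subjects/trials for the requested computation."""


class DegenerateSplitError(MapFactorsError, ValueError):
    """A median split produced an empty group (all values identical)."""


class EmptySubsetError(MapFactorsError, ValueError):
    """A trial subset selected no trials."""


class EmptyInputError(MapFactorsError, ValueError):
    """No valid voxels/values remain after exclusion rules."""


class UndefinedCorrelationError(MapFactorsError, ValueError):
    """Pearson correlation undefined (zero variance on selected voxels)."""


class DimensionError(MapFactorsError, ValueError):
    """Array shapes are mutually inconsistent."""


class MissingMetadataError(MapFactorsError, KeyError):
    """A required label/metadata field is absent."""


class FormatError(MapFactorsError, ValueError):
    """An input file does not conform to the documented format."""
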