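"""Exception types shared across the package."""


class SbmlFeaturesError(Exception):
    """Base class for all package errors."""


class InputError(SbmlFeaturesError, ValueError):
    """Unusable input: unreadable file, empty model list, bad parameter."""


class FormatError(InputError):
    """A file parsed but is not in the expected format (e.g. XML that is not SBML)."""


class TaxonomyError(SbmlFeaturesError, ValueError):
    """Structural violation in an ontology taxonomy (cycle, unreachable concept)."""
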