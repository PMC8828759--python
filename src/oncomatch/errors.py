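"""Exception hierarchy shared across the package."""


class OncomatchError(Exception):
    """Base class for all package errors."""


class ProvenanceCollisionError(OncomatchError):
    """A term with the same (source, sourceId, sourceIdVersion) already exists."""


class NoMatchError(OncomatchError):
    """An exact-name lookup found no term."""


class ReferentialIntegrityError(OncomatchError):
    """An edge or statement refers to a term that is not in the graph."""


class InvariantError(OncomatchError):
    """A record violates one of its declared invariants."""


class FormatError(OncomatchError):
    """An input file does not conform to the expected dialect."""


class ConfigurationError(OncomatchError):
    """An unknown option value (e.g. an unrecognised filter name)."""
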