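"""Exception hierarchy for the oads package."""


class OadsError(Exception):
    """Base class for all package errors."""


class FormatError(OadsError):
    """Malformed input file (e.g. unparsable OBO stanza)."""


class ValidationError(OadsError):
    """Input violates a structural invariant (cycles, negative weights, duplicates)."""


class ContractError(OadsError):
    """An operation was called outside its preconditions."""


class LookupError_(OadsError):
    """A referenced term, disease, drug or cell type is unknown."""


class ConfigurationError(OadsError):
    """Missing or inconsistent configuration (e.g. unweighted classification source)."""
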