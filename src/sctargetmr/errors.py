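"""Exception types shared across the pipeline stages."""


class SCTargetMRError(Exception):
    """Base class for all package errors."""


class ParameterError(SCTargetMRError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyResultError(SCTargetMRError):
    """A filtering stage removed everything."""


class RegionError(SCTargetMRError):
    """A colocalization region could not be formed."""


class ContractError(SCTargetMRError):
    """An operation was called outside its contract (e.g. too few instruments)."""


class ParseError(SCTargetMRError):
    """A malformed input file; message names file and location."""
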