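"""Exception hierarchy.

Exit-code mapping used by the CLI: ParseError -> 2, ValidationError -> 3,
EstimationError -> 4.
"""


class OricycleError(Exception):
    """Base class for all package errors."""


class ParseError(OricycleError):
    """Malformed or missing input file / column."""


class ValidationError(OricycleError):
    """Inputs parsed but are inconsistent or out of domain."""


class EstimationError(OricycleError):
    """A fit or inversion failed to produce a usable estimate."""


class UnsupportedProfileError(EstimationError):
    """Run-out histogram has more than two ploidy peaks; the uninitiated
    fraction is only defined for a two-peak (n, 2n) profile."""
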