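"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: format/data problems exit 3,
statistical preconditions exit 4, configuration problems exit 2.
"""


class RadscreenError(Exception):
    """Base class for all package errors."""


class FormatError(RadscreenError):
    """A file does not conform to its declared dialect."""


class ValidationError(RadscreenError):
    """In-memory data violates an invariant (overlaps, out-of-range values...)."""


class ConfigurationError(RadscreenError):
    """A run or simulation configuration is infeasible or incomplete."""


class StatisticalPreconditionError(RadscreenError):
    """Too few observations / degenerate input for a statistical operation."""
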