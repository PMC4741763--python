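"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config 2, format/input 3, runtime 4),
so library code should raise the most specific class that applies.
"""


class MethsigError(Exception):
    """Base class for all package errors."""


class ParameterError(MethsigError, ValueError):
    """A function argument is outside its documented domain."""


class ConfigError(MethsigError, ValueError):
    """A configuration object is inconsistent or infeasible."""


class FormatError(MethsigError, ValueError):
    """An input file violates the documented tabular format."""


class InputError(MethsigError, ValueError):
    """Inputs are well-formed but mutually inconsistent (e.g. unknown probe)."""
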