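"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`InputError` (and subclasses) -> 2,
:class:`ContractViolation` -> 3.
"""


class SensCallError(Exception):
    """Base class for all package errors."""


class InputError(SensCallError, ValueError):
    """Invalid user-supplied input (file contents or parameter values)."""


class FormatError(InputError):
    """A file or record does not conform to its declared format."""


class ParameterError(InputError):
    """A parameter value is outside its documented domain."""


class ContractViolation(SensCallError, RuntimeError):
    """Internal pre/post-condition broken; indicates inconsistent inputs
    rather than a malformed file (e.g. a truth site outside the depth
    profile it is being classified against)."""
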