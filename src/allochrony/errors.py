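"""Exception hierarchy shared by all stages.

The CLI maps :class:`ValidationError` to exit code 2 and
:class:`ComputationError` to exit code 3.
"""


class AllochronyError(Exception):
    """Base class for package errors."""


class ValidationError(AllochronyError, ValueError):
    """Invalid input data or configuration."""


class ComputationError(AllochronyError, RuntimeError):
    """A stage could not produce a result from valid-looking input."""
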