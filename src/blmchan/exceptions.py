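"""Exception hierarchy.

Validation/format problems (bad inputs, broken invariants) are distinct from
numerical failures (non-convergent fits); the CLI maps the former to exit
code 2 and the latter to exit code 3.
"""


class BlmError(Exception):
    """Base class for all package errors."""


class ValidationError(BlmError):
    """An input violates a documented precondition or type invariant."""


class FormatError(BlmError):
    """An on-disk artifact does not match the expected text format."""


class FitError(BlmError):
    """A numerical fit failed to converge or is degenerate."""
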