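"""Exception hierarchy shared across the package.

InputError maps to CLI exit code 2, InvariantViolation to exit code 3.
"""


class Rpsb2paError(Exception):
    """Base class for package errors."""


class InputError(Rpsb2paError):
    """Malformed or missing user input (schema errors, bad paths, bad params)."""


class InvariantViolation(Rpsb2paError):
    """A domain invariant does not hold (duplicate keys, resonance, asymmetry)."""
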