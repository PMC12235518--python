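"""Exception hierarchy for the dice package.

The CLI maps :class:`DiceInputError` to exit code 2 and
:class:`EmptyResultError` to exit code 3; everything else is a bug.
"""


class DiceError(Exception):
    """Base class for all dice-specific errors."""


class DiceInputError(DiceError):
    """Malformed or structurally invalid input (duplicates, bad ranges...)."""


class EmptyResultError(DiceError):
    """A phase produced an empty result (e.g. no candidates, no edges)."""


class ConvergenceError(DiceError):
    """An iterative numerical routine failed to converge."""
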