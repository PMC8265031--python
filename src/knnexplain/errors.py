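"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (input error -> 2,
precondition violation -> 3, anything else -> 1).
"""


class KnnExplainError(Exception):
    """Base class for all package errors."""


class InputError(KnnExplainError, ValueError):
    """Malformed or invalid user input (bad feature name, non-positive
    intensity where a log transform is configured, malformed CSV, ...)."""


class PreconditionError(KnnExplainError, RuntimeError):
    """A documented precondition of an operation is not met (incomplete
    subset-value table, single-class permutation set, mismatched instance
    sets, ...)."""
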