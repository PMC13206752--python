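"""Exception hierarchy for the pipeline.

Every error raised on bad input derives from :class:`MarsaError` so callers
can catch pipeline failures without masking programming errors.
"""


class MarsaError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MarsaError, ValueError):
    """An argument violates an operation's preconditions."""


class DegeneratePatternError(MarsaError):
    """An activity pattern has zero variance, so correlation is undefined."""

    def __init__(self, items):
        self.items = list(items)
        super().__init__(
            f"zero-variance pattern for item(s) {self.items}: "
            "correlation distance is undefined"
        )


class UndefinedCorrelationError(MarsaError):
    """A correlation was requested between vectors with zero variance."""


class DegenerateTrialError(MarsaError):
    """An arrangement trial carries no distance information (all items coincide)."""


class IncompleteEvidenceError(MarsaError):
    """Some stimulus pairs were never measured with positive evidence."""

    def __init__(self, missing_pairs):
        self.missing_pairs = [tuple(p) for p in missing_pairs]
        shown = ", ".join(map(str, self.missing_pairs[:10]))
        more = "" if len(self.missing_pairs) <= 10 else f" (+{len(self.missing_pairs) - 10} more)"
        super().__init__(f"no evidence for pair(s): {shown}{more}")


class DegenerateTestError(MarsaError):
    """A statistical test cannot be computed (e.g. zero variance across units)."""
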