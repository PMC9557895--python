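"""Exception hierarchy.

Every error raised deliberately by the package derives from :class:`GxeNullError`
so callers can catch the package's failures without swallowing programming bugs.
"""

from __future__ import annotations


class GxeNullError(Exception):
    """Base class for all errors raised by gxenull."""


class InvalidConfigError(GxeNullError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class MissingWeightError(GxeNullError, KeyError):
    """A dosage column has no corresponding row in the variant weight table."""

    def __init__(self, variants):
        self.variants = sorted(variants)
        super().__init__(f"no weight row for variant(s): {', '.join(self.variants)}")


class InsufficientDataError(GxeNullError, ValueError):
    """Too few observations for the requested operation (e.g. < 10 for deciles)."""


class DegenerateInputError(GxeNullError, ValueError):
    """Input with no usable variation (e.g. all values identical for the INT)."""


class EmptyGroupError(GxeNullError, ValueError):
    """A required stratum or group contains no observations."""


class EmptyCellError(GxeNullError, ValueError):
    """A decile x exposure cell needed for a contrast is empty."""


class InvalidSpecError(GxeNullError, ValueError):
    """A model specification is unusable (e.g. constant exposure)."""


class CollinearityError(GxeNullError, ValueError):
    """Rank-deficient design matrix; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending column(s): "
            + ", ".join(map(str, self.columns))
        )


class InvalidInputError(GxeNullError, ValueError):
    """A plain-argument precondition failed (e.g. R = 0 for an empirical P)."""


class InfeasibleTargetsError(GxeNullError, RuntimeError):
    """Matched-group selection could not reach the target moments.

    Mirrors the situation where an optimizer cannot recreate the requested
    outcome distributions (e.g. very large groups leaving no slack).  The
    best-achieved moments are attached for diagnostics.
    """

    def __init__(self, message, achieved=None, iterations=None):
        super().__init__(message)
        self.achieved = achieved
        self.iterations = iterations
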