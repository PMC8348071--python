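"""Exception hierarchy shared across the package.

All errors derive from :class:`ArrcineError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid input rather than internal state.
"""


class ArrcineError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(ArrcineError, ValueError):
    """A generator or acquisition specification violates its invariants."""


class InsufficientDataError(ArrcineError, ValueError):
    """Too few observations to compute the requested statistic."""


class CorruptTimingError(ArrcineError, ValueError):
    """Trigger timestamps are non-monotone or produce non-positive intervals."""


class InfeasibleWindowError(ArrcineError, ValueError):
    """The segmented acquisition window cannot fit the shortest RR interval."""


class DegenerateCycleError(ArrcineError, ValueError):
    """A heartbeat is shorter than one frame's temporal resolution."""


class NoEdgeError(ArrcineError, ValueError):
    """No intensity edge could be located on a profile."""


class AmbiguousEdgeError(ArrcineError, ValueError):
    """Several equally steep edges found and no analysis window was given."""


class FixtureError(ArrcineError, ValueError):
    """A cross-tabulation fixture is internally inconsistent."""


class CohortConfigError(ArrcineError, ValueError):
    """A cohort configuration cannot be satisfied (e.g. irregularity filter)."""
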