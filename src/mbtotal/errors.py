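"""Exception hierarchy for mbtotal.

All package errors derive from :class:`MbTotalError` so callers can catch the
package's failures with a single except clause while still distinguishing
numerical degeneracies (singular fitting matrices, degenerate stratifications)
from plain contract violations.
"""


class MbTotalError(Exception):
    """Base class for all mbtotal errors."""


class InvalidSpecError(MbTotalError, ValueError):
    """A model or simulation specification violates its invariants."""


class TieDegenerateError(MbTotalError, ValueError):
    """The outcome vector cannot be stratified by quantile (heavy ties)."""


class DegenerateGammaError(MbTotalError, RuntimeError):
    """No eigenvalue of the covariate cross-product matrix exceeds one, so
    the simulation coefficient vector is undefined."""


class SuperCollinearityError(MbTotalError, RuntimeError):
    """The cross-product matrix X'X is singular or numerically
    ill-conditioned; ordinary least squares has no stable solution.

    The standard remedy is ridge augmentation: see ``fit_prr``.
    """


class InvalidWeightsError(MbTotalError, ValueError):
    """A weighted fit received a non-positive variance entry."""


class DegreesOfFreedomError(MbTotalError, ValueError):
    """Too few observations for an unbiased error-variance estimate."""


class SelectionError(MbTotalError, RuntimeError):
    """No feasible value remained on the ridge tuning grid."""


class EstimationError(MbTotalError, RuntimeError):
    """A total predictor received an empty or inconsistent sample."""
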