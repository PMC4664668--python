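"""Exception hierarchy for the minibeams package.

Every model-level failure derives from :class:`MinibeamError` so callers
(and the CLI) can map error families to distinct exit codes.
"""


class MinibeamError(Exception):
    """Base class for all package errors."""


class DomainError(MinibeamError):
    """Input outside the physical validity domain of a model.

    Raised e.g. for kinetic energies below the 1 MeV/u stopping-power
    floor or ranges no achievable energy can reach.
    """


class TransportRangeError(MinibeamError):
    """Transport requested beyond 95% of the CSDA range.

    Near the Bragg peak the Gaussian small-angle model breaks down
    (end-of-range straggling, large-angle single scattering), so the
    transport refuses to go there rather than return garbage.
    """


class NotReachedError(MinibeamError):
    """A target width or merge condition is not reached before the beam stops."""


class PlanError(MinibeamError):
    """An interleave plan is infeasible (coverage failure, target too deep...)."""


class ConfigError(MinibeamError):
    """A run configuration is malformed or violates the schema."""
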