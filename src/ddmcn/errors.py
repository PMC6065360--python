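"""Exception hierarchy for droplet-digital quantification workflows."""


class DdmcnError(Exception):
    """Base class for all package-specific errors."""


class SaturatedWellError(DdmcnError):
    """All droplets positive: the Poisson estimate of lambda is unbounded."""


class EmptyWellError(DdmcnError):
    """A well contains no droplets (or no gated droplets)."""


class InfeasibleShiftError(DdmcnError):
    """A gating discrepancy exceeds the occupancy of one of the gates."""


class DesignInfeasibleError(DdmcnError):
    """No primer-concentration pair satisfies the separation constraint."""


class AmbiguousCopyNumberError(DdmcnError):
    """A measured ratio is not close enough to an integer copy number."""


class GateConfigError(DdmcnError):
    """Manual gates are overlapping or otherwise ill-formed."""


class FitError(DdmcnError):
    """A model fit failed to converge or had degenerate inputs."""
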