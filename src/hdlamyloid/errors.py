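"""Exception types shared across the package."""


class HdlAmyloidError(Exception):
    """Base class for package-specific errors."""


class PlacementError(HdlAmyloidError):
    """Overlap-free particle placement failed after bounded retries."""


class EmptyDistributionError(HdlAmyloidError):
    """No pixels fell inside the requested height range."""


class NormalizationError(HdlAmyloidError):
    """A trace or timecourse cannot be normalized (zero starting value)."""


class StructureError(HdlAmyloidError):
    """A coordinate model is missing chains, residues or Cα atoms."""


class FitError(HdlAmyloidError):
    """A model fit failed to converge or was handed degenerate data."""
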