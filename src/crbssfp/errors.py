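"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A physical or sequence parameter is outside its valid domain."""


class InfeasiblePlacementError(RuntimeError):
    """The phantom cannot host the requested tumours without overlap."""


class InsufficientTraceError(RuntimeError):
    """The physiological trace ended before the scan completed.

    Carries a progress report so callers can retry with a longer trace.
    """

    def __init__(self, message: str, blocks_done: int = 0, blocks_total: int = 0):
        super().__init__(message)
        self.blocks_done = blocks_done
        self.blocks_total = blocks_total


class BadSeedError(ValueError):
    """A segmentation seed point lies outside the threshold band."""

    def __init__(self, message: str, seed=None, intensity=None):
        super().__init__(message)
        self.seed = seed
        self.intensity = intensity


class UntrackableError(RuntimeError):
    """Registration QC failed; individual tumours cannot be tracked."""


class CorruptFixtureError(RuntimeError):
    """A packaged reference table failed its checksum."""
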