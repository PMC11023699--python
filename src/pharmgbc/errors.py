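"""Package exception hierarchy."""


class PharmGbcError(Exception):
    """Base class for all pharmgbc errors."""


class InvalidArgumentError(PharmGbcError, ValueError):
    """An argument violates an operation's contract."""


class DegenerateGeometryError(PharmGbcError):
    """Spatial covariance is singular (e.g. duplicate parcel centroids)."""


class DegenerateInputError(PharmGbcError):
    """Input carries no usable variance (constant or all-zero data)."""


class TooFewFramesError(PharmGbcError):
    """Too few frames survive scrubbing for a stable correlation estimate."""


class FlaggedParcelError(PharmGbcError):
    """One or more parcels have zero temporal variance."""

    def __init__(self, parcels):
        self.parcels = list(parcels)
        super().__init__(f"zero-variance parcels: {self.parcels}")


class ConfigError(PharmGbcError):
    """A subscale or pipeline configuration is inconsistent."""
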