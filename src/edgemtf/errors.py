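"""Exception hierarchy for the measurement pipeline.

Every stage raises a subclass of :class:`EdgeMTFError` with a short,
stable message so callers (and the CLI exit-code mapping) can tell input
problems apart from statistical failures.
"""


class EdgeMTFError(Exception):
    """Base class for all errors raised by edgemtf."""


class VolumeError(EdgeMTFError):
    """Problem with the CT volume or the DICOM series it came from."""


class SurfaceError(EdgeMTFError):
    """Problem during segmentation or surface meshing."""


class SamplingError(EdgeMTFError):
    """A sampling line could not produce a usable ESF curve."""


class CurveRejected(EdgeMTFError):
    """An individual ESF curve failed a structural check or filter."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class MeasurementError(EdgeMTFError):
    """The aggregate measurement could not be completed."""
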