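"""Exception hierarchy."""


class NeurospotError(Exception):
    """Base class for package errors."""


class FormatError(NeurospotError):
    """A file does not match the expected tabular/JSON dialect."""


class GeometryError(NeurospotError):
    """Invalid neuron geometry (open or self-intersecting polygon, ...)."""


class CalibrationError(NeurospotError):
    """Too little data to estimate a unit (single-molecule) intensity."""


class SimulationError(NeurospotError):
    """The Monte-Carlo null cannot be built (e.g. more spots than pixels)."""
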