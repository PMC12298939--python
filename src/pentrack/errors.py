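"""Exception types shared across the package."""


class PentrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidEmbeddingError(PentrackError, ValueError):
    """An appearance embedding is unusable (zero norm, wrong shape/dimension)."""


class SimilarityUnavailableError(PentrackError):
    """Appearance similarity cannot be computed (missing embedding on either side)."""


class SequenceOrderError(PentrackError, ValueError):
    """Frames were fed to the tracker out of order."""


class EmptyGroundTruthError(PentrackError, ValueError):
    """A metric requiring ground-truth boxes received none."""


class MissingSowError(PentrackError, ValueError):
    """Behavior analysis requires a sow trajectory and none was supplied."""


class InsufficientOverlapError(PentrackError, ValueError):
    """Piglet and sow trajectories share fewer than two frames."""


class NoPigletsInZoneError(PentrackError, ValueError):
    """The stress zone contains no piglets; a group vote is undefined."""


class MotFormatError(PentrackError, ValueError):
    """A MOTChallenge-dialect file could not be parsed."""
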