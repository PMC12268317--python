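"""Exception hierarchy for rtbridge.

All package-specific failures derive from :class:`RTBridgeError` so callers
can catch one base class at pipeline level while fine-grained handlers stay
possible at stage level.
"""


class RTBridgeError(Exception):
    """Base class for all rtbridge errors."""


class ValidationError(RTBridgeError):
    """Malformed input data (duplicate ids, bad roles, impossible values)."""


class DegenerateAnchorError(RTBridgeError):
    """RTI anchors collapse: rt_max <= rt_min."""


class InsufficientAnchorsError(RTBridgeError):
    """Fewer shared calibrants than the minimum required for a pair."""


class InsufficientOverlapError(RTBridgeError):
    """Too few shared compounds for a correlation (n < 3)."""


class InsufficientDataError(RTBridgeError):
    """Not enough observations for a summary or model fit."""


class DegenerateFitError(RTBridgeError):
    """Model fit impossible: singular basis or constant predictor."""
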