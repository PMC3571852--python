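"""Exception hierarchy for drowsefuse.

Detectors raise specific subclasses so the pipeline can distinguish a
recoverable per-frame/per-window failure (skip or hold last value) from a
configuration or input-format problem (abort with exit code 2).
"""


class DrowsefuseError(Exception):
    """Base class for all drowsefuse errors."""


class ConfigError(DrowsefuseError):
    """Invalid configuration value (unknown color space, bad threshold, ...)."""


class StreamFormatError(DrowsefuseError):
    """Malformed input stream (bad header, non-monotone timestamps, bad row)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NoFaceError(DrowsefuseError):
    """No facial region found in a frame; the frame is skipped."""


class EyesNotFoundError(DrowsefuseError):
    """Face found but no vertically aligned eye-candidate pair."""


class InsufficientDataError(DrowsefuseError):
    """Trace too short / too few events to compute the requested feature."""


class InsufficientBufferError(InsufficientDataError):
    """PPG buffer below the minimum sample count for reliable cycle detection."""


class OutOfSupportError(DrowsefuseError):
    """Crisp value falls outside the support of every membership function."""
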