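"""Exception hierarchy.

Three broad families map onto the CLI exit codes: configuration problems
(exit 2), data problems (exit 3), and training divergence (exit 4).
"""


class PulsePinnError(Exception):
    """Base class for all package errors."""


class ConfigError(PulsePinnError):
    """Invalid configuration or argument combination (CLI exit code 2)."""


class DataError(PulsePinnError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


# -- configuration-type errors -------------------------------------------------

class InvalidWindowError(ConfigError):
    """Moving-average overlap >= window."""


class InfeasibleConfigError(ConfigError):
    """Simulation couplings produce non-physical amplitude or delay."""


class NonIdentifiableGradientError(ConfigError):
    """A generator coupling gain is zero, so d(BP)/du is undefined."""


# -- data-type errors ----------------------------------------------------------

class InvalidBaselineError(DataError):
    """Baseline impedance Z0 <= 0."""


class BoundaryError(DataError):
    """Beat boundaries missing, too few, or not strictly increasing."""


class FiducialDetectionError(DataError):
    """Waveform morphology too degenerate to place the nine landmarks."""

    def __init__(self, message: str, beat_index: int | None = None):
        super().__init__(message)
        self.beat_index = beat_index


class NonPhysicalTimingError(DataError):
    """Fiducial timing violates t_F > t_B or t_J > t_A."""


class BeatTooLongError(DataError):
    """Beat duration exceeds pad_len / target_rate; never silently truncated."""


class DegenerateChannelError(DataError):
    """A channel has zero variance and cannot be standardized."""


class InsufficientSequenceError(DataError):
    """Fewer than two beats: sequential residuals are undefined."""


class NoLabelsError(DataError):
    """Supervised loss requested with an empty labeled set."""


class DegenerateRangeError(DataError):
    """Constant labels: no BP range to bin."""


class FormatError(DataError):
    """A file does not match the expected on-disk schema."""


class DependencyError(DataError):
    """A pipeline stage is missing an upstream artifact or label column."""


# -- training ------------------------------------------------------------------

class TrainingDivergedError(PulsePinnError):
    """Loss became non-finite during optimization (CLI exit code 4)."""

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch


class CorrelationUndefined(UserWarning):
    """Pearson correlation undefined (constant input); other metrics still valid."""
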