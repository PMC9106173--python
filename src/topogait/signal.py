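"""Core signal and metadata containers.

A trial is one straight-walk pass recorded by a foot-mounted IMU; the signal
analysed throughout is the medio-lateral angular velocity (``Gyr-Y``, deg/s),
uniformly sampled (100 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DEFAULT_SAMPLING_RATE = 100.0  # Hz

SESSIONS = ("M0", "M6")
FEET = ("LF", "RF")
TRIAL_LABELS = ("F1", "R1", "F2", "R2", "F3", "R3", "F4", "R4")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled univariate signal.

    Parameters
    ----------
    values
        Sample values in deg/s. Must be finite and contain at least two
        samples for barcode construction.
    sampling_rate
        Samples per second, > 0.
    trial_id
        Opaque identifier linking the signal to its metadata row.
    """

    values: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    trial_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 1:
            raise InvalidInputError("signal must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(
                f"signal {self.trial_id!r} contains non-finite samples"
            )
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.values.size / self.sampling_rate


@dataclass
class TrialRecord:
    """Metadata for one trial.

    ``group`` is HS (healthy subject) or MS (multiple-sclerosis patient).
    EDSS is the Expanded Disability Status Scale, 0-10 in 0.5 steps; healthy
    subjects are recorded with EDSS 0. ``session`` is the baseline (M0) or
    six-month follow-up (M6) measurement. ``trial_label`` identifies the
    walk (F = forward, R = return). ``steps`` is an optional known step
    count used to trim the barcode; when absent it is estimated from the
    signal's autocorrelation.
    """

    trial_id: str
    subject_id: str
    group: str = "HS"
    edss: float = 0.0
    session: str = "M0"
    trial_label: str = "F1"
    foot: str = "LF"
    steps: Optional[int] = None
    velocity: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("HS", "MS"):
            raise InvalidInputError(f"group must be HS or MS, got {self.group!r}")
        if self.session not in SESSIONS:
            raise InvalidInputError(f"session must be one of {SESSIONS}")
        if self.foot not in FEET:
            raise InvalidInputError(f"foot must be one of {FEET}")
        if not 0.0 <= float(self.edss) <= 10.0:
            raise InvalidInputError("EDSS must lie in [0, 10]")
        if self.steps is not None and int(self.steps) < 1:
            raise InvalidInputError("steps must be a positive integer")

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.session, self.trial_label, self.foot)
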