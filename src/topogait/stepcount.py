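"""Step counting from the signal's autocorrelation function.

The number of steps k in a trial decides how many long bars to trim from
its barcode. When the metadata does not supply k, it is estimated from the
autocorrelation function (ACF): the lag of the first ACF peak after lag 0
(the "second peak", lag 0 being the first) is the duration of one gait
cycle, and k = round(trial duration / cycle duration). The estimate is
heuristic — a minimum-lag guard and an ACF-value floor suppress spurious
peaks — and can fail on signals with no periodic structure, in which case
a StepCountError is raised for the caller to handle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelmax

from .signal import TimeSeries, TrialRecord

__all__ = ["StepEstimate", "StepCountError", "count_steps_acf", "resolve_step_count"]

#: Plausible single gait-cycle duration bounds, seconds.
MIN_CYCLE_S = 0.4
MAX_CYCLE_S = 4.0
#: Minimum ACF value for a lag to qualify as the cycle peak.
ACF_FLOOR = 0.2


class StepCountError(RuntimeError):
    """No qualifying ACF peak — the step count could not be estimated."""


@dataclass(frozen=True)
class StepEstimate:
    """An estimated or known step count.

    ``source`` records whether k came from the metadata sheet or the ACF.
    """

    k: int
    cycle_duration: float  # seconds; NaN when k came from metadata
    source: str  # "acf" | "metadata"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("step count must be >= 1")


def autocorrelation(values: np.ndarray) -> np.ndarray:
    """Mean-centered, lag-0-normalised autocorrelation (biased estimator)."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    # FFT-based full autocorrelation; keep nonnegative lags
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    if acf[0] <= 0:  # constant signal
        return np.zeros(n)
    return acf / acf[0]


def count_steps_acf(
    ts: TimeSeries,
    min_cycle_s: float = MIN_CYCLE_S,
    max_cycle_s: float = MAX_CYCLE_S,
    acf_floor: float = ACF_FLOOR,
) -> StepEstimate:
    """Estimate the step count of a trial from its ACF.

    The first local ACF maximum at lag >= ``min_cycle_s`` whose value
    exceeds ``acf_floor`` gives the gait-cycle duration; the step count is
    the trial duration divided by it, rounded to the nearest integer
    (the last step may be incomplete) and floored at 1.

    Raises
    ------
    StepCountError
        If no lag in [min_cycle_s, max_cycle_s] qualifies.
    """
    fs = ts.sampling_rate
    min_lag = max(2, int(round(min_cycle_s * fs)))
    if len(ts) < 2 * min_lag:
        raise StepCountError(
            f"trial {ts.trial_id!r}: too short ({len(ts)} samples) for a "
            f"{min_cycle_s:g} s minimum cycle"
        )
    acf = autocorrelation(ts.values)
    max_lag = min(acf.size - 1, int(round(max_cycle_s * fs)))
    (peaks,) = argrelmax(acf[: max_lag + 1], order=1)
    peaks = peaks[(peaks >= min_lag) & (acf[peaks] > acf_floor)]
    if peaks.size == 0:
        raise StepCountError(
            f"trial {ts.trial_id!r}: no ACF peak above {acf_floor:g} in "
            f"[{min_cycle_s:g}, {max_cycle_s:g}] s"
        )
    lag = int(peaks[0])
    cycle_duration = lag / fs
    k = max(1, int(round(ts.duration / cycle_duration)))
    return StepEstimate(k=k, cycle_duration=cycle_duration, source="acf")


def resolve_step_count(
    record: TrialRecord,
    ts: TimeSeries,
    *,
    force: str | None = None,
    **acf_kwargs,
) -> StepEstimate:
    """Return the metadata step count when present, else the ACF estimate.

    ``force`` may be "metadata" or "acf" to disable the fallback order.
    """
    if force not in (None, "metadata", "acf"):
        raise ValueError("force must be None, 'metadata' or 'acf'")
    if force != "acf" and record.steps is not None:
        return StepEstimate(k=int(record.steps), cycle_duration=float("nan"),
                            source="metadata")
    if force == "metadata":
        raise StepCountError(
            f"trial {record.trial_id!r}: no step count in metadata"
        )
    return count_steps_acf(ts, **acf_kwargs)
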