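"""Synthetic gait-like Gyr-Y signals and cohorts with known ground truth.

Each gait cycle of a foot's medio-lateral angular velocity has four
characteristic extrema: a dip after heel strike (A, negative), the
foot-flat plateau (B, about zero), a deeper dip just before toe off (C)
and the swing-phase plateau (D, large positive). The generator reproduces
exactly this four-extrema topology — the sublevel-set barcode of a clean
n-cycle trial has one long bar per cycle (the (C, D) pair, one of them
infinite) and one medium bar per cycle (the (A, B) pair) — and nothing
more: cycles are piecewise monotone-cubic between the anchor extrema, so
a noise-free trial has no spurious extrema.

Pathology severity is modelled as added mid-frequency oscillation
amplitude plus timing jitter: exactly the mechanism the trimmed-barcode
distance is designed to pick up (small bars read as oscillations and
irregular movements). Left/right asymmetry is an oscillation multiplier on
one foot; longitudinal change is a severity delta between sessions.
Ground truth (cycle count, severity, asymmetry, drift) travels with each
trial's metadata so every downstream stage can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .signal import InvalidInputError, TimeSeries, TrialRecord

__all__ = [
    "CycleTemplate",
    "NoiseSpec",
    "CohortSpec",
    "generate_trial",
    "generate_cohort",
]


@dataclass(frozen=True)
class CycleTemplate:
    """Anchor extrema of one gait cycle (deg/s) and their timing.

    Invariant: toe_off_dip < heel_dip < flat_plateau < swing_plateau
    (C < A < B < D). Fractions position the anchors inside the cycle.
    """

    heel_dip: float = -100.0       # A
    flat_plateau: float = 10.0     # B
    toe_off_dip: float = -280.0    # C
    swing_plateau: float = 350.0   # D
    cycle_duration: float = 1.2    # seconds
    fractions: Tuple[float, float, float, float] = (0.07, 0.28, 0.55, 0.78)

    def __post_init__(self) -> None:
        if not (self.toe_off_dip < self.heel_dip < self.flat_plateau
                < self.swing_plateau):
            raise InvalidInputError(
                "cycle anchors must satisfy C < A < B < D"
            )
        if self.cycle_duration <= 0:
            raise InvalidInputError("cycle_duration must be positive")
        if not all(0 < f < 1 for f in self.fractions) or any(
            b <= a for a, b in zip(self.fractions, self.fractions[1:])
        ):
            raise InvalidInputError("fractions must increase within (0, 1)")


@dataclass(frozen=True)
class NoiseSpec:
    """Band-limited oscillation noise: a sum of random-phase sinusoids."""

    amplitude: float = 0.0         # total RMS-ish amplitude, deg/s
    freq_band: Tuple[float, float] = (4.0, 12.0)  # Hz
    n_components: int = 6

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidInputError("noise amplitude must be >= 0")


def _oscillation(rng: np.random.Generator, t: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.amplitude == 0 or noise.n_components == 0:
        return np.zeros_like(t)
    freqs = rng.uniform(*noise.freq_band, size=noise.n_components)
    phases = rng.uniform(0, 2 * np.pi, size=noise.n_components)
    weights = rng.uniform(0.5, 1.0, size=noise.n_components)
    weights *= noise.amplitude / weights.sum()
    out = np.zeros_like(t)
    for f, p, w in zip(freqs, phases, weights):
        out += w * np.sin(2 * np.pi * f * t + p)
    return out


def generate_trial(
    tmpl: CycleTemplate = CycleTemplate(),
    n_cycles: int = 5,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    sampling_rate: float = 100.0,
    timing_jitter: float = 0.0,
    trial_id: str = "synthetic",
) -> TimeSeries:
    """Generate one gait trial: n_cycles cycles plus oscillation noise.

    The signal starts at zero (a boundary maximum, ignored by the barcode
    sweep) and ends on the last swing plateau. ``timing_jitter`` is the
    relative standard deviation of per-cycle duration. Deterministic per
    seed.
    """
    if n_cycles < 1:
        raise InvalidInputError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)

    durations = np.full(n_cycles, tmpl.cycle_duration)
    if timing_jitter > 0:
        durations *= np.clip(
            1.0 + timing_jitter * rng.standard_normal(n_cycles), 0.5, 1.5
        )
    starts = np.concatenate([[0.0], np.cumsum(durations[:-1])])

    levels = (tmpl.heel_dip, tmpl.flat_plateau, tmpl.toe_off_dip,
              tmpl.swing_plateau)
    knot_t: List[float] = [0.0]
    knot_v: List[float] = [0.0]
    for i in range(n_cycles):
        for frac, level in zip(tmpl.fractions, levels):
            knot_t.append(starts[i] + frac * durations[i])
            knot_v.append(level)
    # last cycle ends at its swing plateau (boundary maximum)
    interp = PchipInterpolator(knot_t, knot_v)
    t = np.arange(0.0, knot_t[-1], 1.0 / sampling_rate)
    values = interp(t) + _oscillation(rng, t, noise)
    return TimeSeries(values=values, sampling_rate=sampling_rate,
                      trial_id=trial_id)


@dataclass(frozen=True)
class CohortSpec:
    """A two-group (HS/MS) longitudinal cohort design.

    Healthy subjects have severity ``hs_severity`` (0 by default); patient
    severities are spread evenly over ``ms_severity_range`` so that
    EDSS-threshold partitions are populated. ``session_drift`` adds a
    severity delta at M6 for selected subjects; ``asymmetry`` multiplies
    the left-foot oscillation amplitude for selected (subject, session)
    pairs. Per-trial seeds are derived from ``seed`` and the trial's
    coordinates, so cohorts are deterministic and order-independent.
    """

    n_hs: int = 6
    n_ms: int = 6
    hs_severity: float = 0.0
    ms_severity_range: Tuple[float, float] = (1.0, 4.0)
    sessions: Tuple[str, ...] = ("M0", "M6")
    trials_per_session: int = 4
    cycles_per_trial: int = 5
    sampling_rate: float = 100.0
    template: CycleTemplate = field(default_factory=CycleTemplate)
    base_noise: float = 6.0            # deg/s, all subjects
    severity_noise_scale: float = 16.0  # extra oscillation deg/s per severity unit
    severity_jitter_scale: float = 0.015  # timing jitter per severity unit
    session_drift: Mapping[str, float] = field(default_factory=dict)
    asymmetry: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hs < 0 or self.n_ms < 0 or self.n_hs + self.n_ms == 0:
            raise InvalidInputError("cohort must contain subjects")
        if self.trials_per_session < 1 or self.trials_per_session > 4:
            raise InvalidInputError("trials_per_session must be in 1..4")
        if self.cycles_per_trial < 1:
            raise InvalidInputError("cycles_per_trial must be >= 1")

    @property
    def subjects(self) -> List[Tuple[str, str, float]]:
        """(subject_id, group, baseline severity) for the whole cohort."""
        out = [(f"HS{i+1:02d}", "HS", self.hs_severity) for i in range(self.n_hs)]
        if self.n_ms == 1:
            sev = [np.mean(self.ms_severity_range)]
        else:
            sev = np.linspace(*self.ms_severity_range, self.n_ms)
        out += [(f"MS{i+1:02d}", "MS", float(sev[i])) for i in range(self.n_ms)]
        return out


def _edss_from_severity(severity: float) -> float:
    # map severity 1..4 roughly onto EDSS 2..6, in half steps
    return float(np.clip(np.round(2 * (1.0 + 1.25 * severity)) / 2, 1.0, 6.5))


def generate_cohort(spec: CohortSpec) -> Tuple[List[TimeSeries], List[TrialRecord]]:
    """Generate one signal per (subject, session, trial, foot).

    Returns the signals and their metadata records. Each record's
    ``extra`` dict carries the ground truth: true cycle count, effective
    severity, asymmetry factor.
    """
    labels = ("F1", "R1", "F2", "R2")[: spec.trials_per_session]
    signals: List[TimeSeries] = []
    records: List[TrialRecord] = []
    for s_idx, (subject, group, severity) in enumerate(spec.subjects):
        edss = 0.0 if group == "HS" else _edss_from_severity(severity)
        for sess_idx, session in enumerate(spec.sessions):
            sev = severity
            if session == "M6":
                sev = max(0.0, sev + float(spec.session_drift.get(subject, 0.0)))
            for t_idx, label in enumerate(labels):
                for f_idx, foot in enumerate(("LF", "RF")):
                    asym = float(spec.asymmetry.get((subject, session), 1.0))
                    amp = spec.base_noise + spec.severity_noise_scale * sev
                    if foot == "LF":
                        amp *= asym
                    child = np.random.SeedSequence(
                        (spec.seed, s_idx, sess_idx, t_idx, f_idx)
                    )
                    trial_seed = int(child.generate_state(1)[0] % (2**31))
                    trial_id = f"{subject}_{session}_{label}_{foot}"
                    ts = generate_trial(
                        tmpl=spec.template,
                        n_cycles=spec.cycles_per_trial,
                        noise=NoiseSpec(amplitude=amp),
                        seed=trial_seed,
                        sampling_rate=spec.sampling_rate,
                        timing_jitter=spec.severity_jitter_scale * sev,
                        trial_id=trial_id,
                    )
                    velocity = max(0.3, 1.4 - 0.15 * sev)
                    records.append(TrialRecord(
                        trial_id=trial_id,
                        subject_id=subject,
                        group=group,
                        edss=edss,
                        session=session,
                        trial_label=label,
                        foot=foot,
                        steps=None,
                        velocity=velocity,
                        extra={
                            "true_cycles": spec.cycles_per_trial,
                            "severity": sev,
                            "asymmetry": asym if foot == "LF" else 1.0,
                        },
                    ))
                    signals.append(ts)
    return signals, records
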