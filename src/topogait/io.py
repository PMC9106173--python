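"""Readers and writers for trials, metadata, barcodes, matrices and tables.

All artifacts are plain CSV/TSV. Trial signals are one-column files (header
optional) or a long-format table with (trial_id, t, value) columns; barcode
files use the literal token ``inf`` for the infinite death.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd

from .persistence import Bar, Barcode
from .signal import DEFAULT_SAMPLING_RATE, InvalidInputError, TimeSeries, TrialRecord

__all__ = [
    "read_trial",
    "write_trial",
    "read_long_trials",
    "read_metadata",
    "write_metadata",
    "read_barcode",
    "write_barcode",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_point_cloud",
    "write_point_cloud",
    "read_cohort",
    "write_cohort",
]

_META_COLUMNS = [
    "trial_id", "subject_id", "group", "edss", "session",
    "trial_label", "foot", "steps", "velocity",
]


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_trial(
    path: Path,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    trial_id: Optional[str] = None,
) -> TimeSeries:
    """Read a one-column trial file (CSV or TSV, header optional)."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0].split(_sep_for(path))[0]
    try:
        float(first)
        header = None
    except ValueError:
        header = 0
    frame = pd.read_csv(path, sep=_sep_for(path), header=header,
                        float_precision="round_trip")
    if frame.shape[1] != 1:
        raise InvalidInputError(
            f"{path}: expected a single value column, got {frame.shape[1]}"
        )
    values = frame.iloc[:, 0].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise InvalidInputError(f"{path}: NaN samples")
    return TimeSeries(values=values, sampling_rate=sampling_rate,
                      trial_id=trial_id or path.stem)


def write_trial(ts: TimeSeries, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"value": ts.values}).to_csv(path, index=False,
                                              sep=_sep_for(path))


def read_long_trials(
    path: Path, sampling_rate: float = DEFAULT_SAMPLING_RATE
) -> List[TimeSeries]:
    """Read a long-format table with columns (trial_id, t, value)."""
    frame = pd.read_csv(path, sep=_sep_for(Path(path)),
                        float_precision="round_trip")
    needed = {"trial_id", "t", "value"}
    if not needed <= set(frame.columns):
        raise InvalidInputError(f"{path}: long format needs columns {needed}")
    out = []
    for tid, sub in frame.groupby("trial_id", sort=True):
        sub = sub.sort_values("t")
        out.append(TimeSeries(values=sub["value"].to_numpy(dtype=float),
                              sampling_rate=sampling_rate, trial_id=str(tid)))
    return out


def read_metadata(path: Path) -> List[TrialRecord]:
    frame = pd.read_csv(path, sep=_sep_for(Path(path)),
                        float_precision="round_trip")
    missing = set(_META_COLUMNS[:7]) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"{path}: metadata lacks columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        steps = row.get("steps")
        steps = None if steps is None or pd.isna(steps) else int(steps)
        vel = row.get("velocity")
        vel = None if vel is None or pd.isna(vel) else float(vel)
        records.append(TrialRecord(
            trial_id=str(row["trial_id"]),
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            edss=float(row["edss"]),
            session=str(row["session"]),
            trial_label=str(row["trial_label"]),
            foot=str(row["foot"]),
            steps=steps,
            velocity=vel,
        ))
    ids = [r.trial_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidInputError(f"{path}: duplicate trial_id(s) {dupes}")
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        raise InvalidInputError(
            f"{path}: duplicate (subject, session, trial, foot) combinations"
        )
    return records


def write_metadata(records: Sequence[TrialRecord], path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{
        "trial_id": r.trial_id, "subject_id": r.subject_id, "group": r.group,
        "edss": r.edss, "session": r.session, "trial_label": r.trial_label,
        "foot": r.foot, "steps": r.steps, "velocity": r.velocity,
    } for r in records]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False,
                                                     sep=_sep_for(path))


def write_barcode(b: Barcode, path: Path) -> None:
    """Write (birth, death) rows; infinite deaths as the token ``inf``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("birth,death\n")
        for bar in b:
            death = "inf" if bar.is_infinite else repr(bar.death)
            fh.write(f"{bar.birth!r},{death}\n")


def read_barcode(path: Path) -> Barcode:
    frame = pd.read_csv(path, float_precision="round_trip")
    bars = []
    for _, row in frame.iterrows():
        death = float(row["death"])  # pandas parses "inf" to math.inf
        bars.append(Bar(float(row["birth"]), death))
    return Barcode(bars)


def write_distance_matrix(dm: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dm.to_csv(path)


def read_distance_matrix(path: Path) -> pd.DataFrame:
    dm = pd.read_csv(path, index_col=0, float_precision="round_trip")
    dm.index = dm.index.astype(str)
    dm.columns = dm.columns.astype(str)
    return dm


def write_point_cloud(coords: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    coords.to_csv(path)


def read_point_cloud(path: Path) -> pd.DataFrame:
    pc = pd.read_csv(path, index_col=0, float_precision="round_trip")
    pc.index = pc.index.astype(str)
    return pc


def write_cohort(
    signals: Sequence[TimeSeries],
    records: Sequence[TrialRecord],
    outdir: Path,
) -> Path:
    """Write per-trial CSV files plus a metadata sheet; returns outdir."""
    outdir = Path(outdir)
    trials = outdir / "trials"
    trials.mkdir(parents=True, exist_ok=True)
    for ts in signals:
        write_trial(ts, trials / f"{ts.trial_id}.csv")
    write_metadata(records, outdir / "metadata.csv")
    return outdir


def read_cohort(
    outdir: Path, sampling_rate: float = DEFAULT_SAMPLING_RATE
) -> Tuple[List[TimeSeries], List[TrialRecord]]:
    """Read a cohort directory (trials/*.csv + metadata.csv).

    Every metadata row must match exactly one trial file; trial files with
    no metadata row are ignored with a warning.
    """
    outdir = Path(outdir)
    records = read_metadata(outdir / "metadata.csv")
    trials_dir = outdir / "trials"
    available = {p.stem: p for p in sorted(trials_dir.glob("*.csv"))}
    signals = []
    for r in records:
        if r.trial_id not in available:
            raise InvalidInputError(
                f"metadata row {r.trial_id!r} has no trial file under {trials_dir}"
            )
        signals.append(read_trial(available[r.trial_id], sampling_rate,
                                  r.trial_id))
    extra = set(available) - {r.trial_id for r in records}
    if extra:
        warnings.warn(
            f"{len(extra)} trial file(s) without metadata ignored: "
            f"{sorted(extra)[:5]}..."
        )
    return signals, records
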