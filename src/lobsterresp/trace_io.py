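"""Readers, writers and validated containers for respirometry data.

All on-disk formats are plain comma-separated text with a mandatory
header row and ``.`` decimals.  Time is stored as seconds since trial
start; the analysis never needs wall-clock time.

Fixed column dialects
---------------------
oxygen trace   : ``time_s, o2_mg_l, temp_c[, phase, cycle_index]``
chase clicks   : ``frame, x, y``  (consecutive rows pair into one tail
                 flip: first click = position before, second = after)
animal table   : ``animal_id, species, sex, body_mass_kg, body_volume_l,
                 carapace_length_cm, acclimation_temp_c, experimental_temp_c``

Readers reject inconsistent input with :class:`TraceIOError` carrying
row numbers; they never silently repair it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraceIOError",
    "Schedule",
    "OxygenTrace",
    "AnimalRecord",
    "ChaseTrack",
    "BackgroundRecord",
    "read_trace",
    "write_trace",
    "read_chase_track",
    "write_chase_track",
    "read_animals",
    "write_animals",
    "read_results",
    "write_results",
    "load_config",
    "save_config",
]

TRACE_COLUMNS = ["time_s", "o2_mg_l", "temp_c", "phase", "cycle_index"]
CLICK_COLUMNS = ["frame", "x", "y"]
ANIMAL_COLUMNS = [
    "animal_id",
    "species",
    "sex",
    "body_mass_kg",
    "body_volume_l",
    "carapace_length_cm",
    "acclimation_temp_c",
    "experimental_temp_c",
]

#: Mean lobster body density (g mL^-1) used to derive body volume from
#: mass when no displacement measurement is available.
DEFAULT_BODY_DENSITY_G_PER_ML = 1.12

MEASURE = "measure"
FLUSH = "flush"


class TraceIOError(ValueError):
    """Structured validation failure while reading or checking a file."""

    def __init__(self, message: str, errors: Sequence[str] = ()):
        self.errors = list(errors)
        if self.errors:
            message = message + "\n  - " + "\n  - ".join(self.errors)
        super().__init__(message)


@dataclass(frozen=True)
class Schedule:
    """Intermittent-flow phase schedule.

    The default 6-min sealed measurement followed by an 8-min flush is
    the cycle used for the lobster trials this package was built around.
    """

    measure_s: float = 360.0
    flush_s: float = 480.0
    start_phase: str = MEASURE

    def __post_init__(self) -> None:
        if self.measure_s <= 0 or self.flush_s < 0:
            raise ValueError("schedule durations must be positive")
        if self.start_phase not in (MEASURE, FLUSH):
            raise ValueError(f"start_phase must be '{MEASURE}' or '{FLUSH}'")

    @property
    def period_s(self) -> float:
        return self.measure_s + self.flush_s

    def phase_at(self, t_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Phase label and measure-cycle index for each time point."""
        t = np.asarray(t_s, dtype=float)
        offset = 0.0 if self.start_phase == MEASURE else self.flush_s
        shifted = t + offset
        within = np.mod(shifted, self.period_s)
        cycle = np.floor_divide(shifted, self.period_s).astype(int)
        phase = np.where(within < self.measure_s, MEASURE, FLUSH)
        return phase, cycle


@dataclass
class OxygenTrace:
    """One chamber's oxygen time series with phase labels.

    ``data`` columns: time_s (strictly increasing), o2_mg_l, temp_c,
    phase ('measure'/'flush'), cycle_index (measure-cycle counter; flush
    samples carry the index of the preceding measure phase).
    """

    data: pd.DataFrame
    channel_id: str = "ch1"

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise TraceIOError(f"trace missing columns {missing}")

    def validate(self, nominal_spacing_s: float = 10.0, rtol: float = 0.5) -> None:
        """Check monotonicity, spacing and minimum cycle length."""
        errors: list[str] = []
        t = self.data["time_s"].to_numpy(dtype=float)
        if len(t) == 0:
            raise TraceIOError("no samples")
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        for i in bad[:5]:
            errors.append(f"row {i + 2}: time not strictly increasing")
        if nominal_spacing_s is not None and len(dt):
            off = np.abs(dt - nominal_spacing_s) > rtol * nominal_spacing_s
            n_off = int(off.sum())
            if n_off:
                errors.append(
                    f"{n_off} intervals deviate >{rtol:.0%} from the nominal "
                    f"{nominal_spacing_s:g} s spacing"
                )
        meas = self.data[self.data["phase"] == MEASURE]
        counts = meas.groupby("cycle_index").size()
        for ci, n in counts.items():
            if n < 3:
                errors.append(f"measure cycle {ci} has only {n} samples (< 3)")
        if errors:
            raise TraceIOError("invalid oxygen trace", errors)

    @property
    def n_cycles(self) -> int:
        meas = self.data[self.data["phase"] == MEASURE]
        return int(meas["cycle_index"].nunique())

    def measure_cycles(self) -> Iterable[tuple[int, pd.DataFrame]]:
        meas = self.data[self.data["phase"] == MEASURE]
        return meas.groupby("cycle_index", sort=True)


@dataclass(frozen=True)
class AnimalRecord:
    """Metadata for one animal at one experimental temperature."""

    animal_id: str
    species: str
    sex: str
    body_mass_kg: float
    carapace_length_cm: float
    acclimation_temp_c: float
    experimental_temp_c: float
    body_volume_l: float | None = None

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError(f"{self.animal_id}: body_mass_kg must be > 0")

    def volume_l(self, density_g_per_ml: float = DEFAULT_BODY_DENSITY_G_PER_ML) -> float:
        """Body volume; derived from mass / density if not measured."""
        if self.body_volume_l is not None:
            return self.body_volume_l
        # mass [kg] / density [g/mL] = volume [L]
        return self.body_mass_kg / density_g_per_ml


@dataclass
class ChaseTrack:
    """Paired before/after click positions delimiting each tail flip.

    ``events`` columns: frame_start, x_start, y_start, frame_end, x_end,
    y_end.  Calibration: fps (default 24, the chase-video recording
    rate) and px_per_cm.
    """

    events: pd.DataFrame
    fps: float = 24.0
    px_per_cm: float = 1.0

    EVENT_COLUMNS = [
        "frame_start",
        "x_start",
        "y_start",
        "frame_end",
        "x_end",
        "y_end",
    ]

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")
        missing = [c for c in self.EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise TraceIOError(f"chase track missing columns {missing}")

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class BackgroundRecord:
    """Blank-chamber (microbial) respiration before and after a trial."""

    pre_rate_mg_per_h: float
    post_rate_mg_per_h: float | None = None

    def __post_init__(self) -> None:
        if self.pre_rate_mg_per_h < 0:
            raise ValueError("pre_rate_mg_per_h must be >= 0")
        if self.post_rate_mg_per_h is not None and self.post_rate_mg_per_h < 0:
            raise ValueError("post_rate_mg_per_h must be >= 0")


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TraceIOError(f"{path}: no samples") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceIOError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise TraceIOError(f"{path}: no samples")
    return df


def read_trace(
    path: str | Path,
    schedule: Schedule | None = None,
    channel_id: str = "ch1",
    validate: bool = True,
) -> OxygenTrace:
    """Read an oxygen trace CSV, assigning phases from ``schedule`` if absent.

    A phase column in the file is taken verbatim; otherwise the schedule
    is mandatory and phases/cycle indices are derived from time alone.
    """
    df = _read_csv(path, ["time_s", "o2_mg_l"])
    errors: list[str] = []
    for col in ("time_s", "o2_mg_l"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        for i in bad[:5]:
            errors.append(f"row {i + 2}: unparseable {col} value {df[col].iloc[i]!r}")
        df[col] = vals
    if errors:
        raise TraceIOError(f"{path}: unparseable numbers", errors)
    if "temp_c" not in df.columns:
        df["temp_c"] = np.nan
    if "phase" in df.columns and "cycle_index" in df.columns:
        pass  # phases taken verbatim
    else:
        if schedule is None:
            raise TraceIOError(
                f"{path}: no phase column and no schedule supplied"
            )
        phase, cycle = schedule.phase_at(df["time_s"].to_numpy(dtype=float))
        df["phase"] = phase
        df["cycle_index"] = cycle
    trace = OxygenTrace(df[TRACE_COLUMNS].copy(), channel_id=channel_id)
    if validate:
        trace.validate()
    return trace


def write_trace(trace: OxygenTrace, path: str | Path) -> Path:
    path = Path(path)
    trace.data.to_csv(path, index=False)
    return path


def read_chase_track(
    path: str | Path, fps: float = 24.0, px_per_cm: float = 1.0
) -> ChaseTrack:
    """Read a click file and pair consecutive clicks into tail-flip events."""
    df = _read_csv(path, CLICK_COLUMNS)
    frames = pd.to_numeric(df["frame"], errors="coerce")
    if frames.isna().any():
        i = int(np.flatnonzero(frames.isna().to_numpy())[0])
        raise TraceIOError(f"{path}: row {i + 2}: unparseable frame number")
    frames = frames.to_numpy(dtype=float)
    decreasing = np.flatnonzero(np.diff(frames) < 0)
    if len(decreasing):
        i = int(decreasing[0])
        raise TraceIOError(
            f"{path}: row {i + 3}: frame number decreases "
            f"({frames[i + 1]:g} after {frames[i]:g})"
        )
    if len(df) % 2:
        raise TraceIOError(
            f"{path}: odd number of clicks ({len(df)}); every tail flip "
            "needs a before and an after click"
        )
    start = df.iloc[0::2].reset_index(drop=True)
    end = df.iloc[1::2].reset_index(drop=True)
    events = pd.DataFrame(
        {
            "frame_start": start["frame"].to_numpy(dtype=float),
            "x_start": start["x"].to_numpy(dtype=float),
            "y_start": start["y"].to_numpy(dtype=float),
            "frame_end": end["frame"].to_numpy(dtype=float),
            "x_end": end["x"].to_numpy(dtype=float),
            "y_end": end["y"].to_numpy(dtype=float),
        }
    )
    return ChaseTrack(events, fps=fps, px_per_cm=px_per_cm)


def write_chase_track(track: ChaseTrack, path: str | Path) -> Path:
    """Write a track back to click rows (inverse of :func:`read_chase_track`)."""
    path = Path(path)
    n = len(track.events)
    rows = np.empty((2 * n, 3), dtype=float)
    ev = track.events
    rows[0::2] = ev[["frame_start", "x_start", "y_start"]].to_numpy()
    rows[1::2] = ev[["frame_end", "x_end", "y_end"]].to_numpy()
    pd.DataFrame(rows, columns=CLICK_COLUMNS).to_csv(path, index=False)
    return path


def read_animals(path: str | Path) -> list[AnimalRecord]:
    df = _read_csv(path, [c for c in ANIMAL_COLUMNS if c != "body_volume_l"])
    records = []
    for _, row in df.iterrows():
        vol = row.get("body_volume_l", np.nan)
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                species=str(row["species"]),
                sex=str(row["sex"]),
                body_mass_kg=float(row["body_mass_kg"]),
                body_volume_l=None if pd.isna(vol) else float(vol),
                carapace_length_cm=float(row["carapace_length_cm"]),
                acclimation_temp_c=float(row["acclimation_temp_c"]),
                experimental_temp_c=float(row["experimental_temp_c"]),
            )
        )
    return records


def write_animals(records: Iterable[AnimalRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "species": r.species,
                "sex": r.sex,
                "body_mass_kg": r.body_mass_kg,
                "body_volume_l": np.nan if r.body_volume_l is None else r.body_volume_l,
                "carapace_length_cm": r.carapace_length_cm,
                "acclimation_temp_c": r.acclimation_temp_c,
                "experimental_temp_c": r.experimental_temp_c,
            }
            for r in records
        ],
        columns=ANIMAL_COLUMNS,
    )
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table with deterministic column order (round-trip stable)."""
    path = Path(path)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, [])


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TraceIOError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
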