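"""Reading and writing trajectory recordings, manifests, and result tables.

The on-disk formats are deliberately plain: tidy tab-separated text with one
row per (trial, sensor, sample) for trajectories, one row per trial for the
manifest, and one row per (participant, task, trial, effector, measure) for
results.  Positions are stored in centimetres; the time column is derived
from the integer sample index and the sampling rate, so the sample index is
the authoritative time base.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Finger",
    "Phalanx",
    "Digit",
    "TaskLabel",
    "SensorId",
    "TrialRecording",
    "ValidationError",
    "ALL_TASKS",
    "ALL_SENSORS",
    "REFERENCE_SENSOR",
    "read_trials",
    "write_trials",
    "write_results",
    "read_results",
    "validate_results",
    "RESULT_MEASURES",
    "RESULT_KEY",
]


class ValidationError(ValueError):
    """Raised when an input file or table violates the format contract."""


class Finger(str, enum.Enum):
    INDEX = "index"
    MIDDLE = "middle"
    RING = "ring"
    LITTLE = "little"


class Phalanx(str, enum.Enum):
    DISTAL = "distal"
    MIDDLE = "middle"
    PROXIMAL = "proximal"


class Digit(str, enum.Enum):
    THUMB = "thumb"
    INDEX = "index"
    MIDDLE = "middle"
    RING = "ring"
    LITTLE = "little"
    REFERENCE = "reference"


_FINGER_CODE = {Finger.INDEX: "I", Finger.MIDDLE: "M", Finger.RING: "R", Finger.LITTLE: "L"}
_PHALANX_CODE = {Phalanx.DISTAL: "D", Phalanx.MIDDLE: "M", Phalanx.PROXIMAL: "P"}
_CODE_FINGER = {v: k for k, v in _FINGER_CODE.items()}
_CODE_PHALANX = {v: k for k, v in _PHALANX_CODE.items()}


@dataclass(frozen=True, order=True)
class TaskLabel:
    """One opposition task: which finger and which phalanx the thumb reaches for.

    Serialises to the two-letter code used throughout the reports: the finger
    initial (I/M/R/L) followed by the phalanx initial (D/M/P), e.g. ``"ID"``
    for index-finger distal phalanx.
    """

    finger: Finger
    phalanx: Phalanx

    @property
    def code(self) -> str:
        return _FINGER_CODE[self.finger] + _PHALANX_CODE[self.phalanx]

    @classmethod
    def from_code(cls, code: str) -> "TaskLabel":
        code = code.strip().upper()
        if len(code) != 2 or code[0] not in _CODE_FINGER or code[1] not in _CODE_PHALANX:
            raise ValidationError(f"unknown task code {code!r} (expected e.g. 'ID', 'LP')")
        return cls(_CODE_FINGER[code[0]], _CODE_PHALANX[code[1]])

    @property
    def target_sensor(self) -> "SensorId":
        """The sensor on the instructed phalanx of the instructed finger."""
        return SensorId(Digit(self.finger.value), self.phalanx)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.code


ALL_TASKS: tuple[TaskLabel, ...] = tuple(
    TaskLabel(f, p) for f in Finger for p in Phalanx
)


@dataclass(frozen=True, order=True)
class SensorId:
    """Identity of one tracking sensor: a digit plus a phalanx segment.

    The wrist reference sensor carries ``segment=None``.  There are 16 valid
    ids: five digits x three segments plus the reference.
    """

    digit: Digit
    segment: Phalanx | None

    def __post_init__(self) -> None:
        if (self.digit is Digit.REFERENCE) != (self.segment is None):
            raise ValidationError(
                "reference sensor must have no segment and vice versa: "
                f"{self.digit.value}/{self.segment}"
            )

    @property
    def name(self) -> str:
        if self.digit is Digit.REFERENCE:
            return "reference"
        return f"{self.digit.value}_{self.segment.value}"

    @classmethod
    def from_name(cls, name: str) -> "SensorId":
        name = name.strip()
        if name == "reference":
            return cls(Digit.REFERENCE, None)
        try:
            digit, segment = name.split("_")
            return cls(Digit(digit), Phalanx(segment))
        except ValueError as exc:
            raise ValidationError(f"unknown sensor name {name!r}") from exc

    def __str__(self) -> str:  # pragma: no cover
        return self.name


REFERENCE_SENSOR = SensorId(Digit.REFERENCE, None)
ALL_SENSORS: tuple[SensorId, ...] = tuple(
    SensorId(d, p) for d in Digit if d is not Digit.REFERENCE for p in Phalanx
) + (REFERENCE_SENSOR,)
SENSOR_NAMES: tuple[str, ...] = tuple(s.name for s in ALL_SENSORS)


@dataclass
class TrialRecording:
    """One trial's multi-sensor 3D position time series.

    ``positions`` maps sensor name -> float array of shape ``(n_samples, 3)``
    in centimetres.  All sensors must share the sample count
    ``round(fs * duration)``.
    """

    participant_id: str
    trial_index: int
    task: TaskLabel
    fs: float
    duration: float
    positions: dict[str, np.ndarray] = field(repr=False)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def validate(self) -> "TrialRecording":
        if self.fs <= 0 or self.duration <= 0:
            raise ValidationError(
                f"trial {self.trial_index}: fs and duration must be positive"
            )
        if self.trial_index < 1:
            raise ValidationError(f"trial index must be >= 1, got {self.trial_index}")
        n = self.n_samples
        missing = set(SENSOR_NAMES) - set(self.positions)
        if missing:
            raise ValidationError(
                f"trial {self.trial_index}: missing sensor(s) {sorted(missing)}"
            )
        for name, xyz in self.positions.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 2 or xyz.shape[1] != 3:
                raise ValidationError(
                    f"trial {self.trial_index}, sensor {name}: expected (n, 3) positions"
                )
            if xyz.shape[0] != n:
                raise ValidationError(
                    f"trial {self.trial_index}, sensor {name}: ragged sample count "
                    f"{xyz.shape[0]} != {n}"
                )
            if not np.all(np.isfinite(xyz)):
                raise ValidationError(
                    f"trial {self.trial_index}, sensor {name}: non-finite samples"
                )
            self.positions[name] = xyz
        return self


# --------------------------------------------------------------------------
# Trajectory TSV
# --------------------------------------------------------------------------

_TRAJ_COLUMNS = ["trial", "time_s", "sensor", "x_cm", "y_cm", "z_cm"]
_MANIFEST_COLUMNS = ["trial", "participant", "task"]


def write_trials(recs: Sequence[TrialRecording], path: str | Path) -> None:
    """Write recordings as tidy TSV (columns trial, time_s, sensor, x/y/z_cm).

    Numbers are printed with 8 significant digits so a write -> read -> write
    cycle is byte-stable.
    """
    frames = []
    for rec in recs:
        rec.validate()
        t = rec.time
        for name in SENSOR_NAMES:
            xyz = rec.positions[name]
            frames.append(
                pd.DataFrame(
                    {
                        "trial": rec.trial_index,
                        "time_s": t,
                        "sensor": name,
                        "x_cm": xyz[:, 0],
                        "y_cm": xyz[:, 1],
                        "z_cm": xyz[:, 2],
                    }
                )
            )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=_TRAJ_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    cols = list(manifest.columns)
    if cols[:3] != _MANIFEST_COLUMNS and set(_MANIFEST_COLUMNS) - set(cols):
        raise ValidationError(f"manifest needs columns {_MANIFEST_COLUMNS}, got {cols}")
    manifest.to_csv(path, sep="\t", index=False)


def read_trials(
    path: str | Path, manifest: str | Path | pd.DataFrame
) -> list[TrialRecording]:
    """Read a trajectory TSV plus its manifest into validated recordings.

    The sampling rate is inferred from the time column of each trial (the
    writer derives time from the sample index, so the grid is uniform).
    Raises :class:`ValidationError` naming the offending trial and sensor on
    any structural problem.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _TRAJ_COLUMNS:
        raise ValidationError(
            f"trajectory file {path}: expected columns {_TRAJ_COLUMNS}, got {list(df.columns)}"
        )
    if isinstance(manifest, (str, Path)):
        man = pd.read_csv(manifest, sep="\t")
    else:
        man = manifest.copy()
    missing_cols = set(_MANIFEST_COLUMNS) - set(man.columns)
    if missing_cols:
        raise ValidationError(f"manifest: missing columns {sorted(missing_cols)}")
    if man["trial"].duplicated().any():
        dup = man.loc[man["trial"].duplicated(), "trial"].iloc[0]
        raise ValidationError(f"manifest: duplicate trial {dup}")
    man = man.set_index("trial")

    recs: list[TrialRecording] = []
    for trial, g in df.groupby("trial", sort=True):
        if trial not in man.index:
            raise ValidationError(f"trial {trial}: not present in manifest")
        row = man.loc[trial]
        task = TaskLabel.from_code(str(row["task"]))
        positions: dict[str, np.ndarray] = {}
        counts = set()
        fs = None
        for sensor, sg in g.groupby("sensor", sort=False):
            if sensor not in SENSOR_NAMES:
                raise ValidationError(f"trial {trial}: unknown sensor {sensor!r}")
            t = sg["time_s"].to_numpy()
            if len(t) > 1:
                dt = np.diff(t)
                if np.any(dt <= 0):
                    raise ValidationError(
                        f"trial {trial}, sensor {sensor}: non-monotone time column"
                    )
                fs_here = 1.0 / np.median(dt)
                fs = fs_here if fs is None else fs
                if abs(fs_here - fs) > 1e-6 * fs:
                    raise ValidationError(
                        f"trial {trial}, sensor {sensor}: inconsistent sampling rate"
                    )
            positions[sensor] = sg[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
            counts.add(len(sg))
        missing = set(SENSOR_NAMES) - set(positions)
        if missing:
            raise ValidationError(
                f"trial {trial}: missing sensor(s) {sorted(missing)}"
            )
        if len(counts) != 1:
            raise ValidationError(f"trial {trial}: ragged sample counts {sorted(counts)}")
        n = counts.pop()
        if fs is None:
            raise ValidationError(f"trial {trial}: fewer than 2 samples")
        fs = float(np.round(fs, 6))
        recs.append(
            TrialRecording(
                participant_id=str(row["participant"]),
                trial_index=int(trial),
                task=task,
                fs=fs,
                duration=n / fs,
                positions=positions,
            ).validate()
        )
    return recs


# --------------------------------------------------------------------------
# Results TSV
# --------------------------------------------------------------------------

RESULT_KEY = ["participant", "task", "trial", "effector"]
RESULT_MEASURES = ("displacement", "D", "z_D", "SAL")
_RESULT_COLUMNS = RESULT_KEY + ["measure", "value"]


def validate_results(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format results table: required columns, unique key."""
    missing = set(_RESULT_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"results table: missing columns {sorted(missing)}")
    bad = set(table["measure"].unique()) - set(RESULT_MEASURES)
    if bad:
        raise ValidationError(f"results table: unknown measures {sorted(bad)}")
    key = RESULT_KEY + ["measure"]
    dups = table.duplicated(subset=key)
    if dups.any():
        first = table.loc[dups, key].iloc[0].to_dict()
        raise ValidationError(f"results table: duplicate key row {first}")
    return table


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    validate_results(table)
    table[_RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results(path: str | Path) -> pd.DataFrame:
    return validate_results(pd.read_csv(path, sep="\t"))
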