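"""Data model and I/O for ankle-worn IMU recordings.

Two inertial sensor units, one strapped laterally above each ankle, record
tri-axial accelerometer (range ±16 g) and gyroscope (range ±2000 °/s)
streams at a nominal 200 Hz during a six-minute walk test.  Magnetometer
channels are deliberately not modelled: indoor magnetic distortions make
them unreliable and the downstream orientation estimate is magnetometer
free.

Canonical internal units are SI throughout: seconds, metres, m/s² and
rad/s.  Files may declare accelerometer data in ``g`` and gyroscope data
in ``deg/s``; readers normalise on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

GRAVITY = 9.80665  # m/s², standard gravity
NOMINAL_FS = 200.0  # Hz
ACCEL_SPAN = 16.0 * GRAVITY  # ±16 g
GYRO_SPAN = np.deg2rad(2000.0)  # ±2000 °/s
_DEG2RAD = np.pi / 180.0

#: minimum left/right overlap accepted by :func:`synchronize_pair`
MIN_OVERLAP_S = 30.0


class RecordingError(ValueError):
    """Raised for malformed or physically implausible recordings."""


@dataclass
class ImuRecording:
    """One ankle sensor's synchronized accelerometer/gyroscope streams.

    Attributes
    ----------
    t : ndarray, shape (N,)
        Timestamps in seconds, strictly increasing, nominally 200 Hz.
    accel : ndarray, shape (N, 3)
        Specific force in m/s² (gravity included, as measured).
    gyro : ndarray, shape (N, 3)
        Angular velocity in rad/s.
    side : str
        ``"left"`` or ``"right"``.
    sensor_id : str
        Free-form hardware identifier.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    side: str
    sensor_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.side not in ("left", "right"):
            raise RecordingError(f"side must be 'left' or 'right', got {self.side!r}")
        n = self.t.shape[0]
        if self.accel.shape != (n, 3):
            raise RecordingError(
                f"accel shape {self.accel.shape} does not match {n} timestamps"
            )
        if self.gyro.shape != (n, 3):
            raise RecordingError(
                f"gyro shape {self.gyro.shape} does not match {n} timestamps"
            )
        dt = np.diff(self.t)
        if n > 1 and not np.all(dt > 0):
            idx = int(np.argmax(dt <= 0))
            raise RecordingError(f"timestamps not strictly increasing at index {idx + 1}")
        if np.any(np.abs(self.accel) > ACCEL_SPAN * 1.001):
            raise RecordingError("accelerometer values exceed the ±16 g sensor span")
        if np.any(np.abs(self.gyro) > GYRO_SPAN * 1.001):
            raise RecordingError("gyroscope values exceed the ±2000 °/s sensor span")

    @property
    def fs(self) -> float:
        """Median sampling rate in Hz."""
        if len(self.t) < 2:
            return NOMINAL_FS
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def gap_mask(self) -> np.ndarray:
        """Boolean mask over inter-sample intervals exceeding 3 nominal periods."""
        return np.diff(self.t) > 3.0 / NOMINAL_FS


@dataclass
class TrialMetadata:
    """Per-trial subject and clinical context.

    ``lems_left``/``lems_right`` are the per-leg lower-extremity motor
    scores (0–25 each); the side with the lower score is treated as the
    more impaired side downstream.
    """

    subject_id: str
    cohort: str = "SCI"  # "SCI" | "HC"
    days_since_injury: float | None = None
    measured_6mwt_distance: float | None = None
    lems_left: float | None = None
    lems_right: float | None = None
    clinical: dict = field(default_factory=dict)  # SCIM, WISCI, AIS, NLI, aids...
    demographics: dict = field(default_factory=dict)  # age, sex, BMI

    def __post_init__(self) -> None:
        if self.cohort not in ("SCI", "HC"):
            raise ValueError(f"cohort must be 'SCI' or 'HC', got {self.cohort!r}")
        if self.measured_6mwt_distance is not None and self.measured_6mwt_distance < 0:
            raise ValueError("6MWT distance must be >= 0")
        for name, v in (("lems_left", self.lems_left), ("lems_right", self.lems_right)):
            if v is not None and not (0 <= v <= 25):
                raise ValueError(f"{name} must lie in [0, 25], got {v}")


# ---------------------------------------------------------------------------
# unit handling
# ---------------------------------------------------------------------------

def _accel_factor(unit: str) -> float:
    unit = unit.strip().lower()
    if unit in ("m/s^2", "m/s2", "m/s²", "ms-2"):
        return 1.0
    if unit == "g":
        return GRAVITY
    raise RecordingError(f"unknown accelerometer unit {unit!r}")


def _gyro_factor(unit: str) -> float:
    unit = unit.strip().lower()
    if unit in ("rad/s", "rads-1"):
        return 1.0
    if unit in ("deg/s", "°/s", "dps"):
        return _DEG2RAD
    raise RecordingError(f"unknown gyroscope unit {unit!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


def write_recording_csv(path, rec: ImuRecording, accel_unit: str = "m/s^2",
                        gyro_unit: str = "rad/s") -> None:
    """Write one recording as CSV (header ``t,ax,ay,az,gx,gy,gz``).

    A ``# units:`` comment line declares the stored units; a ``# side:``
    line carries the side label.
    """
    fa, fg = _accel_factor(accel_unit), _gyro_factor(gyro_unit)
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.accel / fa, rec.gyro / fg]), columns=CSV_COLUMNS
    )
    with open(path, "w") as fh:
        fh.write(f"# units: accel={accel_unit} gyro={gyro_unit} t=s\n")
        fh.write(f"# side: {rec.side}\n")
        fh.write(f"# sensor_id: {rec.sensor_id}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def _read_csv(path) -> ImuRecording:
    accel_unit, gyro_unit, side, sensor_id = "m/s^2", "rad/s", None, ""
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("units:"):
                for tok in body[len("units:"):].split():
                    k, _, v = tok.partition("=")
                    if k == "accel":
                        accel_unit = v
                    elif k == "gyro":
                        gyro_unit = v
            elif body.startswith("side:"):
                side = body.split(":", 1)[1].strip()
            elif body.startswith("sensor_id:"):
                sensor_id = body.split(":", 1)[1].strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        if set(missing) >= {"gx", "gy", "gz"}:
            raise RecordingError("missing gyro")
        if set(missing) >= {"ax", "ay", "az"}:
            raise RecordingError("missing accel")
        raise RecordingError(f"missing channels: {missing}")
    return ImuRecording(
        t=df["t"].to_numpy(),
        accel=df[["ax", "ay", "az"]].to_numpy() * _accel_factor(accel_unit),
        gyro=df[["gx", "gy", "gz"]].to_numpy() * _gyro_factor(gyro_unit),
        side=side or "left",
        sensor_id=sensor_id,
    )


def write_trial_hdf5(path, left: ImuRecording, right: ImuRecording) -> None:
    """Write a two-sensor trial: groups ``/left`` and ``/right``, each with
    datasets ``t``, ``accel``, ``gyro`` and unit attributes."""
    with h5py.File(path, "w") as f:
        for rec in (left, right):
            g = f.create_group(rec.side)
            g.create_dataset("t", data=rec.t)
            g.create_dataset("accel", data=rec.accel)
            g.create_dataset("gyro", data=rec.gyro)
            g.attrs["accel_unit"] = "m/s^2"
            g.attrs["gyro_unit"] = "rad/s"
            g.attrs["sensor_id"] = rec.sensor_id


def _read_hdf5_side(path, side: str) -> ImuRecording:
    with h5py.File(path, "r") as f:
        if side not in f:
            raise RecordingError(f"no group {side!r} in {path}")
        g = f[side]
        for ch in ("t", "accel", "gyro"):
            if ch not in g:
                raise RecordingError(f"missing {ch}" if ch != "gyro" else "missing gyro")
        fa = _accel_factor(g.attrs.get("accel_unit", "m/s^2"))
        fg = _gyro_factor(g.attrs.get("gyro_unit", "rad/s"))
        return ImuRecording(
            t=g["t"][:],
            accel=g["accel"][:] * fa,
            gyro=g["gyro"][:] * fg,
            side=side,
            sensor_id=str(g.attrs.get("sensor_id", "")),
        )


def read_recording(path, format: str = "csv", side: str | None = None) -> ImuRecording:
    """Read one sensor's recording, normalising units to m/s² and rad/s.

    Parameters
    ----------
    format : {"csv", "hdf5"}
    side : str, optional
        Required for HDF5 trial files (which hold both sides).

    Gaps longer than three nominal sample intervals are reported with a
    warning; downstream stride detection treats them like rests.
    """
    if format == "csv":
        rec = _read_csv(path)
    elif format == "hdf5":
        if side is None:
            raise ValueError("side required for hdf5 trial files")
        rec = _read_hdf5_side(path, side)
    else:
        raise ValueError(f"unknown format {format!r}")
    ngaps = int(rec.gap_mask().sum())
    if ngaps:
        warnings.warn(f"{ngaps} timestamp gaps > 3 sample intervals in {path}")
    return rec


def read_trial_hdf5(path) -> tuple[ImuRecording, ImuRecording]:
    return read_recording(path, "hdf5", "left"), read_recording(path, "hdf5", "right")


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def synchronize_pair(
    left: ImuRecording, right: ImuRecording, fs: float = NOMINAL_FS
) -> tuple[ImuRecording, ImuRecording]:
    """Resample both sensors onto one uniform time grid.

    The hardware synchronizes clocks over Bluetooth but the two streams
    start and stop independently; this trims to the overlapping interval
    and linearly interpolates both onto a shared uniform ``fs`` grid.

    Raises
    ------
    RecordingError
        If the streams overlap by less than 30 s.
    """
    t0 = max(left.t[0], right.t[0])
    t1 = min(left.t[-1], right.t[-1])
    if t1 - t0 < MIN_OVERLAP_S:
        raise RecordingError(
            f"left/right overlap {max(t1 - t0, 0.0):.1f} s < {MIN_OVERLAP_S:.0f} s"
        )
    grid = t0 + np.arange(int(np.floor((t1 - t0) * fs + 1e-9)) + 1) / fs
    out = []
    for rec in (left, right):
        accel = np.column_stack([np.interp(grid, rec.t, rec.accel[:, i]) for i in range(3)])
        gyro = np.column_stack([np.interp(grid, rec.t, rec.gyro[:, i]) for i in range(3)])
        out.append(replace(rec, t=grid.copy(), accel=accel, gyro=gyro))
    return out[0], out[1]


def sagittal_rate(rec: ImuRecording) -> np.ndarray:
    """Angular velocity about the medio-lateral axis (the sagittal-plane
    rotation rate ω_z), chosen as the gyro axis with the largest variance.

    Straps rotate and mounting is never guaranteed, so the axis is picked
    from the data rather than assumed; sign is resolved downstream.
    """
    idx = int(np.argmax(np.var(rec.gyro, axis=0)))
    return rec.gyro[:, idx]
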