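"""Magnetometer-free orientation and per-stride 3D trajectory reconstruction.

Orientation is tracked by strapdown integration of the gyroscope with
the inclination continuously corrected toward the accelerometer's
gravity direction (complementary filter).  Heading is unobservable
without a magnetometer and is left free; each stride's horizontal axes
are instead rotated so that the net displacement defines the forward
axis, which is the natural convention for hallway walking.

Displacement per stride comes from double trapezoidal integration of
the gravity-compensated global-frame acceleration between two
mid-stance instants, where the ankle is momentarily still: velocity is
pinned to zero at both ends (zero-velocity update) and residual linear
velocity drift is removed before the second integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .sensor_io import GRAVITY, ImuRecording

log = logging.getLogger(__name__)

COMPLEMENTARY_GAIN = 0.01  # per sample at 200 Hz (~0.5 s time constant)
ACCEL_GATE = 0.5  # m/s²: apply inclination correction only near 1 g
FREEFALL_ACCEL = 0.5  # m/s²: sustained |a| below this is invalid input
MIN_STRIDE_DISPLACEMENT = 0.2  # m: shorter strides treated as turns
GRAVITY_VEC = np.array([0.0, 0.0, GRAVITY])


class TrajectoryError(ValueError):
    pass


@dataclass
class OrientationSeries:
    """Unit quaternions (scalar-last, scipy convention) mapping the sensor
    frame to a gravity-aligned global frame at every sample."""

    t: np.ndarray
    quat: np.ndarray  # (N, 4)

    def rotations(self) -> Rotation:
        return Rotation.from_quat(self.quat)

    def inclination_deg(self) -> np.ndarray:
        """Angle between the sensor's vertical estimate and true vertical."""
        z_sensor = self.rotations().apply(np.repeat([[0.0, 0.0, 1.0]], len(self.t), 0),
                                          inverse=True)
        return np.degrees(np.arccos(np.clip(z_sensor[:, 2], -1.0, 1.0)))


@dataclass
class StrideTrajectory:
    """One stride's reconstructed ankle displacement.

    ``disp`` axes are (forward, lateral, vertical) with the origin at the
    stride start; the forward axis is the net-displacement direction.
    """

    t: np.ndarray
    disp: np.ndarray  # (M, 3)
    stride_length: float  # m, horizontal start-to-end distance
    stride_height: float  # m, max vertical displacement
    stride_width: float  # m, max |lateral| displacement
    stride_duration: float  # s
    stride_speed: float  # m/s

    @property
    def is_turn(self) -> bool:
        return self.stride_length < MIN_STRIDE_DISPLACEMENT


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def estimate_orientation(recording: ImuRecording,
                         gain: float = COMPLEMENTARY_GAIN) -> OrientationSeries:
    """Complementary-filter attitude estimate.

    Gyro strapdown prediction, with the tilt pulled toward the measured
    gravity direction by ``gain`` per sample whenever the accelerometer
    magnitude is within ±0.5 m/s² of 1 g (during impacts and swing the
    accelerometer does not point along gravity and is ignored).
    """
    a = recording.accel
    g = recording.gyro
    t = recording.t
    n = len(t)
    amag = np.linalg.norm(a, axis=1)
    if np.median(amag) < FREEFALL_ACCEL:
        raise TrajectoryError("free-fall or dead input: no gravity signal")

    # initialise from the first near-static accel direction
    i0 = int(np.argmax(np.abs(amag - GRAVITY) < ACCEL_GATE))
    q = _tilt_from_accel(a[i0])
    quats = np.empty((n, 4))
    quats[0] = q.as_quat()
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        q = q * Rotation.from_rotvec(g[i - 1] * dt)
        if abs(amag[i] - GRAVITY) < ACCEL_GATE:
            # rotate the predicted gravity direction toward the measurement
            z_meas = a[i] / amag[i]  # gravity direction in sensor frame
            z_pred = q.apply([0.0, 0.0, 1.0], inverse=True)
            axis = np.cross(z_meas, z_pred)
            s = np.linalg.norm(axis)
            if s > 1e-12:
                angle = np.arcsin(np.clip(s, -1.0, 1.0))
                corr = Rotation.from_rotvec(axis / s * (gain * angle))
                q = q * corr
        quats[i] = q.as_quat()
    return OrientationSeries(t=t, quat=quats)


def _tilt_from_accel(a: np.ndarray) -> Rotation:
    """Rotation taking the sensor frame to a frame whose z is along gravity."""
    z = a / np.linalg.norm(a)
    axis = np.cross(z, [0.0, 0.0, 1.0])
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return Rotation.identity()
    angle = np.arctan2(s, z[2])
    return Rotation.from_rotvec(axis / s * angle).inv()


# ---------------------------------------------------------------------------
# zero-velocity anchors
# ---------------------------------------------------------------------------

def midstance_instants(recording: ImuRecording, events) -> np.ndarray:
    """One zero-velocity anchor per stance: the sample of minimum gyro
    norm between each initial contact and the following final contact."""
    gn = np.linalg.norm(recording.gyro, axis=1)
    t = recording.t
    anchors = []
    ics = np.asarray(events.initial_contacts)
    fcs = np.asarray(events.final_contacts)
    for ic in ics:
        nxt = fcs[fcs > ic]
        if not len(nxt):
            continue
        lo, hi = np.searchsorted(t, (ic, nxt[0]))
        if hi - lo < 2:
            continue
        anchors.append(t[lo + int(np.argmin(gn[lo:hi]))])
    return np.asarray(anchors)


# ---------------------------------------------------------------------------
# stride reconstruction
# ---------------------------------------------------------------------------

def reconstruct_stride(recording: ImuRecording, orientation: OrientationSeries,
                       interval: tuple[float, float]) -> StrideTrajectory | None:
    """Reconstruct the ankle path between two mid-stance instants.

    Steps: rotate specific force to the global frame, subtract gravity,
    integrate to velocity (trapezoid), enforce zero velocity at both
    ends by linear detrending, integrate again to displacement, then
    rotate the horizontal plane so net displacement is the forward axis.

    Returns ``None`` (and logs) when the interval holds fewer than four
    samples.
    """
    t0, t1 = interval
    lo, hi = np.searchsorted(recording.t, (t0, t1))
    hi = min(hi + 1, len(recording.t))
    if hi - lo < 4:
        log.warning("stride %.2f-%.2f s dropped: no mid-stance anchor support", t0, t1)
        return None
    ts = recording.t[lo:hi]
    rot = Rotation.from_quat(orientation.quat[lo:hi])
    a_global = rot.apply(recording.accel[lo:hi]) - GRAVITY_VEC

    vel = cumulative_trapezoid(a_global, ts, axis=0, initial=0.0)
    # ZUPT: velocity must vanish at both anchors; remove linear drift
    T = ts[-1] - ts[0]
    vel -= np.outer((ts - ts[0]) / T, vel[-1])
    disp = cumulative_trapezoid(vel, ts, axis=0, initial=0.0)
    # level walking: both mid-stance anchors are on the ground, so any net
    # vertical displacement is residual drift; remove its linear ramp
    disp[:, 2] -= (ts - ts[0]) / T * disp[-1, 2]

    # heading alignment: net horizontal displacement defines forward
    net = disp[-1, :2]
    norm = np.linalg.norm(net)
    if norm > 1e-9:
        c, s = net / norm
        R = np.array([[c, s], [-s, c]])
        horiz = disp[:, :2] @ R.T
    else:
        horiz = disp[:, :2]
    out = np.column_stack([horiz, disp[:, 2]])
    length = float(norm)
    return StrideTrajectory(
        t=ts, disp=out,
        stride_length=length,
        stride_height=float(np.max(out[:, 2]) - out[0, 2]),
        stride_width=float(np.max(np.abs(out[:, 1] - out[0, 1]))),
        stride_duration=float(T),
        stride_speed=length / float(T) if T > 0 else np.nan,
    )


def reconstruct_strides(recording: ImuRecording, orientation: OrientationSeries,
                        anchors: np.ndarray) -> list[StrideTrajectory]:
    """All stride trajectories between consecutive mid-stance anchors,
    excluding probable turns (net displacement < 0.2 m)."""
    out = []
    for t0, t1 in zip(anchors[:-1], anchors[1:]):
        st = reconstruct_stride(recording, orientation, (t0, t1))
        if st is not None:
            out.append(st)
    return out


def compute_walking_speed(strides: list[StrideTrajectory]
                          ) -> tuple[np.ndarray, float, float]:
    """Per-stride speeds, their mean, and the sensor-estimated distance
    (sum of one foot's stride lengths; rest time adds no distance)."""
    if not strides:
        raise TrajectoryError("need at least one stride")
    walking = [s for s in strides if not s.is_turn]
    if not walking:
        walking = strides
    speeds = np.array([s.stride_speed for s in walking])
    distance = float(sum(s.stride_length for s in walking))
    return speeds, float(np.mean(speeds)), distance
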