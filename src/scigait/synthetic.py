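"""Synthetic ankle-IMU trials and cohorts with planted ground truth.

Real six-minute-walk recordings of spinal-cord-injured patients are not
publicly distributable, so every stage of the pipeline is exercised
against simulated data in which the answer is known by construction:

* :func:`simulate_trial` builds a kinematically explicit two-ankle trial:
  each stride's endpoint path is a smooth closed-loop 3D curve that hits
  the planted stride length / height / width exactly, the foot is still
  during stance (so zero-velocity updates are valid), the accelerometer
  is the analytic second derivative of that path expressed in a tilting
  sensor frame plus gravity and noise, and the sagittal gyro channel is
  the shank angular velocity plus bias and noise.
* :func:`simulate_cohort_features` plants Gaussian cluster structure in a
  per-trial feature table.
* :func:`simulate_longitudinal_cohort` plants a (configurable) dependence
  of future 6MWT change on present gait features.

The generator makes no claim of musculoskeletal realism; its job is to
be *internally consistent* so that pipeline errors are attributable to
the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .sensor_io import GRAVITY, NOMINAL_FS, ImuRecording

# shank rotation model: one forward-swing lobe per stride plus Gaussian
# reversal dips at the foot contacts, sized so the net rotation per stride
# is zero (the shank returns to the same tilt each cycle)
SWING_ROTATION_RAD = 1.0  # net forward shank rotation during swing
CONTACT_DIP_SIGMA_S = 0.05  # width of the contact reversal dips
SETTLE_S = 0.25  # standstill before the first initial contact of a segment


class SimulationError(ValueError):
    pass


@dataclass
class GaitProfile:
    """Planted gait parameters for one simulated 6-minute walk.

    ``double_support_fraction`` is kinematically tied to the swing
    fraction for a periodic bipedal gait (both feet are on the ground a
    fraction ``1 - 2*swing_fraction`` of the stride, independent of the
    left-right phase offset); leave it ``None`` to derive it, or supply a
    consistent value.

    ``asym_factors`` maps parameter names (``stride_length``,
    ``stride_height``, ``stride_width``, ``step_duration``) to
    left/right multiplicative ratios; 1 means symmetric.
    """

    stride_duration_mean: float = 1.1  # s
    stride_duration_cv: float = 0.03  # fraction
    stride_length_mean: float = 1.2  # m
    stride_length_cv: float | None = None  # defaults to stride_duration_cv
    stride_height_mean: float = 0.12  # m
    stride_width_mean: float = 0.05  # m
    swing_fraction: float = 0.38  # fraction of stride
    double_support_fraction: float | None = None
    asym_factors: dict = field(default_factory=dict)
    speed_drift: float = 0.0  # fractional speed change per minute
    rest_breaks: list = field(default_factory=list)  # (start s, duration s)
    trial_duration: float = 360.0  # s

    def __post_init__(self) -> None:
        if min(self.stride_duration_mean, self.stride_length_mean,
               self.trial_duration) <= 0:
            raise SimulationError("durations and lengths must be positive")
        if not 0 < self.swing_fraction < 0.5:
            raise SimulationError("swing_fraction must lie in (0, 0.5)")
        ds_implied = 1.0 - 2.0 * self.swing_fraction
        if self.double_support_fraction is None:
            self.double_support_fraction = ds_implied
        elif abs(self.double_support_fraction - ds_implied) > 1e-9:
            raise SimulationError(
                f"double_support_fraction {self.double_support_fraction} inconsistent "
                f"with swing_fraction (implies {ds_implied:.4f})"
            )
        if self.double_support_fraction >= 1.0 - self.swing_fraction:
            raise SimulationError("double support must be shorter than stance")
        if any(r <= 0 for r in self.asym_factors.values()):
            raise SimulationError("asym ratios must be positive")
        breaks = sorted((float(s), float(d)) for s, d in self.rest_breaks)
        for (s, d) in breaks:
            if d <= 0 or s < 0 or s + d > self.trial_duration:
                raise SimulationError("rest break outside trial or non-positive")
        for (s1, d1), (s2, _) in zip(breaks, breaks[1:]):
            if s1 + d1 > s2:
                raise SimulationError("rest breaks overlap")
        self.rest_breaks = breaks

    def side_ratio(self, param: str, side: str) -> float:
        """Multiplier applied to ``param`` on ``side`` (left gets the ratio,
        right gets 1, so left/right equals the configured factor)."""
        r = self.asym_factors.get(param, 1.0)
        return r if side == "left" else 1.0


@dataclass
class NoiseModel:
    """Additive sensor imperfections (thermo-mechanical noise, gyro bias)."""

    accel_noise_sd: float = 0.1  # m/s²
    gyro_noise_sd: float = 0.05  # rad/s
    gyro_bias: float = 0.0  # rad/s, constant per trial, sagittal axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise SimulationError("noise sds must be >= 0")


@dataclass
class SideTruth:
    """Planted per-side events, stride parameters and path."""

    ic: np.ndarray  # initial-contact times, s
    fc: np.ndarray  # final-contact (toe-off) times, s; fc[j] in (ic[j], ic[j+1])
    midswing: np.ndarray  # mid-swing instants, s
    stride_duration: np.ndarray
    stride_length: np.ndarray
    stride_height: np.ndarray
    stride_width: np.ndarray
    path: np.ndarray  # (N, 3) planted ankle displacement, global frame
    theta: np.ndarray  # (N,) shank sagittal tilt, rad
    omega: np.ndarray  # (N,) true sagittal angular velocity, rad/s


@dataclass
class GroundTruth:
    t: np.ndarray
    left: SideTruth
    right: SideTruth
    swing_fraction: float
    double_support_fraction: float
    cadence_spm: float  # strides per minute
    mean_speed: float  # m/s
    distance_per_foot: dict  # side -> sum of planted stride lengths
    change_speed_per_s: float  # planted fractional speed slope / intercept


def _minjerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk unit step and its second derivative wrt tau."""
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    d2 = 60 * tau - 180 * tau**2 + 120 * tau**3
    return s, d2


def _bump(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit bump sin²(πτ) (0 at both ends, 1 at τ=0.5) and second derivative."""
    b = np.sin(np.pi * tau) ** 2
    d2 = 2 * np.pi**2 * np.cos(2 * np.pi * tau)
    return b, d2


def _walking_segments(profile: GaitProfile) -> list[tuple[float, float]]:
    segs, cursor = [], 0.0
    for (s, d) in profile.rest_breaks:
        if s > cursor:
            segs.append((cursor, s))
        cursor = s + d
    if cursor < profile.trial_duration:
        segs.append((cursor, profile.trial_duration))
    return segs


def simulate_trial(
    profile: GaitProfile,
    noise: NoiseModel | None = None,
    mounting_angle_deg: float = 0.0,
) -> tuple[ImuRecording, ImuRecording, GroundTruth]:
    """Simulate one two-ankle 6MWT trial.

    Parameters
    ----------
    mounting_angle_deg : float
        Constant rotation of the sensor about the shank (vertical) axis,
        emulating an arbitrarily rotated strap.

    Returns
    -------
    (left, right, truth)
        Two :class:`~scigait.sensor_io.ImuRecording` on a shared 200 Hz
        time base, plus the planted :class:`GroundTruth`.
    """
    noise = noise or NoiseModel(accel_noise_sd=0.0, gyro_noise_sd=0.0)
    rng = np.random.default_rng(noise.seed)
    fs = NOMINAL_FS
    n = int(round(profile.trial_duration * fs)) + 1
    t = np.arange(n) / fs

    length_cv = (profile.stride_length_cv if profile.stride_length_cv is not None
                 else profile.stride_duration_cv)

    # --- left-right phase offset from the step-duration asymmetry ratio
    r_step = profile.asym_factors.get("step_duration", 1.0)
    phi = r_step / (1.0 + r_step)  # right IC at phi*T after left IC

    # --- common gait clock: stride boundary times shared by both sides
    segments = _walking_segments(profile)
    boundaries_per_seg = []
    sd_dur = np.sqrt(np.log1p(profile.stride_duration_cv**2))
    for (s0, s1) in segments:
        times = [s0 + SETTLE_S]
        while True:
            T = profile.stride_duration_mean * rng.lognormal(-0.5 * sd_dur**2, sd_dur)
            nxt = times[-1] + T
            if nxt + (phi + 0.05) * T > s1 - SETTLE_S:
                break
            times.append(nxt)
        boundaries_per_seg.append(np.asarray(times))
    n_strides_total = sum(max(len(b) - 1, 0) for b in boundaries_per_seg)
    if n_strides_total < 2:
        raise SimulationError("trial too short")

    stance_frac = 1.0 - profile.swing_fraction
    sd_len = np.sqrt(np.log1p(length_cv**2))

    sides = {}
    truth_sides = {}
    for side, lat_sign in (("left", -1.0), ("right", 1.0)):
        pos = np.zeros((n, 3))
        acc = np.zeros((n, 3))
        omega = np.zeros(n)
        ic_all, fc_all, mid_all = [], [], []
        dur_all, len_all, hgt_all, wid_all = [], [], [], []
        x_cum = 0.0
        for bounds in boundaries_per_seg:
            if len(bounds) < 2:
                continue
            if side == "left":
                ics = bounds.copy()
            else:
                # right ICs interleave at phase phi of each left stride
                ics = bounds[:-1] + phi * np.diff(bounds)
                ics = np.append(ics, ics[-1] + (bounds[-1] - bounds[-2]))
            for j in range(len(ics) - 1):
                ic0, ic1 = ics[j], ics[j + 1]
                T = ic1 - ic0
                fc = ic0 + stance_frac * T
                t_sw = ic1 - fc
                mid_t = t[int(np.searchsorted(t, (ic0 + fc) / 2))]
                drift_gain = 1.0 + profile.speed_drift * (mid_t / 60.0)
                L = (profile.stride_length_mean
                     * profile.side_ratio("stride_length", side)
                     * rng.lognormal(-0.5 * sd_len**2, sd_len) * drift_gain)
                H = profile.stride_height_mean * profile.side_ratio("stride_height", side)
                W = profile.stride_width_mean * profile.side_ratio("stride_width", side)

                i0, i1 = np.searchsorted(t, fc), np.searchsorted(t, ic1)
                tau = (t[i0:i1] - fc) / t_sw
                s, s2 = _minjerk(tau)
                b, b2 = _bump(tau)
                pos[i0:i1, 0] = x_cum + L * s
                pos[i0:i1, 1] = lat_sign * W * b
                pos[i0:i1, 2] = H * b
                acc[i0:i1, 0] = L * s2 / t_sw**2
                acc[i0:i1, 1] = lat_sign * W * b2 / t_sw**2
                acc[i0:i1, 2] = H * b2 / t_sw**2
                # stance after landing (up to next FC handled by next loop pass)
                pos[i1:, 0] = x_cum + L
                x_cum += L

                # sagittal angular velocity: forward lobe over swing ...
                lobe_peak = SWING_ROTATION_RAD / (0.5 * t_sw)
                omega[i0:i1] += lobe_peak * b
                # ... cancelled by reversal dips at the two contacts
                dip_amp = SWING_ROTATION_RAD / (
                    2 * CONTACT_DIP_SIGMA_S * np.sqrt(2 * np.pi))
                for t_ev in (fc, ic1):
                    lo = np.searchsorted(t, t_ev - 5 * CONTACT_DIP_SIGMA_S)
                    hi = np.searchsorted(t, t_ev + 5 * CONTACT_DIP_SIGMA_S)
                    omega[lo:hi] -= dip_amp * np.exp(
                        -((t[lo:hi] - t_ev) ** 2) / (2 * CONTACT_DIP_SIGMA_S**2))

                ic_all.append(ic0)
                fc_all.append(fc)
                mid_all.append(fc + t_sw / 2.0)
                dur_all.append(T)
                len_all.append(L)
                hgt_all.append(H)
                wid_all.append(W)
            ic_all.append(ics[-1])

        ic_arr = np.asarray(ic_all)
        fc_arr = np.asarray(fc_all)
        theta = cumulative_trapezoid(omega, t, initial=0.0)
        truth_sides[side] = SideTruth(
            ic=ic_arr, fc=fc_arr,
            midswing=np.asarray(mid_all),
            stride_duration=np.asarray(dur_all),
            stride_length=np.asarray(len_all),
            stride_height=np.asarray(hgt_all),
            stride_width=np.asarray(wid_all),
            path=pos, theta=theta, omega=omega,
        )
        sides[side] = (pos, acc, omega, theta)

    # --- express in the sensor frame and add noise
    recs = {}
    alpha = np.deg2rad(mounting_angle_deg)
    ca, sa = np.cos(alpha), np.sin(alpha)
    for side in ("left", "right"):
        pos, acc, omega, theta = sides[side]
        f_global = acc.copy()
        f_global[:, 2] += GRAVITY  # specific force includes reaction to gravity
        ct, st_ = np.cos(theta), np.sin(theta)
        # R = R_y(theta) @ R_z(alpha); sensor measurement = R^T f_global
        fx = ct * f_global[:, 0] - st_ * f_global[:, 2]
        fy = f_global[:, 1]
        fz = st_ * f_global[:, 0] + ct * f_global[:, 2]
        accel_sensor = np.column_stack([ca * fx + sa * fy, -sa * fx + ca * fy, fz])
        # angular velocity is omega about global y: R_z(alpha)^T (0, w, 0)
        gyro_sensor = np.column_stack(
            [sa * omega, ca * omega, np.zeros_like(omega)])
        gyro_sensor[:, 1] += noise.gyro_bias
        if noise.accel_noise_sd > 0:
            accel_sensor = accel_sensor + rng.normal(0, noise.accel_noise_sd, (n, 3))
        if noise.gyro_noise_sd > 0:
            gyro_sensor = gyro_sensor + rng.normal(0, noise.gyro_noise_sd, (n, 3))
        recs[side] = ImuRecording(
            t=t.copy(), accel=accel_sensor, gyro=gyro_sensor,
            side=side, sensor_id=f"sim-{side}",
        )

    stride_durs = truth_sides["left"].stride_duration
    mean_T = float(np.mean(stride_durs))
    mean_L = float(np.mean(truth_sides["left"].stride_length))
    truth = GroundTruth(
        t=t,
        left=truth_sides["left"], right=truth_sides["right"],
        swing_fraction=profile.swing_fraction,
        double_support_fraction=profile.double_support_fraction,
        cadence_spm=60.0 / mean_T,
        mean_speed=mean_L / mean_T,
        distance_per_foot={s: float(truth_sides[s].stride_length.sum())
                           for s in ("left", "right")},
        change_speed_per_s=profile.speed_drift / 60.0,
    )
    return recs["left"], recs["right"], truth


# ---------------------------------------------------------------------------
# cohort-level generators
# ---------------------------------------------------------------------------

def simulate_cohort_features(
    cluster_specs: list[tuple[np.ndarray, np.ndarray, int]],
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a cluster-structured feature table.

    Each spec is ``(mean_vector, sd_vector, n)``; rows are independent
    draws from the per-cluster diagonal-covariance normal.

    Returns
    -------
    (features, labels)
        DataFrame of shape (sum n, d) and the true integer labels.
    """
    if len(cluster_specs) < 2:
        raise SimulationError("need at least 2 clusters")
    dims = {len(np.atleast_1d(m)) for m, s, n in cluster_specs}
    if len(dims) != 1 or {len(np.atleast_1d(s)) for m, s, n in cluster_specs} != dims:
        raise SimulationError("cluster specs disagree on feature dimensionality")
    d = dims.pop()
    if any(n < 2 for _, _, n in cluster_specs):
        raise SimulationError("each cluster needs n >= 2")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, (mean, sd, n) in enumerate(cluster_specs):
        mean = np.broadcast_to(np.atleast_1d(mean).astype(float), (d,))
        sd = np.broadcast_to(np.atleast_1d(sd).astype(float), (d,))
        rows.append(rng.normal(mean, sd, size=(n, d)))
        labels.extend([k] * n)
    names = feature_names or [f"gait_{i}" for i in range(d)]
    return pd.DataFrame(np.vstack(rows), columns=names), np.asarray(labels)


#: repeat structure of the longitudinal subset: 10 subjects measured twice,
#: 9 three times, 4 four times -> 40 consecutive-pair observations
DEFAULT_REPEATS = (2,) * 10 + (3,) * 9 + (4,) * 4


def simulate_longitudinal_cohort(
    n_subjects: int | None = None,
    trials_per_subject: tuple[int, ...] = DEFAULT_REPEATS,
    improvement_effect: float = 0.0,
    seed: int = 0,
    n_gait_features: int = 10,
    delta_mean: float = 16.5,
    delta_noise_sd: float = 30.0,
) -> pd.DataFrame:
    """Simulate repeated 6MWT assessments during rehabilitation.

    Each subject receives days-since-injury per trial, a per-trial gait
    feature vector (standard normal), and 6MWT distances whose change
    from one trial to the next is

        Δdistance = delta_mean + improvement_effect * (mean of the first
        three gait features) + N(0, delta_noise_sd)   [metres]

    ``improvement_effect = 0`` yields chance-level labels balanced around
    the 16.5 m standard error of measurement; a large effect makes the
    future improvement a function of the present gait pattern only.

    Returns a tidy DataFrame with columns ``subject_id``, ``day``,
    ``distance`` and ``gait_*``.
    """
    if n_subjects is not None:
        trials_per_subject = tuple(trials_per_subject)[:n_subjects]
    if not any(k >= 2 for k in trials_per_subject):
        raise SimulationError("at least one subject needs >= 2 trials")
    rng = np.random.default_rng(seed)
    w = np.zeros(n_gait_features)
    w[: min(3, n_gait_features)] = 1.0 / min(3, n_gait_features)
    rows = []
    for i, k in enumerate(trials_per_subject):
        day = float(rng.integers(20, 700))
        dist = float(rng.uniform(50, 500))
        for j in range(k):
            x = rng.standard_normal(n_gait_features)
            rows.append({"subject_id": f"S{i:03d}", "day": day, "distance": dist,
                         **{f"gait_{m}": x[m] for m in range(n_gait_features)}})
            delta = (delta_mean + improvement_effect * float(w @ x)
                     + rng.normal(0.0, delta_noise_sd))
            dist = max(dist + delta, 0.0)
            day += float(rng.integers(21, 90))
    return pd.DataFrame(rows)
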