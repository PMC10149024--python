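"""Cadence estimation, stride/gait-event detection, temporal parameters.

Detection operates on the sagittal-plane angular velocity ω_z of the
shank.  Its structure during level walking is stereotyped: a large
positive lobe as the shank swings forward, bounded by sharp negative
reversals at the foot contacts.  Cadence is read off the frequency
spectrum first and then drives adaptive peak-search windows and height
thresholds, which keeps detection robust from very slow (~0.3 Hz) to
brisk (~1.5 Hz) stride rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .sensor_io import ImuRecording, sagittal_rate, GRAVITY

log = logging.getLogger(__name__)

# adaptive-threshold constants
STRIDE_BAND_HZ = (0.3, 1.5)  # physiological stride-frequency band
PEAK_HEIGHT_FRACTION = 0.2  # of the 95th percentile of |ω_z|
PEAK_HEIGHT_FLOOR = 0.5  # rad/s
PEAK_DISTANCE_FRACTION = 0.6  # of the stride period
EVENT_WINDOW_FRACTION = 0.35  # of the stride period, for IC/FC search
ACCEL_CORROBORATION_S = 0.05  # IC accel-peak tolerance
REST_WINDOW_S = 2.0  # moving-variance window for rest segmentation
REST_VAR_THRESHOLD = 0.01  # (rad/s)²
MIN_CADENCE_SIGNAL_S = 10.0


class EventDetectionError(ValueError):
    pass


@dataclass
class GaitEvents:
    """Detected gait events for one side, in seconds on the trial time base."""

    side: str
    initial_contacts: np.ndarray
    final_contacts: np.ndarray
    midswing_peaks: np.ndarray
    cadence_spm: float  # strides per minute

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.side, ev, t)
                for ev, ts in (("initial_contact", self.initial_contacts),
                               ("final_contact", self.final_contacts),
                               ("midswing", self.midswing_peaks))
                for t in ts]
        return pd.DataFrame(rows, columns=["side", "event", "time_s"]).sort_values(
            "time_s", ignore_index=True)


@dataclass
class TemporalParams:
    """Per-stride temporal parameters of the analysis side."""

    side: str
    stride_start: np.ndarray  # IC time of each retained stride, s
    stride_duration: np.ndarray  # s
    step_duration: np.ndarray  # s, this side's IC -> contralateral IC
    swing_pct: np.ndarray  # % of stride
    double_support_pct: np.ndarray  # % of stride
    cadence_series: np.ndarray = field(default=None)  # strides/min per stride

    def __post_init__(self) -> None:
        if self.cadence_series is None:
            self.cadence_series = 60.0 / self.stride_duration


# ---------------------------------------------------------------------------
# rest segmentation
# ---------------------------------------------------------------------------

def rest_mask(omega_z: np.ndarray, fs: float,
              window_s: float = REST_WINDOW_S,
              var_threshold: float = REST_VAR_THRESHOLD) -> np.ndarray:
    """True where the shank is at rest (moving variance of ω_z below
    ``var_threshold`` over a ``window_s`` centred window)."""
    w = max(int(round(window_s * fs)), 2)
    x = pd.Series(omega_z)
    var = x.rolling(w, center=True, min_periods=1).var(ddof=0).to_numpy()
    return var < var_threshold


def _orient_sign(omega_z: np.ndarray, fs: float, stride_freq: float) -> float:
    """Resolve the ω_z sign convention (positive during swing).

    Straps can be mounted rotated 180°.  The forward swing is a broad
    lobe while the contact reversals are sharp impulses of the opposite
    sign, so after low-pass filtering at ~2.5× the stride frequency the
    lobe dominates and the sign of the dominant extremum gives the
    polarity (robust percentiles stand in for the raw extrema).
    """
    nyq = fs / 2.0
    b, a = butter(2, min(2.5 * stride_freq, 0.9 * nyq) / nyq)
    xf = filtfilt(b, a, omega_z)
    hi, lo = np.percentile(xf, [99.5, 0.5])
    return 1.0 if abs(hi) >= abs(lo) else -1.0


# ---------------------------------------------------------------------------
# cadence
# ---------------------------------------------------------------------------

def estimate_cadence(omega_z: np.ndarray, fs: float) -> tuple[float, float]:
    """Stride frequency (Hz) and cadence (strides/min) from the FFT of ω_z,
    restricted to the physiological band 0.3–1.5 Hz.

    The stride rate is the *first main* component of the spectrum: the
    lowest-frequency prominent peak in the band.  For slow walkers the
    sharp contact reversals put more energy into the second harmonic
    than the fundamental, so the global maximum would double the
    cadence.  Rest periods are excised before the transform so that long
    breaks do not dilute the locomotion peak.
    """
    omega_z = np.asarray(omega_z, dtype=float)
    active = ~rest_mask(omega_z, fs)
    x = omega_z[active]
    if len(x) < MIN_CADENCE_SIGNAL_S * fs or not np.any(x):
        raise EventDetectionError("no locomotion detected")
    x = (x - np.mean(x)) * np.hanning(len(x))
    nfft = int(2 ** np.ceil(np.log2(len(x) * 4)))  # pad for bin resolution
    mag = np.abs(np.fft.rfft(x, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    band = (freqs >= STRIDE_BAND_HZ[0]) & (freqs <= STRIDE_BAND_HZ[1])
    if not np.any(band) or not np.any(mag[band] > 0):
        raise EventDetectionError("no locomotion detected")
    mb, fb = mag[band], freqs[band]
    peaks, _ = find_peaks(mb, height=0.35 * mb.max(), prominence=0.1 * mb.max())
    f = float(fb[peaks[0]]) if len(peaks) else float(fb[np.argmax(mb)])
    return f, 60.0 * f


# ---------------------------------------------------------------------------
# stride and event detection
# ---------------------------------------------------------------------------

def detect_strides(recording: ImuRecording, stride_freq: float | None = None
                   ) -> np.ndarray:
    """Mid-swing peak times of one recording.

    Peaks are local maxima of ω_z with a minimum separation of 60% of
    the stride period and a minimum height adapted to the amplitude
    distribution of ω_z (20% of the 95th percentile of |ω_z|, floored at
    0.5 rad/s).  Rest periods yield no peaks.  Equal-height plateau
    candidates resolve to the earliest sample.
    """
    fs = recording.fs
    omega_z = sagittal_rate(recording)
    if stride_freq is None:
        stride_freq, _ = estimate_cadence(omega_z, fs)
    if not np.any(omega_z):
        return np.array([])
    sgn = _orient_sign(omega_z, fs, stride_freq)
    x = sgn * omega_z
    height = max(PEAK_HEIGHT_FRACTION * np.percentile(np.abs(x), 95),
                 PEAK_HEIGHT_FLOOR)
    dist = max(int(PEAK_DISTANCE_FRACTION / stride_freq * fs), 1)
    peaks, _ = find_peaks(x, height=height, distance=dist)
    resting = rest_mask(omega_z, fs)
    peaks = peaks[~resting[peaks]]
    return recording.t[peaks]


def detect_gait_events(recording: ImuRecording, midswing_peaks: np.ndarray,
                       stride_freq: float | None = None) -> GaitEvents:
    """Initial and final foot contacts around each detected mid-swing peak.

    Within a search window scaled by the stride period, the initial
    contact is the first prominent ω_z minimum after mid-swing
    (corroborated, when present, by a peak of the gravity-compensated
    accelerometer magnitude within ±50 ms); the final contact is the
    ω_z minimum preceding the next mid-swing.
    """
    midswing_peaks = np.asarray(midswing_peaks, dtype=float)
    if len(midswing_peaks) < 2:
        raise EventDetectionError("need at least two mid-swing peaks")
    fs = recording.fs
    t = recording.t
    omega_z = sagittal_rate(recording)
    if stride_freq is None:
        stride_freq, _ = estimate_cadence(omega_z, fs)
    sgn = _orient_sign(omega_z, fs, stride_freq)
    x = sgn * omega_z
    win = EVENT_WINDOW_FRACTION / stride_freq
    accel_dev = np.abs(np.linalg.norm(recording.accel, axis=1) - GRAVITY)
    # an IC impact should stand out against the trial-wide accel activity
    accel_floor = 0.1 * np.percentile(accel_dev, 95)

    ics, fcs = [], []
    uncorroborated = 0
    dropped = 0
    for k, m in enumerate(midswing_peaks):
        # initial contact: minimum of ω_z shortly after this mid-swing
        lo, hi = np.searchsorted(t, (m, m + win))
        if hi - lo < 2:
            dropped += 1
            continue
        i_min = lo + int(np.argmin(x[lo:hi]))
        t_ic = t[i_min]
        # corroborate (existence check only; the gyro minimum keeps the time)
        alo, ahi = np.searchsorted(t, (t_ic - ACCEL_CORROBORATION_S,
                                       t_ic + ACCEL_CORROBORATION_S))
        if ahi <= alo or np.max(accel_dev[alo:ahi]) < accel_floor:
            uncorroborated += 1
        ics.append(t_ic)
        # final contact: ω_z minimum just before each mid-swing (the first
        # mid-swing too, whose toe-off precedes any detected stride)
        lo2, hi2 = np.searchsorted(t, (m - win, m))
        if hi2 - lo2 < 2:
            dropped += 1
            continue
        fcs.append(t[lo2 + int(np.argmin(x[lo2:hi2]))])
    if uncorroborated:
        log.info("%d initial contacts lacked an accel-magnitude peak", uncorroborated)
    if dropped:
        log.warning("dropped %d stride intervals without event candidates", dropped)
    return GaitEvents(
        side=recording.side,
        initial_contacts=np.asarray(ics),
        final_contacts=np.asarray(fcs),
        midswing_peaks=midswing_peaks,
        cadence_spm=60.0 * stride_freq,
    )


# ---------------------------------------------------------------------------
# temporal parameters
# ---------------------------------------------------------------------------

def _grounded_intervals(ev: GaitEvents) -> list[tuple[float, float]]:
    """Stance intervals (IC -> following FC) for one side."""
    out = []
    for ic in ev.initial_contacts:
        later_fc = ev.final_contacts[ev.final_contacts > ic]
        nxt_ic = ev.initial_contacts[ev.initial_contacts > ic]
        if len(later_fc) == 0:
            continue
        fc = later_fc[0]
        if len(nxt_ic) and fc > nxt_ic[0]:
            continue  # unmatched: no FC inside this stride
        out.append((float(ic), float(fc)))
    return out


def compute_temporal_params(
    events_side: GaitEvents, events_contra: GaitEvents,
    max_stride_duration: float | None = None,
) -> TemporalParams:
    """Temporal gait parameters of ``events_side``.

    Per stride (consecutive same-side initial contacts): duration, the
    step duration to the contralateral initial contact, swing percentage
    ((IC − preceding FC)/stride) and total double-support percentage
    (time both feet grounded within the stride).  Strides spanning rest
    breaks are excluded via ``max_stride_duration`` (default 2.5× the
    cadence period).
    """
    ic = np.asarray(events_side.initial_contacts)
    if len(ic) < 2:
        raise EventDetectionError("need at least two initial contacts")
    if max_stride_duration is None:
        max_stride_duration = 2.5 * 60.0 / events_side.cadence_spm
    contra_ic = np.asarray(events_contra.initial_contacts)
    grounded_self = _grounded_intervals(events_side)
    grounded_contra = _grounded_intervals(events_contra)

    starts, durs, steps, swings, ds = [], [], [], [], []
    dropped = 0
    for ic0, ic1 in zip(ic[:-1], ic[1:]):
        T = ic1 - ic0
        if T > max_stride_duration:
            continue  # spans a rest break
        fc_in = [fc for (s, fc) in grounded_self if ic0 < fc <= ic1 and s <= ic0 + 1e-9]
        c_in = contra_ic[(contra_ic > ic0) & (contra_ic < ic1)]
        if len(fc_in) != 1 or len(c_in) != 1:
            dropped += 1
            continue
        fc = fc_in[0]
        # both-feet-grounded time inside [ic0, ic1]
        self_stance = [(ic0, fc), (ic1, ic1 + 1e-9)]
        both = 0.0
        for (a, b) in grounded_contra:
            for (c, d) in self_stance[:1]:
                both += max(0.0, min(b, d) - max(a, c))
        starts.append(ic0)
        durs.append(T)
        steps.append(float(c_in[0] - ic0))
        swings.append((ic1 - fc) / T * 100.0)
        ds.append(both / T * 100.0)
    if dropped:
        log.warning("dropped %d strides with unmatched event sequences", dropped)
    if not durs:
        raise EventDetectionError("no complete strides")
    return TemporalParams(
        side=events_side.side,
        stride_start=np.asarray(starts),
        stride_duration=np.asarray(durs),
        step_duration=np.asarray(steps),
        swing_pct=np.asarray(swings),
        double_support_pct=np.asarray(ds),
    )
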