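"""Per-trial gait parameter vector: statistics, cyclograms, smoothness, fatigue.

For each base parameter X (stride duration, step duration, swing phase,
double support phase, stride length, stride width, stride height) the
trial is summarised by

* the mean X̄ in native units,
* cov  = σ / X̄ · 100 %                     (stride-to-stride variability),
* asym = |X̄_L − X̄_R| / (½(X̄_L + X̄_R)) · 100 %   (left-right symmetry index;
  not defined for stride length, whose left/right means coincide by
  construction of the stride),
* d2r  = (X̄ − X̄_ref(v)) / X̄_ref(v) · 100 %  (signed deviation from healthy
  controls interpolated to the same walking speed v).

Cyclograms are the closed 2D curves traced by the ankle over one stride
(side view: forward-vertical; top view: forward-lateral).  After time
normalisation, centering and scaling to unit RMS radius their shape is
compared to a healthy reference (SSD), their cycle-to-cycle consistency
is quantified by the angular component of the coefficient of
correspondence (ACC), and their enclosed area is reported both for the
normalised and the raw-scale shape.

Fatigue-related metrics are the fractional change of speed, stride
length and cadence over the six minutes (slope/intercept of a linear
fit), the speed inconsistency (|change in speed|), and movement
smoothness as the modified spectral arc length of ω_z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CYCLOGRAM_POINTS = 100
SPARC_MAX_CUTOFF_HZ = 20.0
SPARC_AMP_THRESHOLD = 0.05
SPARC_PAD_LEVEL = 4

BASE_PARAMS = ["stride_duration", "step_duration", "swing_pct",
               "double_support_pct", "stride_length", "stride_width",
               "stride_height"]
NO_ASYM = {"stride_length"}  # per-side stride lengths share the same mean


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# statistical features
# ---------------------------------------------------------------------------

def compute_cov(values) -> float:
    """Coefficient of variation: sample sd (ddof=1) over mean, in percent."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise FeatureError("cov needs at least two values")
    m = x.mean()
    if m == 0:
        raise FeatureError("cov undefined for zero mean")
    return float(np.std(x, ddof=1) / m * 100.0)


def compute_asym(mean_left: float, mean_right: float) -> float:
    """Symmetry index between the side means, in percent of their mid-mean."""
    denom = 0.5 * (mean_left + mean_right)
    if denom == 0:
        raise FeatureError("asym undefined when both means are zero")
    return float(abs(mean_left - mean_right) / denom * 100.0)


def compute_d2r(mean_value: float, speed: float, reference: "HealthyReference",
                param: str) -> float:
    """Signed percent deviation from the speed-matched healthy reference."""
    ref = reference.query(param, speed)
    if ref == 0:
        raise FeatureError(f"reference value for {param} is zero")
    return float((mean_value - ref) / ref * 100.0)


# ---------------------------------------------------------------------------
# healthy reference
# ---------------------------------------------------------------------------

@dataclass
class HealthyReference:
    """Speed-indexed control values per parameter and reference cyclogram
    shapes per view, built from healthy-control trials."""

    speeds: np.ndarray  # sorted control speeds
    tables: dict  # param -> values aligned with speeds
    cyclogram_shapes: dict = field(default_factory=dict)  # view -> (100, 2)

    def query(self, param: str, speed: float) -> float:
        """Piecewise-linear interpolation, clamped to the control range."""
        if param not in self.tables:
            raise FeatureError(f"no reference for parameter {param!r}")
        return float(np.interp(speed, self.speeds, self.tables[param]))

    def is_extrapolated(self, speed: float) -> bool:
        return bool(speed < self.speeds[0] or speed > self.speeds[-1])


def build_reference(control_params: list[dict], control_speeds,
                    control_shapes: dict | None = None,
                    min_span: float = 0.3) -> HealthyReference:
    """Build the healthy reference from ≥3 control trials.

    ``control_params`` holds one ``{param: mean value}`` dict per trial;
    ties in speed are averaged before interpolation.  ``control_shapes``
    optionally maps view -> list of normalised cyclogram mean shapes,
    averaged pointwise into the reference shape.
    """
    speeds = np.asarray(control_speeds, dtype=float)
    if len(speeds) < 3 or np.ptp(speeds) < min_span:
        raise FeatureError(
            f"need >= 3 control trials spanning >= {min_span} m/s of speed")
    params = sorted({k for d in control_params for k in d})
    df = pd.DataFrame(control_params).assign(speed=speeds)
    agg = df.groupby("speed", sort=True).mean()
    shapes = {}
    for view, shp in (control_shapes or {}).items():
        shapes[view] = np.mean(np.stack(shp), axis=0)
    return HealthyReference(
        speeds=agg.index.to_numpy(),
        tables={p: agg[p].to_numpy() for p in params},
        cyclogram_shapes=shapes,
    )


# ---------------------------------------------------------------------------
# cyclograms
# ---------------------------------------------------------------------------

def _project(disp: np.ndarray, view: str) -> np.ndarray:
    if view == "side":
        return disp[:, [0, 2]]  # forward-vertical
    if view == "top":
        return disp[:, [0, 1]]  # forward-lateral
    raise ValueError(f"view must be 'side' or 'top', got {view!r}")


def normalize_shape(points: np.ndarray) -> np.ndarray | None:
    """Center at the centroid and scale to unit RMS radius.

    Returns ``None`` for degenerate (all-zero) shapes.
    """
    p = points - points.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum(p**2, axis=1)))
    if rms < 1e-12:
        return None
    return p / rms


def compute_cyclogram(strides, view: str, n_points: int = CYCLOGRAM_POINTS
                      ) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
    """Per-stride cyclogram shapes for one view.

    Each stride's 2D projection is resampled to ``n_points`` uniformly in
    normalised stride time (phase-anchored at the stride start), centred
    and scaled to unit RMS radius.

    Returns
    -------
    (shapes, mean_shape, raw_shapes)
        Normalised per-stride shapes, their pointwise mean, and the
        resampled raw-scale (metres) shapes for area computation.
    """
    if len(strides) < 5:
        raise FeatureError("need at least 5 strides for cyclograms")
    shapes, raw_shapes = [], []
    for s in strides:
        xy = _project(s.disp, view)
        tau = (s.t - s.t[0]) / (s.t[-1] - s.t[0])
        grid = np.linspace(0.0, 1.0, n_points)
        res = np.column_stack([np.interp(grid, tau, xy[:, i]) for i in range(2)])
        norm = normalize_shape(res)
        if norm is None:
            continue  # degenerate shape excluded
        shapes.append(norm)
        raw_shapes.append(res)
    if not shapes:
        raise FeatureError("all cyclogram shapes degenerate")
    return shapes, np.mean(np.stack(shapes), axis=0), raw_shapes


def cyclogram_ssd(mean_shape: np.ndarray, reference_shape: np.ndarray) -> float:
    """Sum of squared pointwise differences between two normalised shapes;
    0 means the participant's cyclogram matches the reference exactly."""
    if mean_shape.shape != reference_shape.shape:
        raise FeatureError(
            f"shape mismatch {mean_shape.shape} vs {reference_shape.shape}")
    return float(np.sum((mean_shape - reference_shape) ** 2))


#: segments shorter than this fraction of a cycle's mean segment length
#: are treated as zero-length: below it the direction angle is dominated
#: by integration residue rather than movement (the ankle barely moves
#: during stance, ~60 % of normalised stride time)
ACC_ZERO_SEGMENT_FRACTION = 0.05


def cyclogram_acc(shapes: list[np.ndarray],
                  zero_fraction: float = ACC_ZERO_SEGMENT_FRACTION) -> float:
    """Angular component of the coefficient of correspondence, percent.

    For each of the normalised-time segments the direction angle of the
    segment vector is computed per cycle; the circular mean resultant
    length across cycles is averaged over segments.  100 % means every
    cycle repeats the same direction sequence; uncorrelated directions
    tend to 0 %.  (Near-)zero-length segments carry no direction and are
    excluded from their cycle's contribution.
    """
    if len(shapes) < 5:
        raise FeatureError("need at least 5 cycles for ACC")
    seg = np.stack([np.diff(s, axis=0) for s in shapes])  # (cycles, n-1, 2)
    lengths = np.linalg.norm(seg, axis=2)
    angles = np.arctan2(seg[:, :, 1], seg[:, :, 0])
    floor = zero_fraction * lengths.mean(axis=1, keepdims=True)
    valid = lengths > np.maximum(floor, 1e-12)
    cosm = np.where(valid, np.cos(angles), 0.0).sum(axis=0)
    sinm = np.where(valid, np.sin(angles), 0.0).sum(axis=0)
    counts = valid.sum(axis=0)
    ok = counts > 0
    r = np.sqrt(cosm[ok] ** 2 + sinm[ok] ** 2) / counts[ok]
    return float(np.mean(r) * 100.0)


def cyclogram_area(shape: np.ndarray) -> float:
    """|signed shoelace area| of the closed shape (first/last joined).

    Self-intersecting shapes are allowed; the absolute value of the
    signed polygon area is the reported convention.
    """
    x, y = shape[:, 0], shape[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


# ---------------------------------------------------------------------------
# smoothness (modified spectral arc length)
# ---------------------------------------------------------------------------

def compute_smoothness(omega_z: np.ndarray, fs: float,
                       max_cutoff_hz: float = SPARC_MAX_CUTOFF_HZ,
                       amp_threshold: float = SPARC_AMP_THRESHOLD,
                       pad_level: int = SPARC_PAD_LEVEL) -> float:
    """Modified spectral arc length of ω_z over the walking segments.

    The magnitude spectrum is normalised by its maximum; the adaptive
    cutoff is the largest frequency below ``max_cutoff_hz`` where the
    normalised magnitude still exceeds ``amp_threshold``; the negated
    arc length of the normalised spectrum over [0, cutoff] is returned.
    Always ≤ 0; values closer to 0 mean smoother movement.
    """
    x = np.asarray(omega_z, dtype=float)
    if len(x) < 10 * fs:
        raise FeatureError("need at least 10 s of walking signal")
    nfft = int(2 ** (np.ceil(np.log2(len(x))) + pad_level))
    freqs = np.arange(nfft // 2 + 1) * (fs / nfft)
    mag = np.abs(np.fft.rfft(x, nfft))
    sel = freqs <= max_cutoff_hz
    freqs, mag = freqs[sel], mag[sel]
    mag = mag / np.max(mag)
    above = np.nonzero(mag >= amp_threshold)[0]
    i_cut = above[-1] + 1 if len(above) else len(mag)
    f, m = freqs[:i_cut], mag[:i_cut]
    f_range = f[-1] - f[0]
    if f_range <= 0:
        raise FeatureError("degenerate spectrum")
    arc = np.sum(np.sqrt((np.diff(f) / f_range) ** 2 + np.diff(m) ** 2))
    return float(-arc)


# ---------------------------------------------------------------------------
# fatigue / change metrics
# ---------------------------------------------------------------------------

@dataclass
class FatigueMetrics:
    change_speed: float  # fractional change per second (slope/intercept)
    change_stride_length: float
    change_cadence: float
    speed_inconsistency: float  # |change_speed|


def _relative_slope(times: np.ndarray, values: np.ndarray) -> float:
    slope, intercept = np.polyfit(times, values, 1)
    if intercept == 0:
        raise FeatureError("zero intercept in change-metric fit")
    return float(slope / intercept)


def compute_change_metrics(stride_times, speeds, stride_lengths, cadences,
                           min_span_s: float = 120.0) -> FatigueMetrics:
    """Slope/intercept of the linear fit of each parameter over trial time.

    The ratio is a unit-free fractional change per second, so a trial
    losing 10 % of its initial speed over six minutes scores
    change_speed ≈ −2.8e−4 s⁻¹ regardless of the absolute speed.
    """
    t = np.asarray(stride_times, dtype=float)
    if len(t) < 10 or np.ptp(t) < min_span_s:
        raise FeatureError("need >= 10 strides spanning >= 120 s")
    ch_speed = _relative_slope(t, np.asarray(speeds, float))
    return FatigueMetrics(
        change_speed=ch_speed,
        change_stride_length=_relative_slope(t, np.asarray(stride_lengths, float)),
        change_cadence=_relative_slope(t, np.asarray(cadences, float)),
        speed_inconsistency=abs(ch_speed),
    )


# ---------------------------------------------------------------------------
# feature vector assembly
# ---------------------------------------------------------------------------

def analysis_side(cohort: str, lems_left: float | None,
                  lems_right: float | None, forced: str | None = None) -> str:
    """More-impaired-side rule: the side with the lower LEMS; the right
    side for healthy controls and for LEMS ties."""
    if forced in ("left", "right"):
        return forced
    if cohort == "HC":
        return "right"
    if lems_left is None or lems_right is None:
        raise FeatureError("missing LEMS for SCI trial (force a side to override)")
    return "left" if lems_left < lems_right else "right"


def feature_names() -> list[str]:
    """The fixed, documented feature ordering of the per-trial vector."""
    names = []
    for p in BASE_PARAMS:
        names.append(f"{p}_mean")
        names.append(f"{p}_cov")
        if p not in NO_ASYM:
            names.append(f"{p}_asym")
        names.append(f"{p}_d2r")
    for view in ("side", "top"):
        names += [f"cyclogram_{view}_acc", f"cyclogram_{view}_ssd",
                  f"cyclogram_{view}_area", f"cyclogram_{view}_area_raw"]
    names += ["smoothness", "change_speed", "change_stride_length",
              "change_cadence", "speed_inconsistency", "mean_speed"]
    return names


@dataclass
class GaitParameterSet:
    """The per-trial feature vector with a flat named view for statistics."""

    values: dict

    def to_series(self) -> pd.Series:
        return pd.Series({k: self.values.get(k, np.nan) for k in feature_names()})


def assemble_feature_vector(
    side_params: dict, metadata, reference: HealthyReference | None = None,
    forced_side: str | None = None,
) -> GaitParameterSet:
    """Assemble the per-trial vector from both sides' computed parameters.

    ``side_params`` maps ``"left"``/``"right"`` to dicts holding per-side
    arrays (``stride_duration``, ``step_duration``, ``swing_pct``,
    ``double_support_pct``, ``stride_length``, ``stride_width``,
    ``stride_height``), per-side cyclogram metrics, smoothness, fatigue
    metrics and the mean stride speed.  Side-specific entries are taken
    from the more impaired side; asym uses both sides by definition.
    """
    side = analysis_side(metadata.cohort, metadata.lems_left,
                         metadata.lems_right, forced_side)
    mine, other = side_params[side], side_params["left" if side == "right" else "right"]
    speed = float(mine["mean_speed"])
    out = {"mean_speed": speed}
    for p in BASE_PARAMS:
        x = np.asarray(mine[p], dtype=float)
        out[f"{p}_mean"] = float(np.mean(x))
        out[f"{p}_cov"] = compute_cov(x)
        if p not in NO_ASYM:
            out[f"{p}_asym"] = compute_asym(float(np.mean(mine[p])),
                                            float(np.mean(other[p])))
        if reference is not None:
            out[f"{p}_d2r"] = compute_d2r(out[f"{p}_mean"], speed, reference, p)
    for key in ("cyclogram_side_acc", "cyclogram_side_ssd", "cyclogram_side_area",
                "cyclogram_side_area_raw", "cyclogram_top_acc", "cyclogram_top_ssd",
                "cyclogram_top_area", "cyclogram_top_area_raw", "smoothness",
                "change_speed", "change_stride_length", "change_cadence",
                "speed_inconsistency"):
        if key in mine:
            out[key] = float(mine[key])
    return GaitParameterSet(values=out)
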