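"""End-to-end trial processing: raw two-ankle recordings to the per-trial
gait parameter vector.

Order of operations: synchronize the pair, estimate cadence from the
ω_z spectrum, detect mid-swing peaks and foot contacts, derive temporal
parameters, estimate orientation, reconstruct per-stride trajectories
between mid-stance zero-velocity anchors, then summarise everything
into the flat feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import events as ev
from . import features as ft
from . import trajectory as tj
from .sensor_io import ImuRecording, TrialMetadata, sagittal_rate, synchronize_pair

log = logging.getLogger(__name__)


@dataclass
class SideResult:
    """Intermediate per-side products, kept for inspection and testing."""

    events: ev.GaitEvents
    temporal: ev.TemporalParams
    strides: list = field(default_factory=list)  # walking StrideTrajectory
    params: dict = field(default_factory=dict)  # inputs for feature assembly


def process_side(rec: ImuRecording, contra_events: ev.GaitEvents | None,
                 own_events: ev.GaitEvents) -> SideResult:
    temporal = None
    if contra_events is not None:
        temporal = ev.compute_temporal_params(own_events, contra_events)
    orientation = tj.estimate_orientation(rec)
    anchors = tj.midstance_instants(rec, own_events)
    strides = [s for s in tj.reconstruct_strides(rec, orientation, anchors)
               if not s.is_turn]
    return SideResult(events=own_events, temporal=temporal, strides=strides)


def process_trial(left: ImuRecording, right: ImuRecording,
                  metadata: TrialMetadata | None = None,
                  reference: ft.HealthyReference | None = None,
                  forced_side: str | None = None):
    """Process one trial.

    Returns
    -------
    (feature_set, side_params, sides)
        ``feature_set`` is the assembled :class:`GaitParameterSet` (or
        ``None`` when no metadata is given), ``side_params`` the raw
        per-side parameter dicts, ``sides`` the intermediate products.
    """
    left, right = synchronize_pair(left, right)
    evts = {}
    for rec in (left, right):
        omega_z = sagittal_rate(rec)
        f, _ = ev.estimate_cadence(omega_z, rec.fs)
        peaks = ev.detect_strides(rec, f)
        evts[rec.side] = ev.detect_gait_events(rec, peaks, f)
    sides = {
        "left": process_side(left, evts["right"], evts["left"]),
        "right": process_side(right, evts["left"], evts["right"]),
    }

    side_params = {}
    for side, rec in (("left", left), ("right", right)):
        sr = sides[side]
        tp = sr.temporal
        strides = sr.strides
        params = {
            "stride_duration": tp.stride_duration,
            "step_duration": tp.step_duration,
            "swing_pct": tp.swing_pct,
            "double_support_pct": tp.double_support_pct,
            "stride_length": np.array([s.stride_length for s in strides]),
            "stride_width": np.array([s.stride_width for s in strides]),
            "stride_height": np.array([s.stride_height for s in strides]),
        }
        if strides:
            speeds, mean_speed, distance = tj.compute_walking_speed(strides)
            params["mean_speed"] = mean_speed
            params["distance"] = distance
            mid_times = np.array([0.5 * (s.t[0] + s.t[-1]) for s in strides])
            lengths = params["stride_length"]
            cadences = 60.0 / np.array([s.stride_duration for s in strides])
            try:
                fat = ft.compute_change_metrics(mid_times, speeds, lengths, cadences)
                params.update(change_speed=fat.change_speed,
                              change_stride_length=fat.change_stride_length,
                              change_cadence=fat.change_cadence,
                              speed_inconsistency=fat.speed_inconsistency)
            except ft.FeatureError as e:
                log.warning("%s side change metrics unavailable: %s", side, e)
        omega_z = sagittal_rate(rec)
        active = ~ev.rest_mask(omega_z, rec.fs)
        try:
            params["smoothness"] = ft.compute_smoothness(omega_z[active], rec.fs)
        except ft.FeatureError as e:
            log.warning("%s side smoothness unavailable: %s", side, e)
        try:
            for view in ("side", "top"):
                shapes, mean_shape, raw = ft.compute_cyclogram(strides, view)
                params[f"cyclogram_{view}_acc"] = ft.cyclogram_acc(shapes)
                params[f"cyclogram_{view}_area"] = ft.cyclogram_area(mean_shape)
                params[f"cyclogram_{view}_area_raw"] = float(np.mean(
                    [ft.cyclogram_area(r) for r in raw]))
                params[f"cyclogram_{view}_mean_shape"] = mean_shape
                if reference is not None and view in reference.cyclogram_shapes:
                    params[f"cyclogram_{view}_ssd"] = ft.cyclogram_ssd(
                        mean_shape, reference.cyclogram_shapes[view])
        except ft.FeatureError as e:
            log.warning("%s side cyclograms unavailable: %s", side, e)
        side_params[side] = params

    feature_set = None
    if metadata is not None:
        feature_set = ft.assemble_feature_vector(
            side_params, metadata, reference=reference, forced_side=forced_side)
    return feature_set, side_params, sides
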