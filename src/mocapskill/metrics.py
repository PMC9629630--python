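"""Per-trial motion-capture metric suite.

Efficiency metrics (operative time OT, path length PL, depth path length
DPL, working area WA), speed metrics (mean velocity/acceleration/jerk and
depth velocity DV), bimanual metrics (BD, ROB, RPLB, ADBO, ADB) and
attitude metrics (AGRA, mean roll/pitch/yaw, angular lengths AL-Roll and
AL-PitchYaw).

Exact formulas for the published metric names are not available; each
definition here is a reconstruction from the metric's name and the stated
hypotheses (e.g. WA as the convex-hull area of the tip's projection
perpendicular to the depth axis, contrasting with the depth metrics
DPL/DV), and is documented as such in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .io import (
    INSTRUMENT_PREFIX,
    TASK_INSTRUMENTS,
    InstrumentTrack,
    RunConfig,
    TrialRecording,
)
from .kinematics import (
    KinematicDerivatives,
    resample_series,
    smooth_and_differentiate,
    unwrap_degrees,
)

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class GripperEventList:
    """Time-ordered, alternating open/close events of one gripper."""

    times: np.ndarray
    kinds: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != len(self.kinds):
            raise ValueError("times and kinds must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("events must be time-ordered")
        for a, b in zip(self.kinds, self.kinds[1:]):
            if a == b:
                raise ValueError("open/close events must alternate")

    def __len__(self) -> int:
        return int(self.times.size)


def compute_efficiency_metrics(
    deriv: KinematicDerivatives, depth_axis: str = "z"
) -> dict[str, float]:
    """OT, PL, DPL and WA from smoothed positions.

    PL sums Euclidean steps of the smoothed tip; DPL sums absolute steps of
    the depth coordinate; WA is the area of the 2-d convex hull of the tip
    positions projected on the plane perpendicular to the depth axis.
    """
    if len(deriv) < 2:
        raise ValueError("need at least 2 samples")
    d = _AXIS_INDEX[depth_axis]
    steps = np.diff(deriv.pos, axis=0)
    pl = float(np.sum(np.linalg.norm(steps, axis=1)))
    dpl = float(np.sum(np.abs(steps[:, d])))
    plane = deriv.pos[:, [i for i in range(3) if i != d]]
    wa = convex_hull_area(plane)
    ot = float(deriv.t[-1] - deriv.t[0])
    return {"OT": ot, "PL": pl, "DPL": dpl, "WA": wa}


def convex_hull_area(points2d: np.ndarray) -> float:
    """Area of the planar convex hull; 0 for degenerate (collinear) input."""
    points2d = np.asarray(points2d, dtype=float)
    if points2d.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(points2d).volume)  # .volume is area in 2-d
    except QhullError:
        return 0.0


def _time_mean(series: np.ndarray, t: np.ndarray) -> float:
    """Trapezoidal time average; equals the arithmetic mean on a uniform
    grid up to endpoint weighting (matters for short segments that start
    and end at rest)."""
    if series.size == 1:
        return float(series[0])
    return float(np.trapezoid(series, t) / (t[-1] - t[0]))


def compute_speed_metrics(
    deriv: KinematicDerivatives, depth_axis: str = "z"
) -> dict[str, float]:
    """Time-means of speed, acceleration and jerk magnitudes, plus DV."""
    if len(deriv) < 1:
        raise ValueError("empty derivatives")
    d = _AXIS_INDEX[depth_axis]
    return {
        "v": _time_mean(deriv.speed, deriv.t),
        "a": _time_mean(deriv.acc_mag, deriv.t),
        "j": _time_mean(deriv.jerk_mag, deriv.t),
        "DV": _time_mean(np.abs(deriv.vel[:, d]), deriv.t),
    }


def detect_gripper_events(
    track: InstrumentTrack, threshold: float = 15.0, hysteresis: float = 5.0
) -> GripperEventList:
    """Hysteresis thresholding of the gripper angle.

    An *open* event fires when the angle rises through threshold+hysteresis
    after having been below threshold-hysteresis; *close* symmetrically.
    Alternation is inherent in the two-state machine.
    """
    grip = track.grip
    hi = threshold + hysteresis
    lo = threshold - hysteresis
    state_open = grip[0] >= threshold
    times: list[float] = []
    kinds: list[str] = []
    for i in range(1, grip.size):
        if not state_open and grip[i] >= hi:
            state_open = True
            times.append(float(track.t[i]))
            kinds.append("open")
        elif state_open and grip[i] <= lo:
            state_open = False
            times.append(float(track.t[i]))
            kinds.append("close")
    return GripperEventList(times=np.asarray(times), kinds=kinds)


def _bd_pearson(speed_r: np.ndarray, speed_l: np.ndarray) -> float:
    if np.std(speed_r) == 0.0 or np.std(speed_l) == 0.0:
        return float("nan")
    return float(np.corrcoef(speed_r, speed_l)[0, 1])


def _bd_xcorr(speed_r: np.ndarray, speed_l: np.ndarray, rate: float) -> float:
    """Max zero-mean Pearson correlation over lags within +-1 s."""
    if np.std(speed_r) == 0.0 or np.std(speed_l) == 0.0:
        return float("nan")
    max_lag = int(round(rate))
    best = -np.inf
    n = speed_r.size
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = speed_r[lag:], speed_l[: n - lag]
        else:
            a, b = speed_r[: n + lag], speed_l[-lag:]
        if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
            continue
        best = max(best, float(np.corrcoef(a, b)[0, 1]))
    return best if np.isfinite(best) else float("nan")


def compute_bimanual_metrics(
    right: KinematicDerivatives,
    left: KinematicDerivatives,
    right_events: GripperEventList,
    left_events: GripperEventList,
    bd_mode: str = "pearson",
) -> dict[str, float]:
    """Two-hand coordination metrics on the common timebase.

    BD is the correlation of the two hands' speed profiles; ROB and RPLB
    are right/left ratios of gripper-event counts and path lengths; ADB is
    the mean inter-tip distance and ADBO that distance sampled at the
    open/close events of either hand.  Undefined ratios or correlations are
    returned as NaN (flagged missing, never infinite).
    """
    t0 = max(right.t[0], left.t[0])
    t1 = min(right.t[-1], left.t[-1])
    if t1 < t0:
        raise ValueError("tracks have no overlapping time range")
    rate = max(right.sample_rate, left.sample_rate)
    t = t0 + np.arange(int(np.floor((t1 - t0) * rate)) + 1) / rate

    speed_r = resample_series(t, right.t, right.speed)
    speed_l = resample_series(t, left.t, left.speed)
    if bd_mode == "pearson":
        bd = _bd_pearson(speed_r, speed_l)
    else:
        bd = _bd_xcorr(speed_r, speed_l, rate)

    pos_r = np.column_stack([resample_series(t, right.t, right.pos[:, k]) for k in range(3)])
    pos_l = np.column_stack([resample_series(t, left.t, left.pos[:, k]) for k in range(3)])
    dist = np.linalg.norm(pos_r - pos_l, axis=1)
    adb = float(np.mean(dist))

    event_times = np.concatenate([right_events.times, left_events.times])
    event_times = event_times[(event_times >= t0) & (event_times <= t1)]
    if event_times.size:
        adbo = float(np.mean(np.interp(event_times, t, dist)))
    else:
        adbo = float("nan")

    n_r, n_l = len(right_events), len(left_events)
    rob = float(n_r) / n_l if n_l > 0 else float("nan")

    pl_r = float(np.sum(np.linalg.norm(np.diff(right.pos, axis=0), axis=1)))
    pl_l = float(np.sum(np.linalg.norm(np.diff(left.pos, axis=0), axis=1)))
    rplb = pl_r / pl_l if pl_l > 0 else float("nan")

    return {"BD": bd, "ROB": rob, "RPLB": rplb, "ADBO": adbo, "ADB": adb}


def compute_attitude_metrics(track: InstrumentTrack) -> dict[str, float]:
    """Gripper/attitude angle summaries of one instrument.

    Angles are unwrapped before averaging or differencing, so a roll series
    crossing 350->10 degrees contributes 20 degrees, not 340.  AL-PitchYaw
    accumulates the great-circle angle between consecutive shaft-direction
    unit vectors reconstructed from (pitch, yaw).
    """
    roll = unwrap_degrees(track.roll)
    pitch = unwrap_degrees(track.pitch)
    yaw = unwrap_degrees(track.yaw)
    al_roll = float(np.sum(np.abs(np.diff(roll))))
    u = shaft_unit_vectors(pitch, yaw)
    dots = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
    al_pitchyaw = float(np.degrees(np.sum(np.arccos(dots))))
    return {
        "AGRA": float(np.mean(track.grip)),
        "Roll": float(np.mean(roll)),
        "Pitch": float(np.mean(pitch)),
        "Yaw": float(np.mean(yaw)),
        "AL-Roll": al_roll,
        "AL-PitchYaw": al_pitchyaw,
    }


def shaft_unit_vectors(pitch_deg: np.ndarray, yaw_deg: np.ndarray) -> np.ndarray:
    """Unit direction of the instrument shaft from pitch (elevation) and yaw
    (azimuth): u = (cos p sin y, sin p, cos p cos y)."""
    p = np.radians(pitch_deg)
    y = np.radians(yaw_deg)
    return np.column_stack([np.cos(p) * np.sin(y), np.sin(p), np.cos(p) * np.cos(y)])


#: bimanual pair per task as ((instrument, hand) right, (instrument, hand) left)
BIMANUAL_PAIR = {
    "task1_dissection": (("scissors", "right"), ("grasper", "left")),
    "task3_suturing": (("needle_holder", "right"), ("needle_holder", "left")),
}


@dataclass
class MetricVector:
    """Named metric values of one trial; NaN marks a flagged-missing value."""

    trial_id: str
    values: dict[str, float] = field(default_factory=dict)

    def missing(self) -> list[str]:
        return [k for k, v in self.values.items() if not np.isfinite(v)]


def compute_metric_vector(trial: TrialRecording, config: RunConfig) -> MetricVector:
    """Assemble the full per-trial metric vector.

    Per-instrument metrics are prefixed by the instrument letter (G/S/C for
    grasper, scissors, clip applier; R/L for the needle holders); OT is
    trial-level (whole-session duration); bimanual metrics are unprefixed.
    """
    values: dict[str, float] = {}
    derivs: dict[tuple[str, str], KinematicDerivatives] = {}
    events: dict[tuple[str, str], GripperEventList] = {}

    for instrument_id, hand in TASK_INSTRUMENTS[trial.task]:
        track = trial.get_track(instrument_id, hand)
        deriv = smooth_and_differentiate(track, config.sg_window, config.sg_polyorder)
        derivs[(instrument_id, hand)] = deriv
        events[(instrument_id, hand)] = detect_gripper_events(
            track, config.grip_threshold, config.grip_hysteresis
        )
        prefix = INSTRUMENT_PREFIX[(instrument_id, hand)]
        eff = compute_efficiency_metrics(deriv, config.depth_axis)
        spd = compute_speed_metrics(deriv, config.depth_axis)
        att = compute_attitude_metrics(track)
        for name, val in {**eff, **spd, **att}.items():
            if name == "OT":
                continue  # trial-level, added once below
            values[f"{prefix}_{name}"] = val

    t_start = min(tr.t[0] for tr in trial.tracks)
    t_end = max(tr.t[-1] for tr in trial.tracks)
    values["OT"] = float(t_end - t_start)

    (r_key, l_key) = BIMANUAL_PAIR[trial.task]
    values.update(
        compute_bimanual_metrics(
            derivs[r_key],
            derivs[l_key],
            events[r_key],
            events[l_key],
            bd_mode=config.bd_mode,
        )
    )
    return MetricVector(trial_id=trial.trial_id, values=values)


def compute_features(cohort, config: RunConfig):
    """Metric vectors for every trial of a cohort, as a FeatureMatrix."""
    from .io import FeatureMatrix

    records, meta = [], []
    for trial in cohort.trials:
        mv = compute_metric_vector(trial, config)
        records.append(mv.values)
        meta.append(
            {
                "trial_id": trial.trial_id,
                "task": trial.task,
                "n_prior_surgeries": trial.n_prior_surgeries,
                "label3": trial.group3,
                "label2": trial.group2,
            }
        )
    return FeatureMatrix.from_records(records, meta)
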