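"""Synthetic two-handed instrument trajectories with planted expertise effects.

No public recordings of wet-lab laparoscopic training exist, so the
package ships a generative model that emulates their structure: 30 Hz
tip tracks built from minimum-jerk reach segments toward goal points in a
workspace box, with skill-dependent corrective submovements, physiological
tremor, depth wobble, attitude fidgeting, gripper cycles and inter-hand
timing jitter.  Skill is a scalar in [0, 1] mapped log-linearly from the
prior caseload; every skill knob moves monotonically so that efficiency
metrics (time, path length, depth path length) fall with expertise while
speed metrics (velocity, acceleration, jerk of the deliberate movements)
rise — the group differences the downstream analysis is built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .io import (
    TASK_INSTRUMENTS,
    Cohort,
    InstrumentTrack,
    TrialRecording,
)

#: (novice_value, expert_value) pairs; linear in skill between the two
SkillMap = tuple[float, float]


def skill_value(mapping: SkillMap, skill: float) -> float:
    novice, expert = mapping
    return float(novice + (expert - novice) * skill)


@dataclass
class SyntheticCohortConfig:
    """Study-condition parameters of the trajectory simulator.

    Skill maps are (novice, expert) endpoint pairs interpolated linearly in
    skill; all the defaults are chosen so a trial lasts roughly 60-180
    simulated seconds and the planted effects have the directions observed
    in trained-surgeon cohorts (see docs/methods.md for the rationale
    behind each magnitude).
    """

    n_experts: int = 32
    n_intermediates: int = 18
    n_novices: int = 20
    task: str = "task1_dissection"
    #: axis-aligned workspace box, mm: ((xmin, xmax), (ymin, ymax), (zmin, zmax))
    workspace: tuple = ((-60.0, 60.0), (-40.0, 40.0), (-120.0, -40.0))
    goals_per_trial: int = 24
    base_segment_duration: float = 2.2      # s, before the skill time-scale
    segment_time_scale: SkillMap = (1.9, 0.55)    # experts move faster
    corrective_rate: SkillMap = (3.0, 0.5)        # submovements per goal
    tremor_rms_mm: SkillMap = (0.015, 0.008)      # tip tremor RMS
    tremor_cutoff_hz: float = 8.0                 # physiological tremor band
    depth_excursion_mm: SkillMap = (6.0, 1.0)     # depth wobble amplitude
    depth_excursion_hz: float = 0.2
    roll_fidget_deg_s: SkillMap = (40.0, 10.0)    # mean |roll rate|
    pause_s: SkillMap = (1.8, 0.5)                # dwell between goals
    bimanual_jitter_s: SkillMap = (0.5, 0.08)     # left-hand timing offset
    spurious_grip_per_min: SkillMap = (4.0, 0.5)  # extra open/close cycles
    #: SD of per-participant aptitude noise added to the caseload-derived
    #: skill; caseload is an imperfect proxy for actual performance
    skill_sigma: float = 0.12
    attitude_noise_deg: float = 0.5
    sample_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_experts, self.n_intermediates, self.n_novices) < 0:
            raise ValueError("group sizes must be >= 0")
        if self.goals_per_trial < 1:
            raise ValueError("goals_per_trial must be >= 1")
        for lo, hi in self.workspace:
            if not hi > lo:
                raise ValueError("workspace box must have positive extent")
        for name in (
            "corrective_rate",
            "tremor_rms_mm",
            "depth_excursion_mm",
            "roll_fidget_deg_s",
            "pause_s",
            "bimanual_jitter_s",
            "spurious_grip_per_min",
        ):
            novice, expert = getattr(self, name)
            if novice < 0 or expert < 0:
                raise ValueError(f"{name} amplitudes must be >= 0")
            if expert > novice:
                raise ValueError(f"{name} must not increase with skill")

    def zero_effect(self) -> "SyntheticCohortConfig":
        """A null copy: every skill map collapsed to its midpoint, so groups
        differ only by sampling noise (classifier chance calibration)."""
        mid = lambda m: ((m[0] + m[1]) / 2.0,) * 2  # noqa: E731
        return replace(
            self,
            segment_time_scale=mid(self.segment_time_scale),
            corrective_rate=mid(self.corrective_rate),
            tremor_rms_mm=mid(self.tremor_rms_mm),
            depth_excursion_mm=mid(self.depth_excursion_mm),
            roll_fidget_deg_s=mid(self.roll_fidget_deg_s),
            pause_s=mid(self.pause_s),
            bimanual_jitter_s=mid(self.bimanual_jitter_s),
            spurious_grip_per_min=mid(self.spurious_grip_per_min),
        )


@dataclass
class MinimumJerkSegment:
    """Straight minimum-jerk reach: zero boundary velocity/acceleration."""

    start: np.ndarray
    end: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if not self.duration > 0:
            raise ValueError("duration must be > 0")


def minimum_jerk_position(segment: MinimumJerkSegment, t) -> np.ndarray:
    """Position along a minimum-jerk segment at time(s) t in [0, T].

    p(t) = start + (end - start) * (10 tau^3 - 15 tau^4 + 6 tau^5) with
    tau = t/T; peak speed is 1.875 * D / T at tau = 1/2.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > segment.duration + 1e-12):
        raise ValueError("t outside [0, duration]")
    tau = np.clip(t / segment.duration, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return segment.start + np.multiply.outer(s, segment.end - segment.start)


def _bandlimited_noise(rng, n: int, rms: float, cutoff_hz: float, fs: float) -> np.ndarray:
    """(n, 3) Gaussian noise low-passed at ``cutoff_hz`` and rescaled so the
    total (3-axis) RMS equals ``rms``."""
    if rms <= 0 or n < 20:
        return np.zeros((n, 3))
    white = rng.standard_normal((n, 3))
    b, a = butter(2, cutoff_hz / (fs / 2.0))
    filtered = filtfilt(b, a, white, axis=0)
    scale = rms / np.sqrt(3.0) / np.std(filtered, axis=0)
    return filtered * scale


def _raised_cosine_bump(n: int, width_samples: int, center: int, amp: float) -> np.ndarray:
    """Smooth open-close gripper pulse added onto the baseline angle."""
    out = np.zeros(n)
    half = width_samples // 2
    lo = max(0, center - half)
    hi = min(n, center + half)
    if hi <= lo:
        return out
    idx = np.arange(lo, hi)
    phase = (idx - (center - half)) / float(2 * half)
    out[lo:hi] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out


def _plan_schedule(cfg: SyntheticCohortConfig, skill: float, rng) -> list[dict]:
    """Shared goal schedule: per goal, a target point (per hand), primary
    segment duration and pause, plus corrective-submovement counts."""
    fs = cfg.sample_rate
    tscale = skill_value(cfg.segment_time_scale, skill)
    rate_corr = skill_value(cfg.corrective_rate, skill)
    pause = skill_value(cfg.pause_s, skill)
    lows = np.array([b[0] for b in cfg.workspace])
    highs = np.array([b[1] for b in cfg.workspace])
    schedule = []
    for _ in range(cfg.goals_per_trial):
        goal_r = rng.uniform(lows, highs)
        goal_l = rng.uniform(lows, highs)
        dur = cfg.base_segment_duration * tscale * rng.uniform(0.7, 1.3)
        schedule.append(
            {
                "goal_right": goal_r,
                "goal_left": goal_l,
                "duration": max(2.0 / fs, dur),
                "pause": max(2.0 / fs, pause * rng.uniform(0.5, 1.5)),
                "n_corrective": int(rng.poisson(rate_corr)),
            }
        )
    return schedule


def _synth_tip_path(
    cfg: SyntheticCohortConfig,
    skill: float,
    schedule: list[dict],
    goal_key: str,
    start: np.ndarray,
    rng,
) -> np.ndarray:
    """Concatenate per-goal minimum-jerk segments, correctives and pauses
    into a sampled (n, 3) tip path on the 30 Hz grid."""
    fs = cfg.sample_rate
    tscale = skill_value(cfg.segment_time_scale, skill)
    blocks = [start[None, :]]
    pos = start.copy()
    for goal in schedule:
        target = goal[goal_key]
        n = max(2, int(round(goal["duration"] * fs)))
        seg = MinimumJerkSegment(pos, target, n / fs)  # snap duration to the grid
        ts = np.arange(1, n + 1) / fs
        blocks.append(minimum_jerk_position(seg, ts))
        pos = target.copy()
        dist = float(np.linalg.norm(seg.end - seg.start))
        for _ in range(goal["n_corrective"]):
            hop_len = rng.uniform(0.05, 0.15) * max(dist, 10.0)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            hop_target = pos + hop_len * direction
            m = max(2, int(round(rng.uniform(0.8, 1.2) * tscale * fs)))
            hop = MinimumJerkSegment(pos, hop_target, m / fs)
            ts = np.arange(1, m + 1) / fs
            blocks.append(minimum_jerk_position(hop, ts))
            pos = hop_target
        n_pause = int(round(goal["pause"] * fs))
        if n_pause:
            blocks.append(np.repeat(pos[None, :], n_pause, axis=0))
    return np.concatenate(blocks, axis=0)


#: trocar entry points, mm: shaft runs from here to the tip
TROCARS = {"right": np.array([110.0, 60.0, 30.0]), "left": np.array([-110.0, 60.0, 30.0])}


def _attitude_from_path(
    cfg: SyntheticCohortConfig, skill: float, path: np.ndarray, hand: str, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(roll, pitch, yaw) in degrees.  Pitch/yaw point the shaft from the
    trocar to the tip (plus smoothed noise); roll is a bounded random walk
    whose mean absolute rate is the skill-dependent fidget rate."""
    fs = cfg.sample_rate
    n = path.shape[0]
    u = path - TROCARS[hand]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pitch = np.degrees(np.arcsin(np.clip(u[:, 1], -1.0, 1.0)))
    yaw = np.degrees(np.arctan2(u[:, 0], u[:, 2]))
    if cfg.attitude_noise_deg > 0 and n >= 20:
        noise = _bandlimited_noise(rng, n, cfg.attitude_noise_deg * np.sqrt(3), 2.0, fs)
        pitch = pitch + noise[:, 0]
        yaw = yaw + noise[:, 1]
    fidget = skill_value(cfg.roll_fidget_deg_s, skill)
    # E|step| * fs = fidget  =>  per-step sigma = fidget/fs * sqrt(pi/2)
    steps = rng.standard_normal(n) * (fidget / fs) * np.sqrt(np.pi / 2.0)
    roll = np.cumsum(steps)
    roll = 90.0 * np.sin(roll / 90.0)  # soft bound at +-90 deg
    return roll, pitch, yaw


def _grip_channel(
    cfg: SyntheticCohortConfig,
    skill: float,
    n: int,
    goal_arrival_idx: np.ndarray,
    rng,
) -> np.ndarray:
    """Baseline-closed gripper with an open-close pulse at each goal arrival
    plus spurious cycles at a skill-dependent Poisson rate."""
    fs = cfg.sample_rate
    grip = np.full(n, 5.0)
    width = int(round(0.8 * fs))
    for idx in goal_arrival_idx:
        grip += _raised_cosine_bump(n, width, int(idx), 40.0)
    rate_per_sample = skill_value(cfg.spurious_grip_per_min, skill) / 60.0 / fs
    n_spurious = rng.poisson(rate_per_sample * n)
    for idx in rng.integers(0, max(1, n - 1), size=n_spurious):
        grip += _raised_cosine_bump(n, width, int(idx), 40.0)
    return grip


def _goal_arrival_indices(
    cfg: SyntheticCohortConfig, skill: float, schedule: list[dict]
) -> np.ndarray:
    fs = cfg.sample_rate
    tscale = skill_value(cfg.segment_time_scale, skill)
    idx, cursor = [], 0
    for goal in schedule:
        cursor += max(2, int(round(goal["duration"] * fs)))
        idx.append(cursor)
        for _ in range(goal["n_corrective"]):
            cursor += max(2, int(round(1.0 * tscale * fs)))  # nominal hop
        cursor += int(round(goal["pause"] * fs))
    return np.asarray(idx)


def _build_track(
    cfg: SyntheticCohortConfig,
    skill: float,
    schedule: list[dict],
    instrument_id: str,
    hand: str,
    rng,
    time_offset_s: float = 0.0,
) -> InstrumentTrack:
    fs = cfg.sample_rate
    goal_key = "goal_right" if hand == "right" else "goal_left"
    lows = np.array([b[0] for b in cfg.workspace])
    highs = np.array([b[1] for b in cfg.workspace])
    start = rng.uniform(lows, highs)
    path = _synth_tip_path(cfg, skill, schedule, goal_key, start, rng)
    n = path.shape[0]

    # timing jitter: shift the whole left-hand stream by a fraction of a
    # second, holding the boundary sample (no wrap-around discontinuity)
    if time_offset_s:
        shift = int(round(abs(time_offset_s) * fs))
        if shift and shift < n:
            if time_offset_s > 0:
                path = np.concatenate(
                    [np.repeat(path[:1], shift, axis=0), path[:-shift]], axis=0
                )
            else:
                path = np.concatenate(
                    [path[shift:], np.repeat(path[-1:], shift, axis=0)], axis=0
                )

    tremor = _bandlimited_noise(
        rng, n, skill_value(cfg.tremor_rms_mm, skill), cfg.tremor_cutoff_hz, fs
    )
    path = path + tremor

    depth_amp = skill_value(cfg.depth_excursion_mm, skill)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    path[:, 2] += depth_amp * np.sin(2 * np.pi * cfg.depth_excursion_hz * t + phase)

    roll, pitch, yaw = _attitude_from_path(cfg, skill, path, hand, rng)
    grip = _grip_channel(cfg, skill, n, _goal_arrival_indices(cfg, skill, schedule), rng)

    return InstrumentTrack(
        instrument_id=instrument_id,
        hand=hand,
        t=t,
        x=path[:, 0],
        y=path[:, 1],
        z=path[:, 2],
        roll=roll,
        pitch=pitch,
        yaw=yaw,
        grip=grip,
        sample_rate=fs,
    )


def _pad_to_length(track: InstrumentTrack, n: int) -> InstrumentTrack:
    """Hold the final sample so all tracks of a trial share one duration."""
    cur = len(track)
    if cur >= n:
        return track
    pad = n - cur
    def ext(a):
        return np.concatenate([a, np.full(pad, a[-1])])
    return InstrumentTrack(
        instrument_id=track.instrument_id,
        hand=track.hand,
        t=np.arange(n) / track.sample_rate,
        x=ext(track.x), y=ext(track.y), z=ext(track.z),
        roll=ext(track.roll), pitch=ext(track.pitch), yaw=ext(track.yaw),
        grip=ext(track.grip),
        sample_rate=track.sample_rate,
    )


def simulate_trial(
    config: SyntheticCohortConfig,
    skill: float,
    participant_id: str,
    trial_id: str,
    n_prior_surgeries: int,
    seed: int,
) -> TrialRecording:
    """One synthetic training session at the given skill level.

    The same (config, skill, seed) always yields bit-identical output; all
    randomness flows from ``seed`` through per-track child generators.
    """
    if not (0.0 <= skill <= 1.0):
        raise ValueError("skill must lie in [0, 1]")
    ss = np.random.SeedSequence(entropy=seed)
    children = ss.spawn(1 + len(TASK_INSTRUMENTS[config.task]))
    rng_plan = np.random.default_rng(children[0])
    schedule = _plan_schedule(config, skill, rng_plan)
    jitter = skill_value(config.bimanual_jitter_s, skill)

    tracks = []
    for k, (instrument_id, hand) in enumerate(TASK_INSTRUMENTS[config.task]):
        rng = np.random.default_rng(children[1 + k])
        offset = rng.uniform(-jitter, jitter) if hand == "left" else 0.0
        tracks.append(
            _build_track(config, skill, schedule, instrument_id, hand, rng, offset)
        )
    n_max = max(len(tr) for tr in tracks)
    tracks = [_pad_to_length(tr, n_max) for tr in tracks]
    return TrialRecording(
        trial_id=trial_id,
        participant_id=participant_id,
        task=config.task,
        n_prior_surgeries=n_prior_surgeries,
        tracks=tracks,
    )


#: caseload sampling range per group (inclusive)
GROUP_CASELOAD = {"expert": (50, 500), "intermediate": (10, 49), "novice": (0, 9)}


def skill_from_caseload(n_prior_surgeries: int) -> float:
    """Log-linear learning curve: skill = log10(1+n)/log10(501), clipped."""
    return float(
        np.clip(np.log10(1.0 + n_prior_surgeries) / np.log10(501.0), 0.0, 1.0)
    )


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """A full cohort with per-group caseloads, skills and trial seeds derived
    reproducibly from ``config.seed``."""
    sizes = {
        "expert": config.n_experts,
        "intermediate": config.n_intermediates,
        "novice": config.n_novices,
    }
    if sum(sizes.values()) == 0:
        raise ValueError("at least one group size must be positive")
    ss = np.random.SeedSequence(entropy=config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    trials = []
    counter = 0
    for group in ("expert", "intermediate", "novice"):
        lo, hi = GROUP_CASELOAD[group]
        for _ in range(sizes[group]):
            counter += 1
            n_cases = int(rng.integers(lo, hi + 1))
            trial_seed = int(rng.integers(0, 2**31 - 1))
            skill = float(
                np.clip(
                    skill_from_caseload(n_cases)
                    + rng.normal(0.0, config.skill_sigma),
                    0.0,
                    1.0,
                )
            )
            trials.append(
                simulate_trial(
                    config,
                    skill=skill,
                    participant_id=f"P{counter:03d}",
                    trial_id=f"T{counter:03d}",
                    n_prior_surgeries=n_cases,
                    seed=trial_seed,
                )
            )
    return Cohort(trials=trials, provenance="synthetic", seed=config.seed)
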