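"""On-disk formats and core domain types.

An instrument track is a flat CSV (header ``t,x,y,z,roll,pitch,yaw,grip``,
9 significant digits, UTF-8); a trial is a YAML manifest naming its track
files, hand assignment, task and the participant's prior caseload; a cohort
is a directory of trial subdirectories plus a label CSV.  Positions are in
millimetres in a right-handed frame, angles in degrees, time in 0-based
seconds at a fixed sample rate carried explicitly in the manifest.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

TRACK_COLUMNS = ("t", "x", "y", "z", "roll", "pitch", "yaw", "grip")

TASK_DISSECTION = "task1_dissection"
TASK_SUTURING = "task3_suturing"

#: instruments each task must contain, as (instrument_id, hand) pairs
TASK_INSTRUMENTS = {
    TASK_DISSECTION: (
        ("grasper", "left"),
        ("scissors", "right"),
        ("clip_applier", "right"),
    ),
    TASK_SUTURING: (
        ("needle_holder", "right"),
        ("needle_holder", "left"),
    ),
}

#: metric-name prefix per (task, instrument_id, hand)
INSTRUMENT_PREFIX = {
    ("grasper", "left"): "G",
    ("scissors", "right"): "S",
    ("clip_applier", "right"): "C",
    ("needle_holder", "right"): "R",
    ("needle_holder", "left"): "L",
}

GROUP_EXPERT = "expert"
GROUP_INTERMEDIATE = "intermediate"
GROUP_NOVICE = "novice"
GROUP_NON_EXPERT = "non_expert"


class TrackParseError(ValueError):
    """Raised when a track file violates the CSV dialect."""


def assign_group(n_prior_surgeries: int) -> str:
    """Three-level experience group from the prior laparoscopic caseload.

    Experts performed >=50 laparoscopic surgeries, intermediates 10-49,
    novices 0-9.
    """
    n = int(n_prior_surgeries)
    if n < 0:
        raise ValueError(f"n_prior_surgeries must be >= 0, got {n}")
    if n >= 50:
        return GROUP_EXPERT
    if n >= 10:
        return GROUP_INTERMEDIATE
    return GROUP_NOVICE


def count_sessions(visit_counts: Sequence[int]) -> int:
    """Total training sessions given per-participant visit counts.

    Each participant contributes as many sessions as visits (e.g. 51
    one-time plus 19 two-time participants -> 89 sessions).
    """
    counts = [int(c) for c in visit_counts]
    if any(c < 1 for c in counts):
        raise ValueError("every participant has at least one visit")
    return sum(counts)


def assign_group2(n_prior_surgeries: int) -> str:
    """Two-level grouping: experts (>=50 cases) vs everyone else."""
    return (
        GROUP_EXPERT
        if assign_group(n_prior_surgeries) == GROUP_EXPERT
        else GROUP_NON_EXPERT
    )


@dataclass
class InstrumentTrack:
    """Raw 30 Hz time series of one instrument.

    Attributes
    ----------
    t : 1-d array, seconds, strictly increasing at 1/sample_rate spacing
    x, y, z : tip coordinates, mm
    roll, pitch, yaw : shaft attitude, degrees
    grip : gripper opening angle, degrees
    """

    instrument_id: str
    hand: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    grip: np.ndarray
    sample_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.hand not in ("right", "left"):
            raise ValueError(f"hand must be 'right' or 'left', got {self.hand!r}")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        arrays = {name: np.asarray(getattr(self, name), dtype=float)
                  for name in TRACK_COLUMNS}
        n = arrays["t"].size
        if n == 0:
            raise ValueError("empty track")
        for name, arr in arrays.items():
            if arr.ndim != 1:
                raise ValueError(f"channel {name!r} must be 1-d")
            if arr.size != n:
                raise ValueError(
                    f"channel {name!r} has length {arr.size}, expected {n}"
                )
            setattr(self, name, arr)
        dt = np.diff(arrays["t"])
        if np.any(dt <= 0):
            raise ValueError("non-monotone time")
        if np.any(np.abs(dt - 1.0 / self.sample_rate) > 1e-6):
            raise ValueError(
                "time spacing deviates from 1/sample_rate by more than 1e-6 s"
            )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def positions(self) -> np.ndarray:
        """(n, 3) array of tip positions in mm."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class TrialRecording:
    """All instrument tracks of one training session plus its labels."""

    trial_id: str
    participant_id: str
    task: str
    n_prior_surgeries: int
    tracks: list[InstrumentTrack]

    def __post_init__(self) -> None:
        if self.task not in TASK_INSTRUMENTS:
            raise ValueError(
                f"unknown task {self.task!r}; expected one of {sorted(TASK_INSTRUMENTS)}"
            )
        if int(self.n_prior_surgeries) < 0:
            raise ValueError("n_prior_surgeries must be >= 0")
        self.n_prior_surgeries = int(self.n_prior_surgeries)
        present = {(tr.instrument_id, tr.hand) for tr in self.tracks}
        for wanted in TASK_INSTRUMENTS[self.task]:
            if wanted not in present:
                raise ValueError(
                    f"task {self.task!r} requires instrument "
                    f"{wanted[1]} {wanted[0]}, which is missing"
                )

    def get_track(self, instrument_id: str, hand: str) -> InstrumentTrack:
        for tr in self.tracks:
            if tr.instrument_id == instrument_id and tr.hand == hand:
                return tr
        raise KeyError(f"no track for {hand} {instrument_id}")

    @property
    def group3(self) -> str:
        return assign_group(self.n_prior_surgeries)

    @property
    def group2(self) -> str:
        return assign_group2(self.n_prior_surgeries)


@dataclass
class Cohort:
    """A set of trials, either simulated or imported from disk."""

    trials: list[TrialRecording]
    provenance: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [tr.trial_id for tr in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("trial_ids are not unique")

    def __len__(self) -> int:
        return len(self.trials)

    def labels_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trial_id": tr.trial_id,
                "participant_id": tr.participant_id,
                "task": tr.task,
                "n_prior_surgeries": tr.n_prior_surgeries,
                "label3": tr.group3,
                "label2": tr.group2,
            }
            for tr in self.trials
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# track CSV


def write_track_file(track: InstrumentTrack, path: str | os.PathLike) -> None:
    """Write a track as CSV with 12 significant digits (keeps the read/write
    round trip within 1e-9 relative error)."""
    if len(track) == 0:  # pragma: no cover - constructor forbids this
        raise ValueError("empty track")
    data = np.column_stack([getattr(track, c) for c in TRACK_COLUMNS])
    header = ",".join(TRACK_COLUMNS)
    np.savetxt(path, data, fmt="%.12g", delimiter=",", header=header, comments="")


def read_track_file(
    path: str | os.PathLike,
    instrument_id: str = "unknown",
    hand: str = "right",
    sample_rate: float | None = None,
) -> InstrumentTrack:
    """Read a track CSV.

    ``instrument_id``, ``hand`` and ``sample_rate`` live in the trial
    manifest, not in the CSV; callers loading bare files may rely on the
    defaults, with the sample rate inferred from the median time step.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    if [c.strip() for c in header.split(",")] != list(TRACK_COLUMNS):
        raise TrackParseError(
            f"{path}, line 1: malformed header {header!r}; "
            f"expected {','.join(TRACK_COLUMNS)}"
        )
    try:
        frame = pd.read_csv(path, dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise TrackParseError(f"{path}: {exc}") from exc
    if frame.isna().any().any():
        row = int(np.where(frame.isna().any(axis=1))[0][0])
        raise TrackParseError(f"{path}, line {row + 2}: missing or ragged values")
    t = frame["t"].to_numpy()
    if t.size > 1:
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise TrackParseError(
                f"{path}, line {int(bad[0]) + 3}: non-monotone time"
            )
    if sample_rate is None:
        if t.size < 2:
            raise TrackParseError(f"{path}: cannot infer sample_rate from one row")
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return InstrumentTrack(
        instrument_id=instrument_id,
        hand=hand,
        sample_rate=float(sample_rate),
        **{c: frame[c].to_numpy() for c in TRACK_COLUMNS},
    )


# ---------------------------------------------------------------------------
# trial manifest + cohort directory


def write_trial(trial: TrialRecording, directory: str | os.PathLike) -> Path:
    """Write a trial as manifest YAML + one CSV per track; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in trial.tracks:
        fname = f"{tr.hand}_{tr.instrument_id}.csv"
        write_track_file(tr, directory / fname)
        entries.append(
            {
                "file": fname,
                "instrument_id": tr.instrument_id,
                "hand": tr.hand,
                "sample_rate": float(tr.sample_rate),
            }
        )
    manifest = {
        "trial_id": trial.trial_id,
        "participant_id": trial.participant_id,
        "task": trial.task,
        "n_prior_surgeries": int(trial.n_prior_surgeries),
        "tracks": entries,
    }
    mpath = directory / "trial.yaml"
    with open(mpath, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def read_trial(manifest_path: str | os.PathLike) -> TrialRecording:
    manifest_path = Path(manifest_path)
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    for key in ("trial_id", "participant_id", "task", "n_prior_surgeries", "tracks"):
        if key not in manifest:
            raise ValueError(f"{manifest_path}: manifest missing field {key!r}")
    tracks = [
        read_track_file(
            manifest_path.parent / entry["file"],
            instrument_id=entry["instrument_id"],
            hand=entry["hand"],
            sample_rate=entry.get("sample_rate"),
        )
        for entry in manifest["tracks"]
    ]
    return TrialRecording(
        trial_id=str(manifest["trial_id"]),
        participant_id=str(manifest["participant_id"]),
        task=manifest["task"],
        n_prior_surgeries=int(manifest["n_prior_surgeries"]),
        tracks=tracks,
    )


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for trial in cohort.trials:
        write_trial(trial, directory / trial.trial_id)
    cohort.labels_frame().to_csv(directory / "labels.csv", index=False)
    meta = {"provenance": cohort.provenance, "seed": cohort.seed}
    with open(directory / "cohort.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh)
    return directory


def read_cohort(directory: str | os.PathLike) -> Cohort:
    directory = Path(directory)
    meta_path = directory / "cohort.yaml"
    provenance, seed = "imported", None
    if meta_path.exists():
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
        provenance = meta.get("provenance", "imported")
        seed = meta.get("seed")
    manifests = sorted(directory.glob("*/trial.yaml"))
    if not manifests:
        raise FileNotFoundError(f"no trial manifests under {directory}")
    trials = [read_trial(m) for m in manifests]
    return Cohort(trials=trials, provenance=provenance, seed=seed)


# ---------------------------------------------------------------------------
# feature matrix


META_COLUMNS = ("task", "n_prior_surgeries", "label3", "label2")


@dataclass
class FeatureMatrix:
    """Per-trial metric values plus experience labels.

    ``values`` is a trials x metrics DataFrame indexed by trial_id; ``meta``
    carries task, prior caseload and the derived group labels.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the trial_id index")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"meta missing column {col!r}")

    @classmethod
    def from_records(
        cls, records: Sequence[dict], meta_records: Sequence[dict]
    ) -> "FeatureMatrix":
        meta = pd.DataFrame(meta_records).set_index("trial_id")
        values = pd.DataFrame(records, index=meta.index)
        return cls(values=values, meta=meta)

    @property
    def trial_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metric_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def labels3(self) -> pd.Series:
        return self.meta["label3"]

    @property
    def labels2(self) -> pd.Series:
        return self.meta["label2"]

    def dropna_rows(self) -> "FeatureMatrix":
        """Listwise-delete trials with any undefined metric."""
        keep = ~self.values.isna().any(axis=1)
        return FeatureMatrix(self.values.loc[keep], self.meta.loc[keep])

    def to_csv(self, path: str | os.PathLike) -> None:
        out = pd.concat([self.meta[list(META_COLUMNS)], self.values], axis=1)
        out.index.name = "trial_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureMatrix":
        frame = pd.read_csv(path, index_col="trial_id")
        meta = frame[list(META_COLUMNS)].copy()
        values = frame.drop(columns=list(META_COLUMNS))
        return cls(values=values, meta=meta)


# ---------------------------------------------------------------------------
# run configuration


def _default_svm_grid() -> dict:
    return {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [0.001, 0.01, 0.1, 1.0]}


def _default_pca_svm_grid() -> dict:
    return {
        "retained_variance": [0.7, 0.8, 0.9, 0.95],
        "C": [0.1, 1.0, 10.0, 100.0],
        "gamma": [0.001, 0.01, 0.1, 1.0],
    }


def _default_gbdt_grid() -> dict:
    return {
        "learning_rate": [0.05, 0.1],
        "n_estimators": [50, 100, 200],
        "num_leaves": [7, 15, 31],
    }


@dataclass
class RunConfig:
    """Settings shared by the preprocessing, screening and classification stages.

    The smoothing window/order, gripper event thresholds and hyperparameter
    grids are package defaults documented in docs/methods.md; the CV layout
    (10 outer x 10 inner folds, 100 repetitions) follows the study design.
    """

    sg_window: int = 9
    sg_polyorder: int = 3
    depth_axis: str = "z"
    grip_threshold: float = 15.0
    grip_hysteresis: float = 5.0
    bd_mode: str = "pearson"  # or "xcorr": max cross-correlation within +-1 s
    alpha: float = 0.05
    holm: bool = False
    outer_k: int = 10
    inner_k: int = 10
    repetitions: int = 100
    svm_grid: dict = field(default_factory=_default_svm_grid)
    pca_svm_grid: dict = field(default_factory=_default_pca_svm_grid)
    gbdt_grid: dict = field(default_factory=_default_gbdt_grid)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.depth_axis not in ("x", "y", "z"):
            raise ValueError("depth_axis must be one of x, y, z")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.bd_mode not in ("pearson", "xcorr"):
            raise ValueError("bd_mode must be 'pearson' or 'xcorr'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
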