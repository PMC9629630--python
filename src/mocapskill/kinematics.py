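"""Savitzky-Golay smoothing and derivative estimation for tip trajectories.

The tip track is smoothed with a Savitzky-Golay filter and derivatives up
to jerk are taken from the filter itself (least-squares local polynomial
fits), not from finite differences of the smoothed signal.  Boundary
samples come from the polynomial fitted to the first/last window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import InstrumentTrack


@dataclass
class KinematicDerivatives:
    """Smoothed position and its first three time derivatives.

    Units: mm, mm/s, mm/s^2, mm/s^3; ``speed``/``acc_mag``/``jerk_mag`` are
    per-sample Euclidean norms.
    """

    t: np.ndarray
    pos: np.ndarray    # (n, 3) smoothed tip position
    vel: np.ndarray
    acc: np.ndarray
    jerk: np.ndarray
    sample_rate: float

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.vel, axis=1)

    @property
    def acc_mag(self) -> np.ndarray:
        return np.linalg.norm(self.acc, axis=1)

    @property
    def jerk_mag(self) -> np.ndarray:
        return np.linalg.norm(self.jerk, axis=1)

    def __len__(self) -> int:
        return int(self.t.size)


def savgol_derivatives(
    values: np.ndarray, window: int, polyorder: int, sample_rate: float
) -> list[np.ndarray]:
    """Derivative orders 0..3 of a 1-d signal via one Savitzky-Golay fit each.

    ``mode="interp"`` fits the local polynomial to the first/last window for
    the edge samples rather than padding, so polynomials of degree <=
    polyorder are reproduced exactly everywhere.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if values.size < window:
        raise ValueError(
            f"track length {values.size} is shorter than the filter window {window}"
        )
    delta = 1.0 / sample_rate
    return [
        savgol_filter(values, window, polyorder, deriv=d, delta=delta, mode="interp")
        for d in range(4)
    ]


def smooth_and_differentiate(
    track: InstrumentTrack, window: int = 9, polyorder: int = 3
) -> KinematicDerivatives:
    """Smooth a track's tip coordinates and estimate velocity/acceleration/jerk.

    ``polyorder`` must be at least 3 so the cubic term needed for jerk is
    in the local model.
    """
    if polyorder < 3:
        raise ValueError("polyorder must be >= 3 to estimate jerk")
    per_axis = [
        savgol_derivatives(getattr(track, axis), window, polyorder, track.sample_rate)
        for axis in ("x", "y", "z")
    ]
    stacked = [np.column_stack([per_axis[a][d] for a in range(3)]) for d in range(4)]
    return KinematicDerivatives(
        t=track.t.copy(),
        pos=stacked[0],
        vel=stacked[1],
        acc=stacked[2],
        jerk=stacked[3],
        sample_rate=track.sample_rate,
    )


def unwrap_degrees(angles: np.ndarray) -> np.ndarray:
    """Remove +-180 degree discontinuities from an angle series."""
    return np.unwrap(np.asarray(angles, dtype=float), period=360.0)


def resample_to_common_timebase(
    a: InstrumentTrack, b: InstrumentTrack
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Linearly interpolate two tracks onto the overlap of their time ranges.

    Returns ``(t, channels_a, channels_b)`` where the channel dicts map each
    track column to its interpolated values on the shared grid.  The grid
    runs at the higher of the two sample rates.
    """
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if t1 < t0:
        raise ValueError("tracks have no overlapping time range")
    rate = max(a.sample_rate, b.sample_rate)
    n = int(np.floor((t1 - t0) * rate)) + 1
    t = t0 + np.arange(n) / rate
    channels = ("x", "y", "z", "roll", "pitch", "yaw", "grip")
    out_a = {c: np.interp(t, a.t, getattr(a, c)) for c in channels}
    out_b = {c: np.interp(t, b.t, getattr(b, c)) for c in channels}
    return t, out_a, out_b


def resample_series(
    t_common: np.ndarray, t: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Interpolate an arbitrary per-sample series onto a common grid."""
    return np.interp(t_common, t, values)
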