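"""Trajectory conditioning: gap reconstruction, low-pass filtering, velocity.

Optoelectronic recordings contain dropouts (occluded markers) and
high-frequency measurement noise.  Interior gaps up to a configurable length
are reconstructed with cubic splines; positions are then smoothed with a
zero-lag (forward-backward) Butterworth filter before differentiation.  The
defaults — 4th-order filter at 6 Hz on 120 Hz data, maximum reconstructed gap
0.1 s — are conventional for upper-limb reach kinematics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .errors import ConfigError, ShapeError, UnrecoverableMarkerError
from .kinio import MARKER_NAMES, TrialRecording

DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_ORDER = 4
DEFAULT_MAX_GAP_FRAMES = 12  # 0.1 s at 120 Hz


@dataclass
class VelocitySeries:
    """Tangential (3D) speed of one marker, metres per second per frame."""

    values: np.ndarray
    rate: float
    marker: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ShapeError("velocity series must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)


def _gap_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous invalid runs as (start, stop) half-open index pairs."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(recording: TrialRecording,
              max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES) -> TrialRecording:
    """Reconstruct interior dropouts by per-coordinate cubic-spline
    interpolation over valid samples.

    Interior gaps longer than ``max_gap_frames`` and gaps touching either end
    of the recording are left masked (edge extrapolation is unreliable) and
    reported with a warning.
    """
    out = recording.copy()
    for name in MARKER_NAMES:
        valid = out.validity[name]
        if valid.all():
            continue
        n_valid = int(valid.sum())
        if n_valid < 4:
            raise UnrecoverableMarkerError(
                f"marker {name}: only {n_valid} valid frames, cannot reconstruct")
        idx = np.flatnonzero(valid)
        spline = CubicSpline(idx, out.markers[name][valid], axis=0)
        skipped = []
        for start, stop in _gap_runs(valid):
            length = stop - start
            interior = start > 0 and stop < len(valid)
            if interior and length <= max_gap_frames:
                frames = np.arange(start, stop)
                out.markers[name][frames] = spline(frames)
                out.validity[name][frames] = True
            else:
                skipped.append((start, stop))
        if skipped:
            warnings.warn(
                f"marker {name}: {len(skipped)} gap(s) left unfilled "
                f"(edge gap or longer than {max_gap_frames} frames): {skipped}")
    return out


def lowpass(recording: TrialRecording, cutoff: float = DEFAULT_CUTOFF_HZ,
            order: int = DEFAULT_ORDER) -> TrialRecording:
    """Zero-lag Butterworth low-pass of every marker coordinate.

    Filtering forward then backward (``filtfilt``) doubles the effective
    order and cancels phase delay, so velocity-peak timing is preserved.
    """
    nyquist = recording.rate / 2.0
    if cutoff <= 0 or cutoff >= nyquist:
        raise ConfigError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    if order < 1:
        raise ConfigError(f"filter order must be >= 1, got {order}")
    b, a = butter(order, cutoff / nyquist)
    out = recording.copy()
    for name in MARKER_NAMES:
        if not out.validity[name].all():
            warnings.warn(f"marker {name}: filtering across unfilled gaps")
        out.markers[name] = filtfilt(b, a, out.markers[name], axis=0,
                                     method="pad")
    return out


def tangential_velocity(trajectory: np.ndarray, rate: float,
                        marker: str = "US") -> VelocitySeries:
    """Speed (norm of the 3D derivative) of a marker trajectory in m/s.

    Differentiation uses central differences in the interior and one-sided
    differences at the edges; input coordinates are millimetres.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.ndim != 2 or trajectory.shape[1] != 3:
        raise ShapeError(f"trajectory must be (n, 3), got {trajectory.shape}")
    if trajectory.shape[0] < 3:
        raise ShapeError("tangential velocity needs at least 3 frames")
    deriv = np.gradient(trajectory, 1.0 / rate, axis=0)  # mm/s
    speed = np.linalg.norm(deriv, axis=1) / 1000.0
    return VelocitySeries(values=speed, rate=rate, marker=marker)
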