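"""Reach segmentation and per-trial kinematic features.

The reaching phase is delimited on the tangential velocity of the ulnar
styloid marker: it starts when the speed rises above 5% of its peak and ends
when it falls back below that threshold.  Within that window the module
computes the study's performance parameters:

* RD — reaching duration, seconds;
* VP — peak tangential speed of the ulnar styloid, m/s;
* E_ROM / S_ROM — elbow flexion-extension and movement-specific shoulder
  angle excursions, degrees;
* MFr — movement fractionation, ``100 * (1 - E_ROM / S_ROM)``, the relative
  contribution of the shoulder over the elbow (a stiffer elbow raises MFr);
* trunk displacement — maximal excursion of the suprasternal notch from its
  position at reach start, millimetres.

Joint angles follow the ISB upper-limb convention as closely as the 8-marker
set allows (see docs/methods.md for the thorax-frame approximation), and the
movement-specific shoulder angle is the humerus elevation projected into the
thorax sagittal plane (anterior reaches) or coronal plane (lateral reach).
Angle curves are resampled onto a 101-point 0-100% grid so that waveforms can
be compared regardless of movement duration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (ConfigError, DegenerateInputError, NoMovementError,
                     ShapeError)
from .kinio import TrialRecording
from .preprocess import VelocitySeries

DEFAULT_THRESHOLD_FRAC = 0.05
NORMALIZED_SAMPLES = 101


@dataclass
class ReachSegment:
    """Frame indices delimiting one reach plus its duration and peak speed."""

    start_frame: int
    peak_frame: int
    end_frame: int
    rate: float
    boundary_snapped: bool = False

    def __post_init__(self) -> None:
        if not (self.start_frame <= self.peak_frame <= self.end_frame):
            raise ShapeError("segment must satisfy start <= peak <= end")

    @property
    def rd(self) -> float:
        """Reaching duration in seconds."""
        return (self.end_frame - self.start_frame) / self.rate

    @property
    def slice(self) -> slice:
        return slice(self.start_frame, self.end_frame + 1)


@dataclass
class JointAngleSet:
    """Elbow flexion-extension and the movement-specific shoulder angle,
    degrees, raw (per frame) and time-normalized (101 samples)."""

    elbow_fe: np.ndarray
    shoulder_angle: np.ndarray
    movement: str
    elbow_fe_norm: np.ndarray | None = None
    shoulder_angle_norm: np.ndarray | None = None


def segment_reach(velocity: VelocitySeries,
                  threshold_frac: float = DEFAULT_THRESHOLD_FRAC) -> ReachSegment:
    """Delimit the reaching phase at a fraction of the peak speed.

    The peak is the global maximum of the whole series (earliest frame on
    ties).  The start is one frame after the last sub-threshold frame before
    the peak; the end is the first sub-threshold frame after it.  When the
    series never drops below threshold at one end, that boundary snaps to the
    series edge with a warning.
    """
    v = velocity.values
    if not np.any(v > 0):
        raise NoMovementError("velocity series has no positive peak")
    if not 0 < threshold_frac < 1:
        raise ConfigError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    peak = int(np.argmax(v))
    vp = v[peak]
    thr = threshold_frac * vp
    below = v < thr
    snapped = False
    before = np.flatnonzero(below[:peak])
    if len(before):
        start = int(before[-1]) + 1
    else:
        start = 0
        snapped = True
    after = np.flatnonzero(below[peak + 1:])
    if len(after):
        end = peak + 1 + int(after[0])
    else:
        end = len(v) - 1
        snapped = True
    if snapped:
        warnings.warn("velocity never fell below threshold at a boundary; "
                      "segment snapped to the series edge")
    return ReachSegment(start_frame=start, peak_frame=peak, end_frame=end,
                        rate=velocity.rate, boundary_snapped=snapped)


def peak_velocity(velocity: VelocitySeries, segment: ReachSegment) -> float:
    """VP: tangential speed at the segment's peak frame, m/s."""
    return float(velocity.values[segment.peak_frame])


def _normalize(vec: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    if np.any(norm < 1e-9):
        raise DegenerateInputError(f"degenerate (zero-length) {what}")
    return vec / norm


def thorax_frame(ij: np.ndarray, c7: np.ndarray, t8: np.ndarray) -> np.ndarray:
    """Orthonormal right-handed thorax frame from the three torso markers.

    Columns are the axes expressed in laboratory coordinates: X anterior,
    Y up (along the C7-T8 spine line), Z to the subject's right.  Origin is
    taken at the suprasternal notch (IJ); only the rotation is returned.
    Without a xiphoid marker the strict ISB thorax frame cannot be built; the
    spine line stands in for the vertical axis.
    """
    ij, c7, t8 = (np.asarray(p, dtype=float) for p in (ij, c7, t8))
    y = _normalize(c7 - t8, "spine axis (C7-T8)")
    anterior = ij - (c7 + t8) / 2.0
    anterior = anterior - np.dot(anterior, y) * y
    if np.linalg.norm(anterior) < 1e-9:
        raise DegenerateInputError("torso markers are collinear")
    x = _normalize(anterior, "anterior axis")
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def joint_angles(recording: TrialRecording, movement: str | None = None,
                 handedness: str | None = None) -> JointAngleSet:
    """Per-frame elbow flexion-extension and movement-specific shoulder angle.

    Elbow flexion-extension is 180 deg minus the angle at the epicondyle
    midpoint between the upper-arm and forearm segments, so a fully extended
    arm reads 0 deg and a right angle reads 90 deg.  The shoulder angle is the
    elevation of the humerus axis (acromion to epicondyle midpoint) from the
    vertical-down reference, projected into the thorax sagittal plane for the
    anterior movements or the coronal plane for the lateral movement.
    Left-handed recordings are mirrored across the sagittal plane first so
    that lateral always means the reaching side.
    """
    movement = movement or recording.movement
    handedness = handedness or recording.handedness
    markers = {k: v.copy() for k, v in recording.markers.items()}
    if handedness == "left":
        # mirror across the laboratory sagittal (XY) plane
        for arr in markers.values():
            arr[:, 2] = -arr[:, 2]

    shoulder = markers["ACR"]
    epi_mid = (markers["LE"] + markers["ME"]) / 2.0
    styl_mid = (markers["RS"] + markers["US"]) / 2.0

    upper = _normalize(epi_mid - shoulder, "upper-arm segment")
    fore = _normalize(styl_mid - epi_mid, "forearm segment")
    cos_int = np.clip(np.einsum("ij,ij->i", -upper, fore), -1.0, 1.0)
    elbow_fe = 180.0 - np.degrees(np.arccos(cos_int))

    n = recording.n_frames
    humerus_t = np.empty((n, 3))
    for i in range(n):
        rot = thorax_frame(markers["IJ"][i], markers["C7"][i], markers["T8"][i])
        humerus_t[i] = rot.T @ upper[i]
    if movement in ("A-Low", "A-High"):
        # sagittal plane: anterior (x) vs vertical (y) components
        shoulder_angle = np.degrees(np.arctan2(humerus_t[:, 0], -humerus_t[:, 1]))
    elif movement == "L-Low":
        # coronal plane: lateral (z, toward reaching side) vs vertical
        shoulder_angle = np.degrees(np.arctan2(humerus_t[:, 2], -humerus_t[:, 1]))
    else:
        raise ConfigError(f"unknown movement {movement!r}")
    return JointAngleSet(elbow_fe=elbow_fe, shoulder_angle=shoulder_angle,
                         movement=movement)


def rom(angle_series: np.ndarray, segment: ReachSegment) -> float:
    """Range of motion: max minus min of the angle over the reach window."""
    angle_series = np.asarray(angle_series, dtype=float)
    if segment.end_frame >= len(angle_series):
        raise ShapeError("segment extends beyond the angle series")
    window = angle_series[segment.slice]
    if window.size == 0:
        raise ShapeError("empty segment window")
    return float(window.max() - window.min())


def movement_fractionation(e_rom: float, s_rom: float) -> float:
    """MFr = 100 * (1 - E_ROM / S_ROM), percent.

    Rises when the elbow excursion shrinks relative to the shoulder's; may be
    negative when the elbow moves more than the shoulder.
    """
    if s_rom <= 0:
        raise DegenerateInputError(
            f"MFr undefined for non-positive shoulder ROM ({s_rom})")
    return 100.0 * (1.0 - e_rom / s_rom)


def trunk_displacement(recording: TrialRecording, segment: ReachSegment) -> float:
    """Maximal excursion (mm) of the suprasternal notch from its position at
    reach start — a check against compensatory trunk strategies."""
    valid = recording.validity["IJ"][segment.slice]
    if not valid.all():
        raise DegenerateInputError("IJ marker has masked frames inside the reach")
    ij = recording.markers["IJ"][segment.slice]
    return float(np.linalg.norm(ij - ij[0], axis=1).max())


def time_normalize(angle_series: np.ndarray, segment: ReachSegment,
                   n: int = NORMALIZED_SAMPLES) -> np.ndarray:
    """Resample the reach window onto ``n`` evenly spaced points (0-100% time)
    by linear interpolation; endpoints match the boundary samples exactly."""
    if n < 2:
        raise ConfigError(f"normalized grid needs at least 2 points, got {n}")
    angle_series = np.asarray(angle_series, dtype=float)
    window = angle_series[segment.slice]
    if window.size < 2:
        raise ShapeError("segment must span at least 2 frames")
    src = np.linspace(0.0, 1.0, window.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, window)
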