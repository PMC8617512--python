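"""Synthetic motion-capture generator for the immobilization experiment.

A two-link arm (upper arm + forearm) attached to a fixed thorax performs the
three reach-to-grasp movements of the study design: two anterior reaches in
the sagittal plane (A-Low at shoulder height, A-High at head height) and one
lateral reach in the coronal plane (L-Low).  Shoulder elevation and elbow
extension both follow minimum-jerk (quintic) profiles, giving the
single-peaked, bell-shaped wrist tangential velocity that the segmentation
stage assumes.

The generator emulates a two-group (AOT vs CTRL) short-term-immobilization
cohort: each subject is measured PRE (baseline, 3 movements x 10 trials) and
POST.  Immobilization effects are injected on POST trials only —

* the elbow range of motion shrinks by a group-dependent fraction,
* the reach duration inflates by a group-dependent amount (peak wrist
  velocity drops accordingly),
* the shoulder range is left untouched (immobilization constrains the elbow
  far more than the shoulder),

and all effects decay across the ten post trials along a clamped logarithmic
recovery curve calibrated so that trial 4 expresses 50% and trial 9 expresses
95% of the recovery.  Marker coordinates receive isotropic Gaussian noise at
the optoelectronic system's spatial resolution, and short dropout runs are
masked to exercise gap reconstruction.

Identical seeds produce bit-identical cohorts; every trial draws from its own
seed stream keyed by (seed, subject, phase, movement, trial), so generation
order does not matter.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ShapeError
from .kinio import (GROUPS, MANIFEST_COLUMNS, MOVEMENTS, PHASES,
                    CohortDataset, TrialRecording)

# Recovery-curve coefficients solving  a + b ln 4 = 0.50,  a + b ln 9 = 0.95
RECOVERY_B_DEFAULT = 0.45 / math.log(9.0 / 4.0)      # ~0.5549
RECOVERY_A_DEFAULT = 0.5 - RECOVERY_B_DEFAULT * math.log(4.0)   # ~-0.2694

#: Per-movement start angles (deg) and range scales relative to the config
#: base ROMs; the lateral reach runs in the coronal plane.
MOVEMENT_PROFILES = {
    "A-Low": dict(plane="sagittal", shoulder_start=5.0, elbow_start=85.0,
                  shoulder_scale=1.00, elbow_scale=1.00),
    "A-High": dict(plane="sagittal", shoulder_start=5.0, elbow_start=90.0,
                   shoulder_scale=1.15, elbow_scale=0.95),
    "L-Low": dict(plane="coronal", shoulder_start=5.0, elbow_start=80.0,
                  shoulder_scale=0.95, elbow_scale=0.90),
}

_SHOULDER_POS = np.array([0.0, 1400.0, 180.0])   # mm, lab frame, right side
_IJ_POS = np.array([30.0, 1380.0, 0.0])
_C7_POS = np.array([-30.0, 1400.0, 0.0])
_T8_POS = np.array([-30.0, 1250.0, 0.0])
_EPI_HALF_WIDTH = 35.0   # mm between epicondyle markers and elbow center
_STYL_HALF_WIDTH = 25.0  # mm between styloid markers and wrist center
_REST_PAD_S = 0.25       # stationary hold before and after the reach


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters (units in field names/docs)."""

    n_per_group: int = 20
    rate: float = 120.0                  # Hz
    upper_arm_len: float = 0.30          # m
    forearm_len: float = 0.26            # m
    base_duration: float = 1.0           # s, pre-immobilization reach
    base_elbow_rom: float = 60.0         # deg
    base_shoulder_rom: float = 70.0      # deg
    ctrl_rom_shrink: float = 0.25        # fraction of elbow ROM lost at T1
    aot_rom_shrink: float = 0.10
    ctrl_rd_inflate: float = 0.30        # s added to duration at T1
    aot_rd_inflate: float = 0.20
    recovery_a: float = RECOVERY_A_DEFAULT
    recovery_b: float = RECOVERY_B_DEFAULT
    noise_sd: float = 0.3                # mm, isotropic marker noise
    gap_rate: float = 0.01               # fraction of frames masked
    between_subject_sd: float = 0.05     # log-sd of subject multipliers
    trial_jitter_sd: float = 0.05        # log-sd of per-trial multipliers
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ("rate", "upper_arm_len", "forearm_len", "base_duration",
                    "base_elbow_rom", "base_shoulder_rom")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("ctrl_rom_shrink", "aot_rom_shrink"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigError(f"{name} must lie in [0, 1)")
        for name in ("ctrl_rd_inflate", "aot_rd_inflate", "noise_sd",
                     "between_subject_sd", "trial_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0 <= self.gap_rate <= 0.2:
            raise ConfigError("gap_rate must lie in [0, 0.2]")
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be at least 1")

    def null(self) -> "SimConfig":
        """A copy with every immobilization effect switched off (both groups
        draw from the same distribution) — for type-I-error studies."""
        return replace(self, ctrl_rom_shrink=0.0, aot_rom_shrink=0.0,
                       ctrl_rd_inflate=0.0, aot_rd_inflate=0.0)

    def rom_shrink(self, group: str) -> float:
        return {"CTRL": self.ctrl_rom_shrink, "AOT": self.aot_rom_shrink}[group]

    def rd_inflate(self, group: str) -> float:
        return {"CTRL": self.ctrl_rd_inflate, "AOT": self.aot_rd_inflate}[group]


@dataclass(frozen=True)
class SubjectProfile:
    """One simulated participant: anthropometry plus random multipliers."""

    subject_id: str
    group: str
    handedness: str = "right"
    upper_arm_len: float = 0.30   # m
    forearm_len: float = 0.26     # m
    multipliers: dict = field(default_factory=lambda: {
        "elbow_rom": 1.0, "shoulder_rom": 1.0, "duration": 1.0})

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"unknown group {self.group!r}")
        if self.handedness not in ("right", "left"):
            raise ConfigError(f"unknown handedness {self.handedness!r}")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ConfigError("subject multipliers must be positive")


@dataclass(frozen=True)
class EffectSchedule:
    """Injected effect sizes for one (group, phase, trial) cell."""

    trial_index: int
    recovery: float          # fraction of recovery expressed, [0, 1]
    rom_multiplier: float    # elbow ROM scale, (0, 1]
    duration: float          # effective reach duration, s
    velocity_scale: float    # expected peak-velocity scale, (0, 1]


def recovery_fraction(j: int, a: float = RECOVERY_A_DEFAULT,
                      b: float = RECOVERY_B_DEFAULT) -> float:
    """Fraction of recovery expressed at post trial ``j``.

    Functional recovery is modeled as a clamped logarithmic curve
    ``clamp(a + b ln j, 0, 1)``; the default coefficients anchor trial 4 at
    50% and trial 9 at 95% recovery.
    """
    if j < 1:
        raise ConfigError(f"trial index must be >= 1, got {j}")
    return float(min(1.0, max(0.0, a + b * math.log(j))))


def effect_schedule(config: SimConfig, group: str, phase: str,
                    j: int) -> EffectSchedule:
    """Effective elbow-ROM multiplier and duration for one trial."""
    if phase not in PHASES:
        raise ConfigError(f"unknown phase {phase!r}")
    if group not in GROUPS:
        raise ConfigError(f"unknown group {group!r}")
    if phase == "PRE":
        return EffectSchedule(trial_index=j, recovery=1.0, rom_multiplier=1.0,
                              duration=config.base_duration, velocity_scale=1.0)
    r = recovery_fraction(j, config.recovery_a, config.recovery_b)
    rom_mult = 1.0 - config.rom_shrink(group) * (1.0 - r)
    duration = config.base_duration + config.rd_inflate(group) * (1.0 - r)
    return EffectSchedule(trial_index=j, recovery=r, rom_multiplier=rom_mult,
                          duration=duration,
                          velocity_scale=config.base_duration / duration)


def minimum_jerk_profile(theta_start: float, theta_end: float,
                         duration: float, rate: float) -> np.ndarray:
    """Quintic point-to-point angle profile (deg) sampled at ``rate``.

    theta(tau) = start + (end - start) * (10 tau^3 - 15 tau^4 + 6 tau^5);
    endpoints are exact and the angular speed is bell-shaped with a single
    interior peak at tau = 0.5.
    """
    if duration <= 0 or rate <= 0:
        raise ConfigError("duration and rate must be positive")
    n = int(round(duration * rate)) + 1
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return theta_start + (theta_end - theta_start) * s


def _arm_points(shoulder_deg: np.ndarray, elbow_deg: np.ndarray, plane: str,
                upper_mm: float, fore_mm: float):
    """Elbow-center and wrist-center trajectories (mm, lab frame, right arm)."""
    phi = np.radians(np.asarray(shoulder_deg, dtype=float))
    eps = np.radians(np.asarray(elbow_deg, dtype=float))
    if plane == "sagittal":
        h = np.column_stack([np.sin(phi), -np.cos(phi), np.zeros_like(phi)])
        # elbow flexion rotates the forearm about the lab Z axis
        cos_e, sin_e = np.cos(eps), np.sin(eps)
        f = np.column_stack([cos_e * h[:, 0] - sin_e * h[:, 1],
                             sin_e * h[:, 0] + cos_e * h[:, 1],
                             np.zeros_like(phi)])
        axis = np.array([0.0, 0.0, 1.0])
    elif plane == "coronal":
        h = np.column_stack([np.zeros_like(phi), -np.cos(phi), np.sin(phi)])
        # flexion about the -X axis lifts the forearm laterally
        cos_e, sin_e = np.cos(eps), np.sin(eps)
        f = np.column_stack([np.zeros_like(phi),
                             cos_e * h[:, 1] + sin_e * h[:, 2],
                             -sin_e * h[:, 1] + cos_e * h[:, 2]])
        axis = np.array([-1.0, 0.0, 0.0])
    else:
        raise ConfigError(f"unknown movement plane {plane!r}")
    elbow_center = _SHOULDER_POS + upper_mm * h
    wrist_center = elbow_center + fore_mm * f
    return elbow_center, wrist_center, axis


def forward_kinematics(profile: SubjectProfile, shoulder_series: np.ndarray,
                       elbow_series: np.ndarray, movement: str,
                       rate: float = 120.0) -> TrialRecording:
    """Place the 8 canonical markers for given joint-angle series.

    The thorax is fixed; the epicondyle midpoint lies at ``upper_arm_len``
    from the shoulder center (the acromion marker) and the styloid midpoint
    at ``forearm_len`` from the epicondyle midpoint.  Epicondyle and styloid
    marker pairs straddle their midpoints along the elbow flexion axis.
    Left-handed profiles are mirrored across the sagittal plane.
    """
    shoulder_series = np.asarray(shoulder_series, dtype=float)
    elbow_series = np.asarray(elbow_series, dtype=float)
    if shoulder_series.shape != elbow_series.shape or shoulder_series.ndim != 1:
        raise ShapeError("shoulder and elbow series must be equal-length 1-D")
    if np.any((shoulder_series < 0) | (shoulder_series > 180)):
        raise ConfigError("shoulder angle outside anatomical range [0, 180]")
    if np.any((elbow_series < 0) | (elbow_series > 160)):
        raise ConfigError("elbow angle outside anatomical range [0, 160]")
    if movement not in MOVEMENT_PROFILES:
        raise ConfigError(f"unknown movement {movement!r}")
    plane = MOVEMENT_PROFILES[movement]["plane"]
    elbow_c, wrist_c, axis = _arm_points(
        shoulder_series, elbow_series, plane,
        profile.upper_arm_len * 1000.0, profile.forearm_len * 1000.0)
    n = len(shoulder_series)
    markers = {
        "IJ": np.tile(_IJ_POS, (n, 1)),
        "C7": np.tile(_C7_POS, (n, 1)),
        "T8": np.tile(_T8_POS, (n, 1)),
        "ACR": np.tile(_SHOULDER_POS, (n, 1)),
        "LE": elbow_c + _EPI_HALF_WIDTH * axis,
        "ME": elbow_c - _EPI_HALF_WIDTH * axis,
        "RS": wrist_c + _STYL_HALF_WIDTH * axis,
        "US": wrist_c - _STYL_HALF_WIDTH * axis,
    }
    if profile.handedness == "left":
        for arr in markers.values():
            arr[:, 2] = -arr[:, 2]
    return TrialRecording(
        subject_id=profile.subject_id, group=profile.group,
        handedness=profile.handedness, phase="PRE", movement=movement,
        trial_index=1, rate=rate, markers=markers,
    )


def _trial_rng(config: SimConfig, subject_index: int, phase: str,
               movement: str, j: int) -> np.random.Generator:
    key = (int(config.seed) % (2**31), subject_index, PHASES.index(phase),
           MOVEMENTS.index(movement), j)
    return np.random.default_rng(np.random.SeedSequence(key))


def trial_parameters(config: SimConfig, profile: SubjectProfile, phase: str,
                     movement: str, j: int, rng: np.random.Generator | None
                     ) -> dict:
    """Noise-free kinematic parameters for one trial (plus trial jitter when
    an RNG is given).  This is the generator's ground truth."""
    if movement not in MOVEMENT_PROFILES:
        raise ConfigError(f"unknown movement {movement!r}")
    mov = MOVEMENT_PROFILES[movement]
    sched = effect_schedule(config, profile.group, phase, j)
    jit = (lambda: 1.0) if rng is None else (
        lambda: float(np.exp(rng.normal(0.0, config.trial_jitter_sd))))
    elbow_rom = (config.base_elbow_rom * mov["elbow_scale"]
                 * profile.multipliers["elbow_rom"] * sched.rom_multiplier
                 * jit())
    shoulder_rom = (config.base_shoulder_rom * mov["shoulder_scale"]
                    * profile.multipliers["shoulder_rom"] * jit())
    duration = (sched.duration * profile.multipliers["duration"] * jit())
    return dict(
        movement=movement, phase=phase, trial_index=j,
        shoulder_start=mov["shoulder_start"],
        shoulder_end=mov["shoulder_start"] + shoulder_rom,
        elbow_start=mov["elbow_start"],
        elbow_end=mov["elbow_start"] - elbow_rom,
        elbow_rom=elbow_rom, shoulder_rom=shoulder_rom, duration=duration,
        rom_multiplier=sched.rom_multiplier, recovery=sched.recovery,
    )


def synthesize_trial(config: SimConfig, profile: SubjectProfile, phase: str,
                     movement: str, j: int, subject_index: int = 0,
                     jitter: bool = True) -> TrialRecording:
    """One simulated trial: min-jerk joint motion with a stationary hold on
    both sides, marker noise, and masked dropout runs."""
    rng = _trial_rng(config, subject_index, phase, movement, j)
    params = trial_parameters(config, profile, phase, movement, j,
                              rng if jitter else None)
    shoulder = minimum_jerk_profile(params["shoulder_start"],
                                    params["shoulder_end"],
                                    params["duration"], config.rate)
    elbow = minimum_jerk_profile(params["elbow_start"], params["elbow_end"],
                                 params["duration"], config.rate)
    pad = int(round(_REST_PAD_S * config.rate))
    shoulder = np.concatenate([np.full(pad, shoulder[0]), shoulder,
                               np.full(pad, shoulder[-1])])
    elbow = np.concatenate([np.full(pad, elbow[0]), elbow,
                            np.full(pad, elbow[-1])])
    rec = forward_kinematics(profile, shoulder, elbow, movement,
                             rate=config.rate)
    rec.phase = phase
    rec.trial_index = j
    n = rec.n_frames
    if config.noise_sd > 0:
        for name in rec.markers:
            rec.markers[name] = rec.markers[name] + rng.normal(
                0.0, config.noise_sd, size=(n, 3))
    if config.gap_rate > 0:
        # short interior dropout runs (always reconstructable downstream)
        for name in rec.markers:
            target = config.gap_rate * n
            masked = 0
            while masked < target:
                length = int(rng.integers(1, 7))
                start = int(rng.integers(1, max(2, n - length - 1)))
                rec.validity[name][start:start + length] = False
                masked += length
    return rec


def sample_subjects(config: SimConfig) -> list[SubjectProfile]:
    """Draw the cohort: ``n_per_group`` subjects per group, right-handed with
    probability 37/40, lognormal between-subject multipliers."""
    rng = np.random.default_rng(
        np.random.SeedSequence((int(config.seed) % (2**31), 999_983)))
    profiles = []
    for g, group in enumerate(GROUPS):
        for i in range(config.n_per_group):
            sid = f"S{g * config.n_per_group + i + 1:03d}"
            handed = "right" if rng.random() < 37.0 / 40.0 else "left"
            mults = {k: float(np.exp(rng.normal(0.0, config.between_subject_sd)))
                     for k in ("elbow_rom", "shoulder_rom", "duration")}
            length_mult = float(np.exp(rng.normal(0.0, 0.03)))
            profiles.append(SubjectProfile(
                subject_id=sid, group=group, handedness=handed,
                upper_arm_len=config.upper_arm_len * length_mult,
                forearm_len=config.forearm_len * length_mult,
                multipliers=mults))
    return profiles


def generate_cohort(config: SimConfig, trials_per_movement: int = 10
                    ) -> CohortDataset:
    """The full two-group cohort: every subject performs 3 movements x
    ``trials_per_movement`` trials in each phase.  Deterministic under a
    fixed seed."""
    profiles = sample_subjects(config)
    recordings = []
    rows = []
    for idx, prof in enumerate(profiles):
        for phase in PHASES:
            for movement in MOVEMENTS:
                for j in range(1, trials_per_movement + 1):
                    rec = synthesize_trial(config, prof, phase, movement, j,
                                           subject_index=idx)
                    recordings.append(rec)
                    rows.append(dict(subject_id=prof.subject_id,
                                     group=prof.group,
                                     handedness=prof.handedness, phase=phase,
                                     movement=movement, trial_index=j,
                                     file=""))
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    return CohortDataset(recordings=recordings, manifest=manifest)


def ground_truth_table(config: SimConfig, trials_per_movement: int = 10
                       ) -> pd.DataFrame:
    """Injected (noise-free, jitter-free) effect parameters per cohort cell —
    the reference for parameter-recovery tests."""
    rows = []
    for group in GROUPS:
        for phase in PHASES:
            for movement in MOVEMENTS:
                for j in range(1, trials_per_movement + 1):
                    sched = effect_schedule(config, group, phase, j)
                    mov = MOVEMENT_PROFILES[movement]
                    rows.append(dict(
                        group=group, phase=phase, movement=movement,
                        trial_index=j, recovery=sched.recovery,
                        rom_multiplier=sched.rom_multiplier,
                        duration=sched.duration,
                        elbow_rom=config.base_elbow_rom * mov["elbow_scale"]
                        * sched.rom_multiplier,
                        shoulder_rom=config.base_shoulder_rom
                        * mov["shoulder_scale"]))
    return pd.DataFrame(rows)


def reach_truncation_fraction(config: SimConfig, profile: SubjectProfile,
                              movement: str, phase: str = "PRE", j: int = 1,
                              threshold_frac: float = 0.05,
                              n: int = 20001) -> float:
    """Fraction of the commanded movement time between the threshold
    crossings of the noise-free wrist speed, evaluated on a dense time grid
    from the continuous geometry (independent of the sampled pipeline).

    Because the hand-path Jacobian varies along the reach, this differs
    slightly from the pure minimum-jerk constant 0.8812.
    """
    params = trial_parameters(config, profile, phase, movement, j, None)
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    shoulder = params["shoulder_start"] + (
        params["shoulder_end"] - params["shoulder_start"]) * s
    elbow = params["elbow_start"] + (
        params["elbow_end"] - params["elbow_start"]) * s
    plane = MOVEMENT_PROFILES[movement]["plane"]
    _, wrist, _ = _arm_points(shoulder, elbow, plane,
                              profile.upper_arm_len * 1000.0,
                              profile.forearm_len * 1000.0)
    dt = params["duration"] / (n - 1)
    speed = np.linalg.norm(np.gradient(wrist, dt, axis=0), axis=1)
    peak = int(np.argmax(speed))
    thr = threshold_frac * speed[peak]
    below = speed < thr
    before = np.flatnonzero(below[:peak])
    start = int(before[-1]) + 1 if len(before) else 0
    after = np.flatnonzero(below[peak + 1:])
    end = peak + 1 + int(after[0]) if len(after) else n - 1
    return (end - start) / (n - 1)


# ---------------------------------------------------------------------------
# Reduced (analytic) feature simulator for statistical studies
# ---------------------------------------------------------------------------

_VP_BASE = {"A-Low": 1.30, "A-High": 1.45, "L-Low": 1.20}  # m/s, baseline


def simulate_feature_table(config: SimConfig,
                           trials_per_movement: int = 10) -> pd.DataFrame:
    """Per-trial features drawn directly from the effect schedule plus
    multiplicative measurement/execution noise, bypassing marker synthesis.

    This is the fast path for large simulation studies (type-I error, power):
    the deterministic part of each feature equals what the full marker
    pipeline recovers from noise-free trials, and trial-to-trial variability
    enters as additive Gaussian measurement error with relative scale
    ``trial_jitter_sd`` (for MFr, the delta-method propagation of the
    elbow/shoulder ROM errors).  Columns: subject, group, movement, phase,
    trial_index, RD, VP, E_ROM, S_ROM, MFr, AM_Elb, AM_Sho (AM only for POST
    trials; NaN on PRE rows).
    """
    profiles = sample_subjects(config)
    rng = np.random.default_rng(
        np.random.SeedSequence((int(config.seed) % (2**31), 424_243)))
    sd = config.trial_jitter_sd
    n_subj = len(profiles)
    n_j = trials_per_movement
    shape = (n_subj, len(PHASES), len(MOVEMENTS), n_j)

    mult_e = np.array([p.multipliers["elbow_rom"] for p in profiles])
    mult_s = np.array([p.multipliers["shoulder_rom"] for p in profiles])
    mult_d = np.array([p.multipliers["duration"] for p in profiles])
    el_scale = np.array([MOVEMENT_PROFILES[m]["elbow_scale"]
                         for m in MOVEMENTS])
    sh_scale = np.array([MOVEMENT_PROFILES[m]["shoulder_scale"]
                         for m in MOVEMENTS])
    vp_base = np.array([_VP_BASE[m] for m in MOVEMENTS])

    rom_mult = np.ones((n_subj, len(PHASES), n_j))
    duration = np.full((n_subj, len(PHASES), n_j), config.base_duration)
    for s_i, prof in enumerate(profiles):
        for p_i, phase in enumerate(PHASES):
            for j in range(1, n_j + 1):
                sched = effect_schedule(config, prof.group, phase, j)
                rom_mult[s_i, p_i, j - 1] = sched.rom_multiplier
                duration[s_i, p_i, j - 1] = sched.duration

    def gauss():
        return rng.normal(0.0, 1.0, size=shape)

    e_mu = (config.base_elbow_rom * el_scale[None, None, :, None]
            * mult_e[:, None, None, None] * rom_mult[:, :, None, :]
            * np.ones(shape))
    s_mu = (config.base_shoulder_rom * sh_scale[None, None, :, None]
            * mult_s[:, None, None, None] * np.ones(shape))
    rd_mu = (duration[:, :, None, :] * mult_d[:, None, None, None]
             * np.ones(shape))
    vp_mu = (vp_base[None, None, :, None]
             * (config.base_duration / duration)[:, :, None, :]
             / mult_d[:, None, None, None] * np.ones(shape))
    e = e_mu * (1.0 + sd * gauss())
    s = s_mu * (1.0 + sd * gauss())
    rd = rd_mu * (1.0 + sd * gauss())
    vp = vp_mu * (1.0 + sd * gauss())
    mfr_mu = 100.0 * (1.0 - e_mu / s_mu)
    mfr = mfr_mu + 100.0 * (e_mu / s_mu) * np.sqrt(2.0) * sd * gauss()
    am_elb = rom_mult[:, :, None, :] + sd * gauss()
    am_sho = 1.0 + sd * gauss()
    pre = PHASES.index("PRE")
    am_elb[:, pre] = np.nan
    am_sho[:, pre] = np.nan

    index = pd.MultiIndex.from_product(
        [[p.subject_id for p in profiles], list(PHASES), list(MOVEMENTS),
         range(1, n_j + 1)],
        names=["subject", "phase", "movement", "trial_index"])
    out = pd.DataFrame(
        dict(RD=rd.ravel(), VP=vp.ravel(), E_ROM=e.ravel(), S_ROM=s.ravel(),
             MFr=mfr.ravel(),
             AM_Elb=am_elb.ravel(), AM_Sho=am_sho.ravel()),
        index=index).reset_index()
    group_of = {p.subject_id: p.group for p in profiles}
    out.insert(1, "group", out["subject"].map(group_of))
    return out
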