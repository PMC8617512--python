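"""End-to-end per-trial processing: preprocess -> features -> LFM.

Takes a :class:`~reachkin.kinio.CohortDataset` (simulated or loaded from
disk) through gap filling, low-pass filtering, reach segmentation, joint
angles and per-trial features, then runs the linear fit method of every
post-immobilization normalized curve against the subject's averaged
pre-immobilization curve.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinfeatures, lfm, preprocess
from .errors import ReachKinError
from .kinio import CohortDataset, TrialRecording


@dataclass
class ProcessConfig:
    """Parameters of the measurement pipeline."""

    cutoff_hz: float = preprocess.DEFAULT_CUTOFF_HZ
    filter_order: int = preprocess.DEFAULT_ORDER
    max_gap_frames: int = preprocess.DEFAULT_MAX_GAP_FRAMES
    threshold_frac: float = kinfeatures.DEFAULT_THRESHOLD_FRAC
    n_normalized: int = kinfeatures.NORMALIZED_SAMPLES
    lowpass_enabled: bool = True


@dataclass
class TrialResult:
    """Features and normalized angle curves of one processed trial."""

    features: dict
    elbow_curve: np.ndarray
    shoulder_curve: np.ndarray
    qc: dict = field(default_factory=dict)


def process_trial(recording: TrialRecording,
                  config: ProcessConfig | None = None) -> TrialResult:
    """Run the full measurement chain on one recording."""
    config = config or ProcessConfig()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rec = preprocess.fill_gaps(recording, config.max_gap_frames)
        if config.lowpass_enabled:
            rec = preprocess.lowpass(rec, config.cutoff_hz, config.filter_order)
        velocity = preprocess.tangential_velocity(rec.markers["US"], rec.rate)
        segment = kinfeatures.segment_reach(velocity, config.threshold_frac)
        angles = kinfeatures.joint_angles(rec)
        e_rom = kinfeatures.rom(angles.elbow_fe, segment)
        s_rom = kinfeatures.rom(angles.shoulder_angle, segment)
        mfr = kinfeatures.movement_fractionation(e_rom, s_rom)
        trunk = kinfeatures.trunk_displacement(rec, segment)
        elbow_curve = kinfeatures.time_normalize(angles.elbow_fe, segment,
                                                 config.n_normalized)
        shoulder_curve = kinfeatures.time_normalize(
            angles.shoulder_angle, segment, config.n_normalized)
    features = dict(
        subject=rec.subject_id, group=rec.group, handedness=rec.handedness,
        phase=rec.phase, movement=rec.movement, trial_index=rec.trial_index,
        RD=segment.rd, VP=kinfeatures.peak_velocity(velocity, segment),
        E_ROM=e_rom, S_ROM=s_rom, MFr=mfr, trunk_disp=trunk,
        qc_snapped=segment.boundary_snapped,
        qc_warnings=len(caught),
    )
    return TrialResult(features=features, elbow_curve=elbow_curve,
                       shoulder_curve=shoulder_curve,
                       qc=dict(warnings=[str(w.message) for w in caught]))


def process_cohort(dataset: CohortDataset,
                   config: ProcessConfig | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Process every trial of a cohort.

    Returns ``(features, lfm_table, qc_log)``:

    * ``features`` — one row per trial with RD, VP, E_ROM, S_ROM, MFr,
      trunk displacement and QC flags;
    * ``lfm_table`` — one row per POST trial and joint with AM, R2, AOff
      against the subject's averaged PRE curve for the same movement;
    * ``qc_log`` — per-trial warnings and failures (failed trials are
      excluded from the other tables).
    """
    config = config or ProcessConfig()
    feature_rows: list[dict] = []
    qc_rows: list[dict] = []
    curves: dict[tuple, TrialResult] = {}
    for rec in dataset:
        key = rec.key
        try:
            result = process_trial(rec, config)
        except ReachKinError as exc:
            qc_rows.append(dict(subject=rec.subject_id, phase=rec.phase,
                                movement=rec.movement,
                                trial_index=rec.trial_index,
                                status="failed", detail=str(exc)))
            continue
        curves[key] = result
        feature_rows.append(result.features)
        qc_rows.append(dict(subject=rec.subject_id, phase=rec.phase,
                            movement=rec.movement, trial_index=rec.trial_index,
                            status="ok",
                            detail="; ".join(result.qc["warnings"])))
    features = pd.DataFrame(feature_rows)

    lfm_rows: list[dict] = []
    if len(features):
        post = features[features["phase"] == "POST"]
        for (subj, movement), sub in post.groupby(["subject", "movement"],
                                                  sort=True):
            pre_keys = [k for k in curves
                        if k[0] == subj and k[1] == "PRE" and k[2] == movement]
            if not pre_keys:
                continue
            ref_elbow = lfm.baseline_curve(
                [curves[k].elbow_curve for k in pre_keys])
            ref_shoulder = lfm.baseline_curve(
                [curves[k].shoulder_curve for k in pre_keys])
            for rec_row in sub.to_dict("records"):
                key = (subj, "POST", movement, rec_row["trial_index"])
                result = curves[key]
                for joint, ref, test in (
                        ("elbow", ref_elbow, result.elbow_curve),
                        ("shoulder", ref_shoulder, result.shoulder_curve)):
                    fit = lfm.lfm_compare(ref, test, joint=joint,
                                          trial_index=rec_row["trial_index"])
                    lfm_rows.append(dict(
                        subject=subj, group=rec_row["group"],
                        movement=movement, joint=joint,
                        trial_index=rec_row["trial_index"],
                        AM=fit.am, R2=fit.r2, AOff=fit.aoff))
    lfm_table = pd.DataFrame(lfm_rows, columns=["subject", "group", "movement",
                                                "joint", "trial_index",
                                                "AM", "R2", "AOff"])
    return features, lfm_table, pd.DataFrame(qc_rows)
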