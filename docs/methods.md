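# Methods

`reachkin` implements a complete upper-limb reach-to-grasp kinematic
analysis for a two-group (action-observation treatment, AOT, vs control)
short-term-immobilization design, together with a synthetic motion-capture
generator that makes every stage verifiable by parameter recovery.  This
note documents the models, the defaults and why, the numerical choices, and
what the synthetic data do and do not show about real recordings.

## Measurement model

**Marker set and coordinates.**  Eight markers: suprasternal notch (IJ),
C7, T8, acromion (ACR), lateral/medial humeral epicondyles (LE/ME),
radial/ulnar styloids (RS/US).  All modules assume ISB-style laboratory
axes — X anterior, Y vertical (up), Z to the subject's right — with
coordinates in millimetres at 120 Hz.

**Preprocessing.**  Interior dropouts up to `max_gap_frames` (default 12
frames, 0.1 s) are reconstructed by per-coordinate cubic splines over valid
samples; longer and edge gaps stay masked and are reported.  Positions are
smoothed with a zero-lag (forward-backward) Butterworth low-pass, default
4th order at 6 Hz — the conventional choice for reach kinematics; the
original study does not publish its filter parameters, so these are exposed
in the configuration and are the main expected source of discrepancy when
reprocessing real recordings.  Velocity is obtained by finite differences
on the filtered positions (central interior, one-sided edges) rather than
spline derivatives, for determinism and simplicity.

**Reach segmentation.**  The reaching phase is delimited on the tangential
velocity of the ulnar styloid: peak = global maximum (earliest frame on
ties); start = one frame after the last sub-threshold frame before the
peak; end = first sub-threshold frame after it; threshold = 5% of the peak.
If the series never falls below threshold at an end, the boundary snaps to
the series edge and the trial is QC-flagged.  Closed forms for reference
profiles: a half-sine speed bell keeps 96.82% of its duration between the
5% crossings, a minimum-jerk speed bell 88.12%.

**Features.**  RD = (end − start)/rate; VP = speed at the peak frame;
E_ROM / S_ROM = max − min of the joint angle inside the reach window;
MFr = 100·(1 − E_ROM/S_ROM) (%), which rises when the elbow contribution
shrinks relative to the shoulder and may be negative when the elbow moves
more; trunk control = maximal excursion of IJ from its position at reach
start.  MFr is computed per trial (not from trial-averaged ROMs), matching
the trial-wise statistical design; S_ROM ≤ 0 flags the trial as undefined.

**Joint angles.**  Elbow flexion–extension is 180° minus the interior angle
at the epicondyle midpoint between the upper-arm (ACR→epicondyle midpoint)
and forearm (epicondyle→styloid midpoint) segments: full extension reads
0°, a right angle 90°.  The movement-specific shoulder angle is the
elevation of the humerus axis from vertical-down, projected into the thorax
sagittal plane (A-Low/A-High) or coronal plane (L-Low).  Deviations from
strict ISB, forced by the 8-marker set: (i) the thorax frame has no xiphoid
marker, so the vertical axis is the C7–T8 spine line with the anterior axis
from IJ; (ii) the shoulder centre is proxied by the acromion marker (no
glenohumeral regression is possible with one scapular marker); (iii) planar
projections replace the full Y-X-Y Euler sequence, because exactly one
planar angle per movement is analysed and projections are robust near the
gimbal region.  Left-handed recordings are mirrored across the sagittal
plane before angle extraction.

**Waveform similarity (linear fit method).**  Angle curves are resampled to
101 points (0–100% of the reach) by linear interpolation, making patterns
comparable regardless of duration.  Each post-immobilization curve is
regressed on the subject's pointwise-mean pre-immobilization curve:
test ≈ AM·reference + AOff.  AM (slope) indexes amplitude scaling (AM < 1 =
shrinkage of the excursion), AOff (intercept) a vertical offset, and R² is
the squared Pearson correlation (shape similarity, invariant to affine
transformation of either curve).  The regression direction is fixed — post
on pre — so AM < 1 always reads as post-immobilization shrinkage.  The fit
is on raw (not log-transformed) curves.

## Statistical design

Delta scores are post-trial values minus the subject's mean over all
available pre trials, per movement.  The ten post trials are reduced to
T1/T4/T9 — the ~0/50/95% points of a logarithmic recovery (below) — and a
2 (GROUP, between) × 3 (MOVEMENT) × 3 (TIME) mixed ANOVA is computed from
first-principles sums of squares on subject-level cell means, with the
classical error strata (subjects within groups for GROUP; factor × subjects
within groups for each within effect).  Sphericity is assumed (no
correction), matching conventional reporting for this design;
Greenhouse–Geisser adjustment is deliberately out of scope.  Partial
η² = SS_effect/(SS_effect + SS_error).  Missing trials trigger listwise
deletion (the classical univariate mixed model needs balanced
within-subject cells).  Unequal group sizes are supported via weighted
group means.

Five main variables (RD, VP, MFr, elbow AM, shoulder AM) share a
Bonferroni-corrected threshold 0.05/5 = 0.01 (the exact Šidák form
1 − 0.95^(1/5) ≈ 0.0102 is available); R², AOff and trunk displacement are
control variables expected to show null effects, reported with BF01.

**Post hocs** use the stepwise Newman–Keuls studentized-range procedure:
means ranked, q per pair against the critical studentized range for the
stretch spanned, with non-significant ranges blocking nested comparisons.
The error term is the tested effect's own stratum MS.

**Normality** is screened with a one-sample Kolmogorov–Smirnov test against
a normal with the sample's mean/SD.  Estimating parameters from the sample
makes the test conservative (the Lilliefors caveat); it is used only as the
screening check of the original design.

**Bayes factors** use the BIC approximation
BF10 = exp((BIC₀ − BIC₁)/2) on nested OLS models at the effect's own
aggregation level: subject means for GROUP; subject × factor cell means
with subject fixed effects for within effects and their interactions with
GROUP.  The method label is embedded in all outputs: BIC Bayes factors are
directionally informative but not numerically comparable to default-prior
Bayesian ANOVA implementations.

## Synthetic cohort generator

A two-link arm (upper arm 0.30 m, forearm 0.26 m) on a fixed thorax
performs the three reaches: A-Low and A-High in the sagittal plane, L-Low
in the coronal plane.  Shoulder elevation and elbow extension follow
minimum-jerk quintic profiles — the standard bell-velocity model for
point-to-point reaching, which satisfies the single-peak assumption of the
segmentation — padded with 0.25 s stationary holds.  Epicondyle and styloid
marker pairs straddle their segment endpoints along the elbow flexion axis,
so re-deriving joint angles from noise-free markers reproduces the
commanded series to machine precision, and the full pipeline recovers
injected ROMs and durations within 1% (the 5%-threshold truncation is
corrected with the exact crossing fraction of the continuous wrist-speed
profile, ≈0.880 for this geometry, computed by
`armsim.reach_truncation_fraction`; it differs slightly from the pure
minimum-jerk constant 0.8812 because the hand-path Jacobian varies along
the reach).

**Injected immobilization effects** (POST trials only): elbow ROM is scaled
by 1 − shrink·(1 − r_j) and duration inflated by inflate·(1 − r_j), where
r_j = clamp(a + b·ln j, 0, 1) is the recovery fraction, calibrated through
r₄ = 0.50 and r₉ = 0.95 (a ≈ −0.269, b ≈ 0.555) — the two anchors the
logarithmic-recovery assumption of the design provides.  Peak wrist
velocity falls automatically with the longer duration.  Shoulder ROM is
left untouched: the bandage fixes the elbow but leaves the shoulder
residual mobility, and the study's shoulder waveforms were only weakly
affected.  Default magnitudes — CTRL 25% / AOT 10% ROM shrinkage, CTRL
0.30 s / AOT 0.20 s duration inflation — are simulation choices picked to
reproduce the qualitative ordering of the study (CTRL worse than AOT, T1
worst, near-complete recovery by T9/T10); they are not measured facts.

**Variability and noise.**  Between-subject lognormal multipliers (log-sd
0.05) on ROMs and duration, 3% on segment lengths; per-trial lognormal
execution jitter (log-sd 0.05); isotropic Gaussian marker noise of 0.3 mm
(the stated spatial resolution of the optoelectronic system); short
interior dropout runs masking ~1% of frames (kept ≤ 6 frames so gap
reconstruction always succeeds, by design).  Handedness is sampled
right-handed with probability 37/40 and left-handed subjects are mirrored
across the sagittal plane — the harmonization the study leaves unstated.
Every trial draws from a seed stream keyed by
(seed, subject, phase, movement, trial), so identical seeds give
bit-identical cohorts regardless of generation order.

**Reduced feature simulator.**  For large simulation studies
(`armsim.simulate_feature_table`) features are generated analytically from
the effect schedule plus Gaussian measurement error (for MFr, the
delta-method propagation of the two ROM errors), bypassing marker
synthesis.  The deterministic part equals what the marker pipeline recovers
from noise-free trials; the marker-level path is validated separately by
the round-trip tests.  With it, the full design is calibrated and powered
by simulation: under the null the GROUP test rejects at ≈0.05
(0.045–0.052 measured over 1000–2000 cohorts), and under the default
effect sizes the GROUP effect on MFr and elbow AM is detected at p < 0.01
in ~100% of cohorts of 20 subjects per group.

**What the generator does not emulate:** muscle dynamics, grasp/finger
kinematics, trunk compensation strategies, soft-tissue artefact,
correlated (non-isotropic) camera noise, marker swaps, or inter-trial
learning beyond the logarithmic recovery.  Passing recovery tests
therefore shows the measurement chain is correct and the statistics
calibrated — not that real recordings meet the generator's assumptions.

## Problem sizes and numerical choices

The shipped analysis simulates the full study (2 × 20 subjects, 2400
trials); the simulation studies use 1000–2000 reduced cohorts for type-I
error and 200 for power.  Tolerances: LFM affine recovery to 1e-10; angle
round trips to 1e-6°; ROM/duration recovery to 1%; ANOVA sums of squares
validated against an independent mixed-model implementation to 1e-8, with
the total-SS decomposition exact to 1e-9 (relative) on balanced designs.
Ties at the velocity peak break to the earliest frame; near-zero sums of
squares (constant data) are guarded to F = 0; degenerate inputs (collinear
torso markers, zero-length segments, constant LFM reference, S_ROM ≤ 0)
raise typed errors rather than propagating NaNs.

## Known limitations

* The exact ISB angle decomposition and filter settings of the original
  recordings are not recoverable from the study's description; planar
  projections and the 6 Hz default are reasoned substitutes, so bit-exact
  reproduction of real-data statistics is not promised.
* C3D reading requires the optional `ezc3d` dependency; the first-class
  interchange format is the documented trial CSV dialect.
* BIC Bayes factors are directional evidence only.
* The classical mixed ANOVA drops subjects listwise on missing cells;
  multilevel modelling is out of scope.
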