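"""Linear fit method (LFM) for waveform similarity of joint-angle curves.

Each post-immobilization angle curve (time-normalized to 101 samples) is
regressed on the subject's averaged pre-immobilization curve:

    test(k) = AM * reference(k) + AOff + residual(k)

* AM (amplitude modulation, the slope): 1 means equal amplitude, below 1 a
  shrinkage of the investigated angle, above 1 an increased excursion.
* AOff (amplitude offset, the intercept): a vertical shift between curves.
* R^2: squared Pearson correlation of the two curves — shape similarity
  irrespective of amplitude or offset.

The regression direction is fixed (post trial on pre reference) so that
AM < 1 always reads as a post-immobilization shrinkage.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ShapeError


@dataclass
class LFMResult:
    """Slope, intercept and shape similarity of one test curve against a
    reference curve."""

    am: float
    r2: float
    aoff: float
    joint: str = ""
    trial_index: int = 0


def baseline_curve(pre_curves: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise mean of the pre-immobilization normalized curves."""
    if len(pre_curves) == 0:
        raise DegenerateInputError("no pre-immobilization curves to average")
    arrays = [np.asarray(c, dtype=float) for c in pre_curves]
    length = arrays[0].shape
    for arr in arrays:
        if arr.shape != length:
            raise ShapeError(f"curve length mismatch: {arr.shape} vs {length}")
    return np.mean(arrays, axis=0)


def lfm_compare(reference: np.ndarray, test: np.ndarray,
                joint: str = "", trial_index: int = 0) -> LFMResult:
    """Least-squares fit of ``test`` on ``reference`` over the common grid."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape or reference.ndim != 1:
        raise ShapeError(
            f"curves must be 1-D and equal length, got {reference.shape} "
            f"and {test.shape}")
    r_c = reference - reference.mean()
    y_c = test - test.mean()
    ss_r = float(r_c @ r_c)
    if ss_r < 1e-12:
        raise DegenerateInputError(
            "constant reference curve: LFM slope and R^2 are undefined")
    am = float(r_c @ y_c) / ss_r
    aoff = float(test.mean() - am * reference.mean())
    ss_y = float(y_c @ y_c)
    r2 = 0.0 if ss_y < 1e-300 else float(r_c @ y_c) ** 2 / (ss_r * ss_y)
    return LFMResult(am=am, r2=r2, aoff=aoff, joint=joint,
                     trial_index=trial_index)
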