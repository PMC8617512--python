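"""The study's statistical analysis assembled end to end.

Consumes the per-trial feature table and the LFM table produced by
:mod:`reachkin.pipeline` and runs the full design: baseline equivalence
checks, delta-to-baseline scores, reduction to the T1/T4/T9 recovery
timepoints, the 2 x 3 x 3 mixed ANOVA with partial eta^2 and BIC Bayes
factors on the five main variables (RD, VP, MFr, AM elbow, AM shoulder),
null-control ANOVAs with BF01 on R2, AOff and trunk displacement, and
Newman-Keuls post hocs on the TIME factor.
"""
from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from . import groupstats
from .errors import ReachKinError

MAIN_DVS = ("RD", "VP", "MFr", "AM_Elb", "AM_Sho")
CONTROL_DVS = ("R2_Elb", "R2_Sho", "AOff_Elb", "AOff_Sho", "Trunk")
_BF_EFFECTS = ("GROUP", "MOVEMENT", "TIME", "GROUP:MOVEMENT", "GROUP:TIME",
               "MOVEMENT:TIME")


def _lfm_long(lfm_table: pd.DataFrame, joint: str, column: str) -> pd.DataFrame:
    sub = lfm_table[lfm_table["joint"] == joint]
    return pd.DataFrame(dict(subject=sub["subject"], group=sub["group"],
                             movement=sub["movement"],
                             trial_index=sub["trial_index"],
                             value=sub[column].astype(float)))


def _delta_long(deltas: pd.DataFrame, parameter: str) -> pd.DataFrame:
    sub = deltas[deltas["parameter"] == parameter]
    return sub.drop(columns=["parameter"]).copy()


def _analysis_tables(features: pd.DataFrame, lfm_table: pd.DataFrame,
                     deltas: pd.DataFrame) -> dict[str, pd.DataFrame]:
    tables = {p: _delta_long(deltas, p) for p in ("RD", "VP", "MFr")}
    tables["AM_Elb"] = _lfm_long(lfm_table, "elbow", "AM")
    tables["AM_Sho"] = _lfm_long(lfm_table, "shoulder", "AM")
    tables["R2_Elb"] = _lfm_long(lfm_table, "elbow", "R2")
    tables["R2_Sho"] = _lfm_long(lfm_table, "shoulder", "R2")
    tables["AOff_Elb"] = _lfm_long(lfm_table, "elbow", "AOff")
    tables["AOff_Sho"] = _lfm_long(lfm_table, "shoulder", "AOff")
    if "trunk_disp" in features.columns:
        trunk = groupstats.delta_scores(features, parameters=("trunk_disp",))
        tables["Trunk"] = _delta_long(trunk, "trunk_disp")
    return tables


def _anova_with_bf(table: pd.DataFrame, direction: str
                   ) -> tuple[pd.DataFrame, dict[str, float]]:
    anova = groupstats.mixed_anova(table)
    bf = {}
    for effect in _BF_EFFECTS:
        try:
            bf[effect] = groupstats.bayes_factor(table, effect=effect,
                                                 direction=direction)
        except ReachKinError:
            continue
    return anova, bf


def _posthoc_time(table: pd.DataFrame, anova: pd.DataFrame,
                  alpha: float) -> pd.DataFrame:
    time_row = anova[anova["effect"] == "TIME"].iloc[0]
    cell = table.groupby(["trial_index", "subject"], sort=True)["value"].mean()
    means = cell.groupby("trial_index").mean()
    n = int(cell.groupby("trial_index").count().min())
    ms_err = time_row["error_ss"] / time_row["df_den"]
    return groupstats.newman_keuls(
        means.to_numpy(), ms_err, int(time_row["df_den"]), n, alpha=alpha,
        labels=[f"T{t}" for t in means.index])


def analyze_cohort(features: pd.DataFrame, lfm_table: pd.DataFrame,
                   trials: Iterable[int] = groupstats.DEFAULT_TIMEPOINTS,
                   alpha: float = 0.05) -> dict:
    """Run the full statistical design and return a dict of result tables.

    Keys: ``baseline`` (pre-immobilization t-tests), ``table1`` (delta
    summaries at the selected timepoints), ``anova`` (main-variable
    records with BF10), ``controls`` (control-variable records with BF01),
    ``posthoc`` (Newman-Keuls on TIME), ``normality`` (KS p per variable),
    ``threshold`` (the corrected significance threshold).
    """
    trials = tuple(sorted(set(int(t) for t in trials)))
    deltas = groupstats.delta_scores(features)
    tables = _analysis_tables(features, lfm_table, deltas)

    baseline = pd.concat(
        [groupstats.baseline_equivalence(features, p) for p in
         ("RD", "VP", "MFr")], ignore_index=True)
    table1 = groupstats.summarize_deltas(deltas, trials=trials)

    threshold = groupstats.sidak_threshold(alpha, k=len(MAIN_DVS))
    anova_records: list[dict] = []
    control_records: list[dict] = []
    posthoc_frames: list[pd.DataFrame] = []
    normality_rows: list[dict] = []

    for dv in MAIN_DVS + CONTROL_DVS:
        if dv not in tables or tables[dv].empty:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reduced = groupstats.select_timepoints(tables[dv], trials=trials)
        direction = "BF10" if dv in MAIN_DVS else "BF01"
        anova, bf = _anova_with_bf(reduced, direction)
        records = groupstats.anova_to_records(anova, dv, bf)
        if dv in MAIN_DVS:
            anova_records.extend(records)
            ph = _posthoc_time(reduced, anova, alpha)
            ph.insert(0, "dv", dv)
            posthoc_frames.append(ph)
        else:
            control_records.extend(records)
        subj_means = reduced.groupby("subject")["value"].mean()
        try:
            p_norm = groupstats.ks_normality(subj_means.to_numpy())
        except ReachKinError:
            p_norm = np.nan
        normality_rows.append(dict(dv=dv, ks_p=p_norm))

    return dict(
        baseline=baseline,
        table1=table1,
        deltas=deltas,
        anova=anova_records,
        controls=control_records,
        posthoc=pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames else pd.DataFrame(),
        normality=pd.DataFrame(normality_rows),
        threshold=threshold,
        trials=trials,
    )
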