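"""Group-level statistics for the two-group immobilization design.

The study design is a 2 (GROUP: AOT/CTRL, between subjects) x 3 (MOVEMENT)
x 3 (TIME: post trials T1/T4/T9) mixed-design ANOVA on delta-to-baseline
scores (RD, VP, MFr) and on the LFM amplitude-modulation indices.  The
sums-of-squares decomposition is computed from first principles on
subject-level cell means, with the classical error strata of the univariate
mixed model:

    GROUP                 vs  subjects within groups
    MOVEMENT, G x M       vs  MOVEMENT x subjects within groups
    TIME, G x T           vs  TIME x subjects within groups
    M x T, G x M x T      vs  M x T x subjects within groups

Sphericity is assumed (no correction), matching how repeated-measures F
statistics are conventionally reported for this design; partial eta^2 is
SS_effect / (SS_effect + SS_error).  Post hoc comparisons use the
Newman-Keuls stepwise studentized-range procedure, normality is screened
with a one-sample Kolmogorov-Smirnov test against a fitted normal, the
multiple-ANOVA significance threshold follows the Bonferroni form
alpha / k (Sidak variant available), and Bayes factors are approximated
from BIC differences of nested linear models.
"""
from __future__ import annotations

import itertools
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateInputError, ShapeError

DEFAULT_TIMEPOINTS = (1, 4, 9)
MAIN_PARAMETERS = ("RD", "VP", "MFr")

_WITHIN_EFFECTS = {"MOVEMENT": "movement", "TIME": "trial_index"}


# ---------------------------------------------------------------------------
# Baseline checks and delta scores
# ---------------------------------------------------------------------------

def baseline_equivalence(features: pd.DataFrame, parameter: str,
                         welch: bool = False) -> pd.DataFrame:
    """Unpaired two-sample t-tests between groups on subject-level
    pre-immobilization means, one row per movement."""
    pre = features[features["phase"] == "PRE"]
    groups = sorted(pre["group"].unique())
    if len(groups) < 2:
        raise ConfigError("baseline equivalence needs both groups present")
    rows = []
    for movement, sub in pre.groupby("movement", sort=True):
        means = sub.groupby(["group", "subject"], sort=True)[parameter].mean()
        a = means.loc[groups[0]].to_numpy()
        b = means.loc[groups[1]].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ConfigError("need at least 2 subjects per group")
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0  # degenerate: identical constant groups
        else:
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
        df = (len(a) + len(b) - 2) if not welch else None
        rows.append(dict(movement=movement, parameter=parameter, t=float(t),
                         df=df, p=float(p),
                         mean_a=float(a.mean()), mean_b=float(b.mean()),
                         group_a=groups[0], group_b=groups[1]))
    return pd.DataFrame(rows)


def delta_scores(features: pd.DataFrame,
                 parameters: Sequence[str] = MAIN_PARAMETERS) -> pd.DataFrame:
    """Post-trial deltas relative to each subject's average baseline.

    For every POST trial, ``value = post_j - mean(all PRE trials)`` of that
    subject/movement/parameter.  Subjects lacking a baseline for a movement
    are excluded with a warning.
    """
    parameters = list(parameters)
    pre = features[features["phase"] == "PRE"]
    post = features[features["phase"] == "POST"]
    baseline = pre.groupby(["subject", "movement"], sort=True)[
        parameters].mean()
    merged = post.merge(baseline, on=["subject", "movement"], how="left",
                        suffixes=("", "_baseline"), indicator=True)
    missing = merged["_merge"] == "left_only"
    if missing.any():
        dropped = sorted(set(zip(merged.loc[missing, "subject"],
                                 merged.loc[missing, "movement"])))
        warnings.warn(f"missing baseline, excluded: {dropped}")
        merged = merged[~missing]
    out_parts = []
    for param in parameters:
        value = merged[param] - merged[f"{param}_baseline"]
        part = pd.DataFrame(dict(
            subject=merged["subject"], group=merged["group"],
            movement=merged["movement"],
            trial_index=merged["trial_index"].astype(int),
            parameter=param, value=value.astype(float)))
        out_parts.append(part[part["value"].notna()])
    out = pd.concat(out_parts, ignore_index=True) if out_parts else \
        pd.DataFrame()
    cols = ["subject", "group", "movement", "trial_index", "parameter",
            "value"]
    return out.reindex(columns=cols) if len(out) else pd.DataFrame(
        columns=cols)


def select_timepoints(table: pd.DataFrame,
                      trials: Iterable[int] = DEFAULT_TIMEPOINTS
                      ) -> pd.DataFrame:
    """Reduce the TIME factor to the requested post trials (default T1, T4,
    T9 — the ~0%, ~50% and ~95% recovery points of the logarithmic recovery
    model).  Subjects missing any requested trial are dropped listwise."""
    trials = sorted(set(int(t) for t in trials))
    missing = [t for t in trials if t not in set(table["trial_index"])]
    if missing:
        raise ConfigError(f"requested trials absent from table: {missing}")
    out = table[table["trial_index"].isin(trials)].copy()
    need = len(trials) * out["movement"].nunique()
    other = [c for c in ("parameter",) if c in out.columns]
    counts = out.groupby(["subject"] + other)["trial_index"].count()
    per_param = counts.groupby("subject").min() if other else counts
    bad = per_param[per_param < need].index.tolist()
    if bad:
        warnings.warn(f"subjects dropped (incomplete trial set): {bad}")
        out = out[~out["subject"].isin(bad)]
    return out


# ---------------------------------------------------------------------------
# Mixed-design ANOVA
# ---------------------------------------------------------------------------

def _pivot_design(table: pd.DataFrame, dv: str, subject: str, between: str,
                  within: tuple[str, str]):
    """Subject-level cell means as a (subjects, levels1, levels2) array."""
    w1, w2 = within
    cells = table.groupby([subject, between, w1, w2], sort=True)[dv].mean()
    frame = cells.reset_index()
    subjects = sorted(frame[subject].unique())
    lev1 = sorted(frame[w1].unique())
    lev2 = sorted(frame[w2].unique())
    group_of = frame.drop_duplicates(subject).set_index(subject)[between]
    y = np.full((len(subjects), len(lev1), len(lev2)), np.nan)
    pos1 = {v: i for i, v in enumerate(lev1)}
    pos2 = {v: i for i, v in enumerate(lev2)}
    poss = {v: i for i, v in enumerate(subjects)}
    for rec in frame.to_dict("records"):
        y[poss[rec[subject]], pos1[rec[w1]], pos2[rec[w2]]] = rec[dv]
    incomplete = [subjects[i] for i in range(len(subjects))
                  if np.isnan(y[i]).any()]
    if incomplete:
        raise ShapeError(
            f"unbalanced within-subject cells for subjects {incomplete}; "
            "apply select_timepoints/listwise deletion first")
    groups = np.asarray([group_of[s] for s in subjects])
    return y, groups, subjects, lev1, lev2


def _safe_f(ss_eff, df_eff, ss_err, df_err):
    ms_eff = ss_eff / df_eff if df_eff > 0 else 0.0
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ms_err <= 0:
        return (0.0, 1.0) if ms_eff <= 0 else (np.inf, 0.0)
    f = ms_eff / ms_err
    p = float(stats.f.sf(f, df_eff, df_err))
    return float(f), p


def mixed_anova(table: pd.DataFrame, dv: str = "value",
                subject: str = "subject", between: str = "group",
                within: tuple[str, str] = ("movement", "trial_index")
                ) -> pd.DataFrame:
    """Mixed-design ANOVA: one between-subjects factor, two within-subjects
    factors, computed from first-principles sums of squares on subject-level
    cell means.

    Returns one row per effect with SS, df, F, p, partial eta^2, and the
    error stratum used.  Requires complete within-subject cells (use
    :func:`select_timepoints` for listwise deletion) and at least two
    subjects per group.
    """
    y, groups, subjects, lev1, lev2 = _pivot_design(
        table, dv, subject, between, within)
    S, B, C = y.shape
    glabels = sorted(set(groups))
    a = len(glabels)
    if a < 2:
        raise ConfigError("need at least 2 between-subject groups")
    n_g = np.array([(groups == g).sum() for g in glabels])
    if np.any(n_g < 2):
        raise ConfigError("need at least 2 subjects per group")
    gidx = np.array([glabels.index(g) for g in groups])

    grand = y.mean()
    subj = y.mean(axis=(1, 2))                       # (S,)
    m_mean = y.mean(axis=(0, 2))                     # (B,)
    t_mean = y.mean(axis=(0, 1))                     # (C,)
    mt_mean = y.mean(axis=0)                         # (B, C)
    sm = y.mean(axis=2)                              # (S, B)
    st = y.mean(axis=1)                              # (S, C)
    g_mean = np.array([y[gidx == g].mean() for g in range(a)])
    gm = np.stack([y[gidx == g].mean(axis=(0, 2)) for g in range(a)])  # (a,B)
    gt = np.stack([y[gidx == g].mean(axis=(0, 1)) for g in range(a)])  # (a,C)
    gmt = np.stack([y[gidx == g].mean(axis=0) for g in range(a)])      # (a,B,C)

    ss_g = B * C * float(np.sum(n_g * (g_mean - grand) ** 2))
    ss_s_g = B * C * float(np.sum((subj - g_mean[gidx]) ** 2))

    ss_m = S * C * float(np.sum((m_mean - grand) ** 2))
    eff_gm = gm - g_mean[:, None] - m_mean[None, :] + grand
    ss_gm = C * float(np.sum(n_g[:, None] * eff_gm ** 2))
    eff_ms = sm - subj[:, None] - gm[gidx] + g_mean[gidx, None]
    ss_ms = C * float(np.sum(eff_ms ** 2))

    ss_t = S * B * float(np.sum((t_mean - grand) ** 2))
    eff_gt = gt - g_mean[:, None] - t_mean[None, :] + grand
    ss_gt = B * float(np.sum(n_g[:, None] * eff_gt ** 2))
    eff_ts = st - subj[:, None] - gt[gidx] + g_mean[gidx, None]
    ss_ts = B * float(np.sum(eff_ts ** 2))

    eff_mt = mt_mean - m_mean[:, None] - t_mean[None, :] + grand
    ss_mt = S * float(np.sum(eff_mt ** 2))
    eff_gmt = (gmt - gm[:, :, None] - gt[:, None, :]
               - mt_mean[None] + g_mean[:, None, None]
               + m_mean[None, :, None] + t_mean[None, None, :] - grand)
    ss_gmt = float(np.sum(n_g[:, None, None] * eff_gmt ** 2))
    resid = (y - sm[:, :, None] - st[:, None, :] + subj[:, None, None]
             - gmt[gidx] + gm[gidx][:, :, None] + gt[gidx][:, None, :]
             - g_mean[gidx][:, None, None])
    ss_mts = float(np.sum(resid ** 2))

    df_s_g = S - a
    rows = []
    ss_total = float(np.sum((y - grand) ** 2))
    tol = 1e-12 * max(ss_total, 1.0)

    def add(effect, ss, df_num, ss_err, df_den, error):
        ss = 0.0 if ss < tol else ss
        ss_err = 0.0 if ss_err < tol else ss_err
        f, p = _safe_f(ss, df_num, ss_err, df_den)
        pes = 0.0 if ss + ss_err <= 0 else ss / (ss + ss_err)
        rows.append(dict(effect=effect, ss=ss, df_num=df_num, df_den=df_den,
                         F=f, p=p, partial_eta2=pes, error_ss=ss_err,
                         error_term=error))

    add("GROUP", ss_g, a - 1, ss_s_g, df_s_g, "S(G)")
    add("MOVEMENT", ss_m, B - 1, ss_ms, df_s_g * (B - 1), "MxS(G)")
    add("GROUP:MOVEMENT", ss_gm, (a - 1) * (B - 1), ss_ms,
        df_s_g * (B - 1), "MxS(G)")
    add("TIME", ss_t, C - 1, ss_ts, df_s_g * (C - 1), "TxS(G)")
    add("GROUP:TIME", ss_gt, (a - 1) * (C - 1), ss_ts,
        df_s_g * (C - 1), "TxS(G)")
    add("MOVEMENT:TIME", ss_mt, (B - 1) * (C - 1), ss_mts,
        df_s_g * (B - 1) * (C - 1), "MxTxS(G)")
    add("GROUP:MOVEMENT:TIME", ss_gmt, (a - 1) * (B - 1) * (C - 1), ss_mts,
        df_s_g * (B - 1) * (C - 1), "MxTxS(G)")
    out = pd.DataFrame(rows)
    out.attrs["ss_subjects_within_groups"] = ss_s_g
    out.attrs["ss_total"] = ss_total
    out.attrs["n_per_group"] = {g: int(n) for g, n in zip(glabels, n_g)}
    out.attrs["cell_n"] = {g: int(n) for g, n in zip(glabels, n_g)}
    return out


# ---------------------------------------------------------------------------
# Post hoc, normality, thresholds, Bayes factors
# ---------------------------------------------------------------------------

def newman_keuls(means: Sequence[float], ms_error: float, df_error: int,
                 n_per_cell: int, alpha: float = 0.05,
                 labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Stepwise Newman-Keuls studentized-range procedure.

    Means are ranked; each pair is tested with q against the critical
    studentized range for the stretch ``r`` spanned by the pair, and a
    non-significant range blocks all pairs nested inside it.
    """
    means = np.asarray(means, dtype=float)
    k = len(means)
    if k < 2:
        raise ConfigError("need at least 2 means")
    if n_per_cell < 2:
        raise ConfigError("need at least 2 observations per cell")
    if ms_error < 0 or df_error < 1:
        raise ConfigError("invalid error term")
    if labels is None:
        labels = [f"cell{i}" for i in range(k)]
    order = np.argsort(means)
    se = math.sqrt(ms_error / n_per_cell)
    sig = {}
    results = []
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            i, j = order[lo], order[hi]
            diff = means[j] - means[i]
            q = np.inf if se == 0 and diff > 0 else (
                0.0 if se == 0 else diff / se)
            q_crit = float(stats.studentized_range.ppf(1 - alpha, span,
                                                       df_error))
            blocked = any(not sig[(l2, h2)] for l2 in range(0, lo + 1)
                          for h2 in range(hi, k) if (l2, h2) != (lo, hi)
                          and (l2, h2) in sig)
            significant = (not blocked) and q > q_crit
            sig[(lo, hi)] = significant
            p = float(stats.studentized_range.sf(q, span, df_error)) \
                if np.isfinite(q) else 0.0
            results.append(dict(a=labels[i], b=labels[j],
                                mean_a=means[i], mean_b=means[j],
                                span=span, q=float(q), q_crit=q_crit,
                                p=p, blocked=blocked,
                                significant=significant))
    return pd.DataFrame(results)


def ks_normality(values: Sequence[float]) -> float:
    """One-sample Kolmogorov-Smirnov p-value against a normal with the
    sample's mean and SD.

    Estimating the parameters from the same sample makes the test
    conservative (the Lilliefors caveat); it is used here only as the
    screening check of the original design.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise ConfigError("KS normality check needs at least 5 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant sample: normality undefined")
    return float(stats.kstest(values, "norm",
                              args=(values.mean(), sd)).pvalue)


def sidak_threshold(alpha: float = 0.05, k: int = 5,
                    method: str = "bonferroni") -> float:
    """Per-test significance threshold for ``k`` primary analyses.

    The Bonferroni form alpha/k is the default (0.05 / 5 variables = 0.01);
    ``method='sidak'`` gives the exact Sidak threshold 1 - (1-alpha)^(1/k).
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if method == "bonferroni":
        return alpha / k
    if method == "sidak":
        return 1.0 - (1.0 - alpha) ** (1.0 / k)
    raise ConfigError(f"unknown method {method!r}")


def _ols_bic(y: np.ndarray, x: np.ndarray) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    rank = np.linalg.matrix_rank(x)
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + (rank + 1) * math.log(n)


def _dummies(values: pd.Series) -> np.ndarray:
    return pd.get_dummies(values, drop_first=True).to_numpy(dtype=float)


def bayes_factor(table: pd.DataFrame, dv: str = "value",
                 effect: str = "GROUP", direction: str = "BF10",
                 subject: str = "subject", between: str = "group",
                 within: tuple[str, str] = ("movement", "trial_index")
                 ) -> float:
    """BIC-approximated Bayes factor for one design effect.

    The data are aggregated to the effect's own level (subject means for
    GROUP, subject x factor cell means for within effects, with subject
    fixed effects absorbing between-subject variance), and the models with
    and without the effect term are compared through
    ``BF10 = exp((BIC_null - BIC_alt) / 2)``.  ``direction='BF01'`` returns
    the reciprocal (evidence for the null, used for control variables).
    """
    if direction not in ("BF10", "BF01"):
        raise ConfigError(f"direction must be BF10 or BF01, got {direction}")
    w_cols = {"MOVEMENT": within[0], "TIME": within[1]}
    parts = effect.split(":")
    unknown = [p for p in parts if p not in ("GROUP", *w_cols)]
    if unknown or len(parts) > 2:
        raise ConfigError(f"unsupported effect {effect!r} for the BIC "
                          "Bayes-factor comparison (nested models only)")
    if parts == ["GROUP"]:
        agg = table.groupby([subject, between], sort=True)[dv].mean().reset_index()
        y = agg[dv].to_numpy(dtype=float)
        ones = np.ones((len(y), 1))
        x0 = ones
        x1 = np.column_stack([ones, _dummies(agg[between])])
    else:
        factors = [w_cols[p] for p in parts if p != "GROUP"]
        cols = [subject, between] + factors
        agg = table.groupby(cols, sort=True)[dv].mean().reset_index()
        y = agg[dv].to_numpy(dtype=float)
        ones = np.ones((len(y), 1))
        subj_d = _dummies(agg[subject])
        base = [ones, subj_d]
        if len(factors) == 2 or "GROUP" in parts:
            # interaction: base model carries both marginal factor terms
            for f in factors:
                base.append(_dummies(agg[f]))
            if "GROUP" in parts:
                inter = pd.Series(agg[between].astype(str) + "*"
                                  + agg[factors[0]].astype(str))
                extra = _dummies(inter)
            else:
                inter = pd.Series(agg[factors[0]].astype(str) + "*"
                                  + agg[factors[1]].astype(str))
                extra = _dummies(inter)
        else:
            extra = _dummies(agg[factors[0]])
        x0 = np.column_stack(base)
        x1 = np.column_stack(base + [extra])
    bic0 = _ols_bic(y, x0)
    bic1 = _ols_bic(y, x1)
    bf10 = math.exp((bic0 - bic1) / 2.0)
    return bf10 if direction == "BF10" else 1.0 / bf10


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def summarize_deltas(deltas: pd.DataFrame,
                     trials: Iterable[int] = DEFAULT_TIMEPOINTS
                     ) -> pd.DataFrame:
    """Group-level mean and SE of per-subject deltas, one row per
    group x movement x parameter x trial — the study's headline delta table."""
    trials = sorted(set(int(t) for t in trials))
    sub = deltas[deltas["trial_index"].isin(trials)]
    per_subject = sub.groupby(
        ["group", "movement", "parameter", "trial_index", "subject"],
        sort=True)["value"].mean()
    rows = []
    for key, vals in per_subject.groupby(level=[0, 1, 2, 3]):
        v = vals.to_numpy()
        se = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else np.nan
        rows.append(dict(group=key[0], movement=key[1], parameter=key[2],
                         trial_index=int(key[3]), mean=float(v.mean()),
                         se=se, n=len(v),
                         flag="single-subject" if len(v) < 2 else ""))
    return pd.DataFrame(rows)


def anova_to_records(anova: pd.DataFrame, dv_name: str,
                     bf: dict[str, float] | None = None) -> list[dict]:
    """Flatten an ANOVA table (plus optional Bayes factors) for JSON output."""
    records = []
    for rec in anova.to_dict("records"):
        entry = dict(dv=dv_name, **{k: rec[k] for k in
                                    ("effect", "ss", "df_num", "df_den", "F",
                                     "p", "partial_eta2", "error_term")})
        if bf and rec["effect"] in bf:
            entry["BF"] = bf[rec["effect"]]
            entry["BF_method"] = "BIC approximation"
        records.append(entry)
    return records
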