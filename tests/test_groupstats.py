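"""Statistical design: mixed ANOVA against an independent oracle, delta
scores, post hocs, Bayes factors, normality and thresholds."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reachkin import groupstats
from reachkin.errors import ConfigError, DegenerateInputError, ShapeError
from reachkin.groupstats import (baseline_equivalence, bayes_factor,
                                 delta_scores, ks_normality, mixed_anova,
                                 newman_keuls, select_timepoints,
                                 sidak_threshold, summarize_deltas)

MOVEMENTS = ["A-Low", "A-High", "L-Low"]
TIMES = [1, 4, 9]

# 4-subject, 3 movement x 3 time fixture (values drawn once from a seeded
# normal and frozen together with the reference results below).
FIXTURE_VALUES = [
    0.636603, -1.22553, 0.232875, -0.901332, -0.58638, 0.277983, 0.805414,
    1.386547, -0.802209, 0.809483, -0.016934, -1.12747, 0.344078, -0.546025,
    0.378316, -0.420996, 0.742954, -0.798169, -0.04604, -0.458985, 0.239867,
    -0.904055, -0.217845, 0.591818, 1.508362, 0.594059, 1.46504, 0.142087,
    0.412331, 1.912284, 1.30673, -0.859738, 0.925115, 1.074564, -1.255923,
    0.310218]

# Reference decomposition computed with R stats::aov,
# value ~ group*movement*time + Error(subject/(movement*time)).
R_ORACLE = {
    "GROUP": dict(ss=1.583688432327, F=34.7738493454146,
                  p=0.0275733826989985, df=(1, 2)),
    "MOVEMENT": dict(ss=0.987599043538, F=0.426879295742285,
                     p=0.67914676771963, df=(2, 4)),
    "GROUP:MOVEMENT": dict(ss=0.051943439036, F=0.0224520050108492,
                           p=0.977920483795158, df=(2, 4)),
    "TIME": dict(ss=2.031231739121, F=2.81915389709171,
                 p=0.172233806668183, df=(2, 4)),
    "GROUP:TIME": dict(ss=3.306851864336, F=4.58959169497865,
                       p=0.0921176775464849, df=(2, 4)),
    "MOVEMENT:TIME": dict(ss=2.565163216862, F=1.21423370773954,
                          p=0.376416925054173, df=(4, 8)),
    "GROUP:MOVEMENT:TIME": dict(ss=4.612631878952, F=2.1834139332733,
                                p=0.161298300633134, df=(4, 8)),
}
R_ERROR_SS = {"S(G)": 0.091085022920, "MxS(G)": 4.627064621723,
              "TxS(G)": 1.441022245161, "MxTxS(G)": 4.225155668982}


def anova_fixture():
    rows = []
    it = iter(FIXTURE_VALUES)
    for subj, grp in [("S1", "AOT"), ("S2", "AOT"), ("S3", "CTRL"),
                      ("S4", "CTRL")]:
        for m in MOVEMENTS:
            for t in TIMES:
                rows.append(dict(subject=subj, group=grp, movement=m,
                                 trial_index=t, value=next(it)))
    return pd.DataFrame(rows)


def random_balanced_table(rng, n_per_group=5, n_mov=3, n_time=3):
    rows = []
    for g, grp in enumerate(["AOT", "CTRL"]):
        for s in range(n_per_group):
            subj = f"{grp}{s}"
            for m in range(n_mov):
                for t in range(n_time):
                    rows.append(dict(subject=subj, group=grp,
                                     movement=f"M{m}", trial_index=t + 1,
                                     value=rng.normal()))
    return pd.DataFrame(rows)


class TestMixedAnovaOracle:
    def test_matches_reference_decomposition(self):
        """All seven effects agree with an independent reference
        implementation of the univariate mixed model to 1e-8."""
        res = mixed_anova(anova_fixture()).set_index("effect")
        for effect, ref in R_ORACLE.items():
            row = res.loc[effect]
            assert row["ss"] == pytest.approx(ref["ss"], abs=1e-8)
            assert row["F"] == pytest.approx(ref["F"], abs=1e-8)
            assert row["p"] == pytest.approx(ref["p"], abs=1e-8)
            assert (row["df_num"], row["df_den"]) == ref["df"]
            pes = ref["ss"] / (ref["ss"] + row["error_ss"])
            assert row["partial_eta2"] == pytest.approx(pes, abs=1e-10)

    def test_error_strata_match_reference(self):
        res = mixed_anova(anova_fixture())
        assert res.attrs["ss_subjects_within_groups"] == pytest.approx(
            R_ERROR_SS["S(G)"], abs=1e-8)
        for term in ("MxS(G)", "TxS(G)", "MxTxS(G)"):
            err = res.loc[res["error_term"] == term, "error_ss"].iloc[0]
            assert err == pytest.approx(R_ERROR_SS[term], abs=1e-8)


class TestMixedAnovaProperties:
    def test_ss_decomposition_exact(self, rng):
        for _ in range(5):
            table = random_balanced_table(rng)
            res = mixed_anova(table)
            parts = (res["ss"].sum()
                     + res.attrs["ss_subjects_within_groups"]
                     + sum(res.loc[res["error_term"] == t, "error_ss"].iloc[0]
                           for t in ("MxS(G)", "TxS(G)", "MxTxS(G)")))
            assert parts == pytest.approx(res.attrs["ss_total"], rel=1e-9)

    def test_constant_dv_gives_zero_f(self):
        table = random_balanced_table(np.random.default_rng(0))
        table["value"] = 3.14
        res = mixed_anova(table)
        assert (res["F"] == 0).all()
        assert (res["partial_eta2"] == 0).all()

    def test_group_df_matches_design(self):
        table = random_balanced_table(np.random.default_rng(1), n_per_group=20)
        res = mixed_anova(table).set_index("effect")
        assert res.loc["GROUP", "df_den"] == 38  # 2n - 2
        assert res.loc["MOVEMENT", "df_den"] == 76  # 2(2n-2)

    def test_unbalanced_cells_rejected(self):
        table = random_balanced_table(np.random.default_rng(2))
        table = table.drop(table.index[5])
        with pytest.raises(ShapeError, match="unbalanced"):
            mixed_anova(table)

    def test_single_group_rejected(self):
        table = random_balanced_table(np.random.default_rng(3))
        table = table[table["group"] == "AOT"]
        with pytest.raises(ConfigError):
            mixed_anova(table)

    def test_duplicate_trials_averaged_to_cell_means(self):
        table = random_balanced_table(np.random.default_rng(4))
        doubled = pd.concat([table, table], ignore_index=True)
        a = mixed_anova(table)
        b = mixed_anova(doubled)
        np.testing.assert_allclose(a["F"], b["F"], atol=1e-12)


class TestDeltaScores:
    def _features(self):
        rows = []
        for subj, grp in [("S1", "AOT"), ("S2", "CTRL")]:
            for phase, trials in (("PRE", [1, 2, 3]), ("POST", [1, 2])):
                for t in trials:
                    rows.append(dict(subject=subj, group=grp,
                                     movement="A-Low", phase=phase,
                                     trial_index=t, RD=float(t), VP=1.0,
                                     MFr=10.0 * t))
        return pd.DataFrame(rows)

    def test_delta_relative_to_baseline_mean(self):
        deltas = delta_scores(self._features())
        rd = deltas[(deltas.parameter == "RD") & (deltas.subject == "S1")]
        # baseline mean of {1,2,3} = 2; post_1 delta = -1, post_2 delta = 0
        assert sorted(rd["value"]) == [-1.0, 0.0]
        assert set(deltas["parameter"]) == {"RD", "VP", "MFr"}

    def test_post_equal_to_baseline_gives_zero(self):
        feats = self._features()
        feats.loc[feats.phase == "POST", ["RD", "VP", "MFr"]] = \
            feats[feats.phase == "PRE"][["RD", "VP", "MFr"]].mean().values
        deltas = delta_scores(feats)
        sub = deltas[deltas.subject == "S1"]
        assert np.allclose(sub["value"], 0.0)

    def test_missing_baseline_excluded_with_warning(self):
        feats = self._features()
        feats = feats[~((feats.subject == "S2") & (feats.phase == "PRE"))]
        with pytest.warns(UserWarning, match="missing baseline"):
            deltas = delta_scores(feats)
        assert set(deltas["subject"]) == {"S1"}


class TestSelectTimepoints:
    def _deltas(self, n_trials=10):
        rows = []
        for subj in ("S1", "S2"):
            for m in MOVEMENTS:
                for t in range(1, n_trials + 1):
                    rows.append(dict(subject=subj, group="AOT", movement=m,
                                     trial_index=t, parameter="MFr",
                                     value=float(t)))
        return pd.DataFrame(rows)

    def test_reduces_to_three_levels(self):
        table = self._deltas()
        out = select_timepoints(table)
        assert set(out["trial_index"]) == {1, 4, 9}
        assert len(out) == len(table) * 3 // 10

    def test_custom_trials(self):
        out = select_timepoints(self._deltas(), trials=(2, 5, 8))
        assert set(out["trial_index"]) == {2, 5, 8}

    def test_absent_trial_rejected(self):
        with pytest.raises(ConfigError):
            select_timepoints(self._deltas(3), trials=(1, 4, 9))

    def test_listwise_deletion_of_incomplete_subjects(self):
        table = self._deltas()
        table = table.drop(table[(table.subject == "S2")
                                 & (table.trial_index == 4)
                                 & (table.movement == "A-Low")].index)
        with pytest.warns(UserWarning, match="dropped"):
            out = select_timepoints(table)
        assert set(out["subject"]) == {"S1"}


class TestBaselineEquivalence:
    def _features(self, shift=0.0, n=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, grp in enumerate(["AOT", "CTRL"]):
            for s in range(n):
                val = rng.normal(loc=shift * g)
                rows.append(dict(subject=f"{grp}{s}", group=grp,
                                 movement="A-Low", phase="PRE",
                                 trial_index=1, RD=val))
        return pd.DataFrame(rows)

    def test_identical_groups_give_t0_p1(self):
        feats = self._features()
        feats["RD"] = 1.0
        res = baseline_equivalence(feats, "RD")
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_three_sd_shift_detected(self):
        res = baseline_equivalence(self._features(shift=3.0), "RD")
        assert res["p"].iloc[0] < 0.001

    def test_null_type_i_error_calibrated(self):
        rejections = sum(
            baseline_equivalence(self._features(seed=s), "RD")["p"].iloc[0]
            < 0.05 for s in range(400))
        assert 0.02 <= rejections / 400 <= 0.08

    def test_single_group_rejected(self):
        feats = self._features()
        with pytest.raises(ConfigError):
            baseline_equivalence(feats[feats.group == "AOT"], "RD")


class TestNewmanKeuls:
    def test_two_equal_means_not_significant(self):
        res = newman_keuls([1.0, 1.0], ms_error=1.0, df_error=38,
                           n_per_cell=20)
        assert not res["significant"].any()
        assert res["q"].iloc[0] == 0.0

    def test_outer_pairs_significant_inner_not(self):
        # means {0, 0, 10*SE}: both pairs with the distant mean significant,
        # the tied inner pair not
        ms, n = 1.0, 4
        se = np.sqrt(ms / n)
        res = newman_keuls([0.0, 0.0, 10 * se], ms_error=ms, df_error=38,
                           n_per_cell=n, labels=["a", "b", "c"])
        sig = {(r["a"], r["b"]): r["significant"]
               for r in res.to_dict("records")}
        assert sig[("a", "c")] and sig[("b", "c")]
        assert not sig[("a", "b")]

    def test_critical_value_matches_studentized_range(self):
        res = newman_keuls([0.0, 1.0, 5.0], ms_error=1.0, df_error=38,
                           n_per_cell=20)
        outer = res[res["span"] == 3].iloc[0]
        assert outer["q_crit"] == pytest.approx(
            stats.studentized_range.ppf(0.95, 3, 38), abs=1e-10)

    def test_nonsignificant_range_blocks_inner_pairs(self):
        # all means close: the full range is not significant, so nested
        # pairs must be blocked regardless of their own q
        res = newman_keuls([0.0, 0.01, 0.02], ms_error=1.0, df_error=10,
                           n_per_cell=4)
        inner = res[res["span"] == 2]
        assert not res[res["span"] == 3]["significant"].iloc[0]
        assert inner["blocked"].all()
        assert not inner["significant"].any()

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            newman_keuls([1.0], 1.0, 10, 4)
        with pytest.raises(ConfigError):
            newman_keuls([1.0, 2.0], 1.0, 10, 1)


class TestKsNormality:
    def test_normal_sample_usually_passes(self):
        passed = 0
        for s in range(60):
            x = np.random.default_rng(s).normal(size=200)
            passed += ks_normality(x) > 0.05
        assert passed >= 50

    def test_exponential_sample_rejected(self):
        rejected = 0
        for s in range(30):
            x = np.random.default_rng(s).exponential(size=200)
            rejected += ks_normality(x) < 0.05
        assert rejected >= 28

    def test_degenerate_constant_sample(self):
        with pytest.raises(DegenerateInputError):
            ks_normality(np.full(10, 2.0))

    def test_minimum_sample_size(self):
        with pytest.raises(ConfigError):
            ks_normality([1.0, 2.0, 3.0])


class TestSidakThreshold:
    def test_paper_form_bonferroni(self):
        assert sidak_threshold(0.05, 5) == pytest.approx(0.01)

    def test_single_test_unchanged(self):
        assert sidak_threshold(0.05, 1) == 0.05

    def test_sidak_variant(self):
        assert sidak_threshold(0.05, 5, method="sidak") == pytest.approx(
            1 - 0.95 ** 0.2, abs=1e-12)
        assert sidak_threshold(0.05, 5, method="sidak") == pytest.approx(
            0.010206, abs=1e-6)


class TestBayesFactor:
    def _table(self, shift=0.0, seed=0, n=20):
        rng = np.random.default_rng(seed)
        rows = []
        for g, grp in enumerate(["AOT", "CTRL"]):
            for s in range(n):
                subj_eff = rng.normal(loc=shift * (g - 0.5))
                for m in MOVEMENTS:
                    for t in TIMES:
                        rows.append(dict(subject=f"{grp}{s}", group=grp,
                                         movement=m, trial_index=t,
                                         value=subj_eff + rng.normal(0, 0.5)))
        return pd.DataFrame(rows)

    def test_bf01_is_reciprocal_of_bf10(self):
        table = self._table(seed=1)
        bf10 = bayes_factor(table, effect="GROUP", direction="BF10")
        bf01 = bayes_factor(table, effect="GROUP", direction="BF01")
        assert bf01 == pytest.approx(1.0 / bf10, rel=1e-12)

    def test_null_data_favors_h0(self):
        favored = sum(
            bayes_factor(self._table(seed=s), effect="GROUP") < 1.0
            for s in range(60))
        assert favored >= 54  # > 90% of null replicates

    def test_strong_group_effect_favors_h1(self):
        # 1.5-SD between-group shift at n=20/group: the noncentral-t
        # argument gives P(BF10 > 3) ~ 0.99 for the BIC approximation
        hits = sum(
            bayes_factor(self._table(shift=1.5, seed=100 + s),
                         effect="GROUP") > 3.0
            for s in range(30))
        assert hits >= 27

    def test_within_effect_supported(self):
        table = self._table(seed=2)
        table["value"] += table["trial_index"] * 0.8
        assert bayes_factor(table, effect="TIME") > 3.0

    def test_unsupported_effect_rejected(self):
        with pytest.raises(ConfigError):
            bayes_factor(self._table(), effect="GROUP:MOVEMENT:TIME")


class TestSummarizeDeltas:
    def _deltas(self, value=0.0, n_subj=3):
        rows = []
        for s in range(n_subj):
            for t in (1, 4, 9):
                rows.append(dict(subject=f"S{s}", group="CTRL",
                                 movement="A-Low", trial_index=t,
                                 parameter="MFr", value=value + s))
        return pd.DataFrame(rows)

    def test_zero_deltas_give_zero_table(self):
        table = summarize_deltas(self._deltas(0.0, n_subj=1).assign(value=0.0))
        assert (table["mean"] == 0).all()

    def test_mean_and_se(self):
        table = summarize_deltas(self._deltas())
        row = table[table.trial_index == 1].iloc[0]
        assert row["mean"] == pytest.approx(1.0)
        assert row["se"] == pytest.approx(1.0 / np.sqrt(3))

    def test_single_subject_flagged(self):
        table = summarize_deltas(self._deltas(n_subj=1))
        assert (table["flag"] == "single-subject").all()
        assert table["se"].isna().all()
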