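"""Behavioural metrics, robust correlation, OLS/mixed models, Holm."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from fmrspipe.simulate import CohortConfig, simulate_cohort
from fmrspipe.stats import (
    behavioural_metrics,
    delta_metabolites,
    fit_baseline_model,
    fit_mixed_model,
    holm_adjust,
    medication_model,
    percent_task_effect,
    rank_tests,
    skipped_spearman,
)


class TestBehaviouralMetrics:
    def _log(self, correct, rt, congruent):
        return pd.DataFrame(
            {"trial_id": range(len(correct)), "congruent": congruent,
             "rt_s": rt, "correct": correct, "session": "fMRS"}
        )

    def test_response_accuracy(self):
        log = self._log([True] * 8 + [False] * 2, [0.4] * 10, [True] * 10)
        assert behavioural_metrics(log)["ra"] == pytest.approx(0.8)

    def test_rt_slowing_hand_computed(self):
        rt = [0.40, 0.42, 0.44, 0.50, 0.52, 0.54]
        cong = [True] * 3 + [False] * 3
        log = self._log([True] * 6, rt, cong)
        m = behavioural_metrics(log)
        assert m["rt_slowing_s"] == pytest.approx(0.10)

    def test_identical_distributions_zero_slowing(self):
        rt = [0.4, 0.5, 0.6] * 2
        log = self._log([True] * 6, rt, [True, True, True, False, False, False])
        assert behavioural_metrics(log)["rt_slowing_s"] == pytest.approx(0.0)

    def test_no_correct_responses_flagged(self):
        log = self._log([False] * 5, [np.nan] * 5, [True] * 5)
        m = behavioural_metrics(log)
        assert m["flagged"] and np.isnan(m["rt_s"])


class TestRankTests:
    def test_identical_paired_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            stat, p = rank_tests([1, 2, 3], [1, 2, 3], paired=True)
        assert p == 1.0

    def test_u_statistic_complete_separation(self):
        u, p = rank_tests(np.arange(1, 11), np.arange(11, 21), paired=False)
        assert u == 0.0
        assert p < 0.001

    def test_order_symmetry(self):
        a, b = np.arange(10.0), np.arange(10.0) + 2.5
        _, p_ab = rank_tests(a, b, paired=False)
        _, p_ba = rank_tests(b, a, paired=False)
        assert p_ab == pytest.approx(p_ba)

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            rank_tests([1, 2], [1, 2, 3], paired=True)


class TestSkippedSpearman:
    def test_perfect_monotone_no_outliers(self):
        x = np.arange(1.0, 21.0)
        res = skipped_spearman(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.n_outliers_removed == 0

    def test_reduces_to_classical_when_nothing_flagged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(scale=0.5, size=40)
        res = skipped_spearman(x, y)
        if res.n_outliers_removed == 0:
            assert res.r == pytest.approx(scipy.stats.spearmanr(x, y).statistic)

    def test_gross_outlier_removed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.1, size=40)
        x2, y2 = np.append(x, 8.0), np.append(y, -8.0)
        res = skipped_spearman(x2, y2)
        assert res.n_outliers_removed >= 1
        assert res.r == pytest.approx(scipy.stats.spearmanr(x, y).statistic, abs=0.05)

    def test_matches_pingouin_on_shared_data(self):
        """Independent cross-check against the established implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        y = 0.6 * x + rng.normal(scale=0.8, size=60)
        ours = skipped_spearman(x, y)
        theirs = pingouin.corr(x, y, method="skipped")
        assert ours.r == pytest.approx(float(theirs["r"].iloc[0]), abs=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            skipped_spearman(np.arange(5.0), np.arange(5.0))


def _clean_table(n=120, seed=3, offset=-2.0):
    rng = np.random.default_rng(seed)
    group = np.array(["control"] * (n // 2) + ["patient"] * (n // 2))
    z = rng.normal(2.0, 0.8, n)
    glx = 15.0 + offset * (group == "patient") + rng.normal(0, 0.8, n)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": group,
            "bold_fmri_z": z,
            "bold_fmrs": z * 0.2 + rng.normal(0, 0.1, n),
            "glx_off_iu": glx,
            "fgm": rng.normal(0.55, 0.05, n),
            "age_y": rng.normal(31.0, 9.0, n),
        }
    )


class TestBaselineModel:
    def test_group_offset_recovery_with_ci_coverage(self):
        hits = 0
        for seed in range(30):
            res = fit_baseline_model(_clean_table(n=200, seed=seed), "glx_off_iu")
            t = res.term("C(group)[T.patient]")
            hits += t.ci95_lo <= -2.0 <= t.ci95_hi
        assert hits >= 27

    def test_no_influential_points_nothing_dropped(self):
        # exact linear response: every DFFITS is numerically zero
        tab = _clean_table(n=80, seed=1)
        tab["glx_off_iu"] = 15.0 - 2.0 * (tab.group == "patient") + 0.5 * tab.fgm
        res = fit_baseline_model(tab, "glx_off_iu")
        assert res.dropped == []

    def test_planted_high_leverage_outlier_uniquely_dropped(self):
        """The planted point must agree with a brute-force leave-one-out
        DFFITS computation."""
        import statsmodels.formula.api as smf

        tab = _clean_table(n=60, seed=9)
        tab.loc[59, "bold_fmri_z"] = 9.0
        tab.loc[59, "glx_off_iu"] = 30.0
        formula = "glx_off_iu ~ C(group) * bold_fmri_z + fgm + age_y"
        fit = smf.ols(formula, data=tab).fit()
        k, n = fit.df_model + 1, int(fit.nobs)
        # brute-force studentized difference in fits
        infl = []
        for i in range(n):
            sub = tab.drop(index=i)
            f_i = smf.ols(formula, data=sub).fit()
            yhat_full = fit.fittedvalues.iloc[i]
            yhat_loo = f_i.predict(tab.iloc[[i]]).iloc[0]
            h = fit.get_influence().hat_matrix_diag[i]
            s_i = np.sqrt(f_i.mse_resid)
            infl.append((yhat_full - yhat_loo) / (s_i * np.sqrt(h)))
        brute = np.abs(np.asarray(infl)) > 2 * np.sqrt(k / n)
        res = fit_baseline_model(tab, "glx_off_iu")
        dropped_ids = {tab.loc[i, "subject_id"] for i, _ in
                       [(idx, r) for idx, r in res.dropped]}
        assert "s59" in dropped_ids
        assert brute[59]

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="fgm"):
            fit_baseline_model(_clean_table().drop(columns="fgm"), "glx_off_iu")


def _long_table(n_subj=40, task=1.0, seed=4, noise=0.3, between=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subj):
        grp = "patient" if i >= n_subj // 2 else "control"
        base = rng.normal(15.0, between) if between else 15.0
        fgm, age = rng.normal(0.55, 0.05), rng.normal(31, 9)
        for state in ("OFF", "ON"):
            val = base + task * (state == "ON") + rng.normal(0, noise)
            rows.append(dict(subject_id=f"s{i}", group=grp, task_state=state,
                             value_iu=val, fgm=fgm, age_y=age))
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_task_effect_ci_coverage(self):
        hits = 0
        for seed in range(15):
            res = fit_mixed_model(_long_table(seed=seed))
            t = res.term("C(task_state)[T.ON]")
            hits += t.ci95_lo <= 1.0 <= t.ci95_hi
        assert hits >= 12

    def test_noiseless_data_nothing_filtered(self):
        # fully deterministic responses: marginal residuals are numerically
        # zero, so the MAD filter must not exclude anything
        res = fit_mixed_model(_long_table(noise=0.0, between=0.0))
        assert res.dropped == []

    def test_percent_task_effect(self):
        res = fit_mixed_model(_long_table(task=0.9, noise=0.1, seed=8))
        assert percent_task_effect(res) == pytest.approx(6.0, abs=1.5)

    def test_single_observation_per_subject_rejected(self):
        tab = _long_table().groupby("subject_id").head(1)
        with pytest.raises(ValueError):
            fit_mixed_model(tab)


class TestMedicationModel:
    def _patients(self, slope=0.15, seed=11, n=60):
        rng = np.random.default_rng(seed)
        ddd = np.clip(rng.exponential(1.4, n), 0, 6)
        active = ddd > 0.2
        gaba = 3.0 + slope * ddd + rng.normal(0, 0.3, n)
        return pd.DataFrame(
            {
                "subject_id": [f"p{i}" for i in range(n)],
                "group": "patient",
                "gaba_off_iu": gaba,
                "ddd": ddd,
                "is_active": active,
                "fgm": rng.normal(0.55, 0.05, n),
                "age_y": rng.normal(31, 9, n),
                "panss_pos": rng.normal(18, 5, n),
            }
        )

    def test_ddd_slope_recovered(self):
        res = medication_model(self._patients())
        t = [x for x in res.terms if x.name.endswith("ddd")][0]
        assert t.ci95_lo <= 0.15 <= t.ci95_hi

    def test_all_zero_ddd_raises(self):
        tab = self._patients()
        tab["ddd"] = 0.0
        with pytest.raises(ValueError, match="ddd"):
            medication_model(tab)

    def test_constant_is_active_drops_interaction(self):
        tab = self._patients()
        tab["is_active"] = True
        with pytest.warns(UserWarning, match="interaction dropped"):
            res = medication_model(tab)
        assert all("is_active" not in t.name for t in res.terms)


class TestHolm:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert holm_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 8))
            np.testing.assert_allclose(
                holm_adjust(p), multipletests(p, method="holm")[1], atol=1e-12
            )

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_dominance_and_cap(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_empty_input(self):
        assert holm_adjust([]).size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestDeltaMetabolites:
    def test_simple_difference(self):
        tab = pd.DataFrame({"glx_on_iu": [15.9], "glx_off_iu": [15.0]})
        assert delta_metabolites(tab).iloc[0] == pytest.approx(0.9)

    def test_identical_conditions_zero(self):
        tab = pd.DataFrame({"glx_on_iu": [15.0], "glx_off_iu": [15.0]})
        assert delta_metabolites(tab).iloc[0] == 0.0

    def test_unusable_condition_gives_missing(self):
        tab = pd.DataFrame(
            {"glx_on_iu": [15.9], "glx_off_iu": [15.0], "off_ok": [False]}
        )
        d = delta_metabolites(tab, usable_off="off_ok")
        assert d.isna().iloc[0]
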