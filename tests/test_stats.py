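"""Statistical stage: transforms, test battery, permutation test, models."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

import mammodense as md
from mammodense.stats import (CaseCaseModel, _logit_fit, box_cox_standardize,
                              cohort_summary, feature_risk_factor_models,
                              summarize_counts, tumor_size_regression)


def simple_cohort(n, seed, n_feats=8, beta=None, feature_effects=None):
    """Cohort + one feature table with configurable logistic effects."""
    r = np.random.default_rng(seed)
    feats = r.standard_normal((n, n_feats))
    pdv = np.exp(r.normal(math.log(19), 0.55, n))
    lp = np.full(n, -0.94)
    if feature_effects:
        for idx, b in feature_effects.items():
            lp = lp + b * feats[:, idx]
    y = r.random(n) < 1.0 / (1.0 + np.exp(-lp))
    cohort = pd.DataFrame({
        "outcome": np.where(y, "IC", "SC"), "pd": pdv,
        "age_dx": r.normal(60, 7, n), "bmi": r.normal(25.5, 4, n),
        "hrt": np.where(r.random(n) < 0.19, "yes", "no"),
        "months_to_dx": r.uniform(2, 30, n),
    })
    table = pd.DataFrame(feats, columns=[f"F{i + 1}" for i in range(n_feats)])
    return cohort, table


# ---------------------------------------------------------------------------
# Box-Cox standardization
# ---------------------------------------------------------------------------

def test_box_cox_recovers_log_for_lognormal():
    rng = np.random.default_rng(0)
    x = np.exp(rng.normal(3.0, 0.6, 5000))
    z, spec = box_cox_standardize(x)
    assert -0.15 <= spec.lam <= 0.15
    assert abs(z.mean()) < 1e-10 and abs(z.std() - 1.0) < 1e-10


def test_box_cox_near_identity_for_normal():
    rng = np.random.default_rng(1)
    x = rng.normal(50.0, 5.0, 5000)
    _, spec = box_cox_standardize(x)
    assert 0.7 <= spec.lam <= 1.3


def test_box_cox_shifts_nonpositive_samples():
    rng = np.random.default_rng(2)
    x = rng.normal(0.0, 1.0, 500)
    z, spec = box_cox_standardize(x)
    assert spec.shift == pytest.approx(1.0 - x.min())
    assert np.isfinite(z).all()
    # transform is replayable
    assert np.allclose(spec.apply(x), z)


def test_box_cox_constant_sample_raises():
    with pytest.raises(ValueError):
        box_cox_standardize(np.full(100, 3.0))


# ---------------------------------------------------------------------------
# per-feature test battery
# ---------------------------------------------------------------------------

def test_type_one_error_calibrated_on_null_features():
    """Null features reject at close to the nominal 5% level."""
    rejections = []
    for seed in range(2):
        cohort, table = simple_cohort(2000, seed, n_feats=250)
        model = CaseCaseModel(cohort, {"otsu": table})
        res = model.per_feature_tests()
        rejections.append((res.p < 0.05).to_numpy())
    rate = np.concatenate(rejections).mean()
    assert 0.03 <= rate <= 0.07


def test_adjustment_absorbs_pd_driven_confounding():
    """A feature that is only a noisy copy of PD shows no conditional
    effect when the outcome depends on PD alone."""
    r = np.random.default_rng(5)
    n = 4000
    pdv = np.exp(r.normal(math.log(19), 0.55, n))
    zpd = (pdv - pdv.mean()) / pdv.std()
    y = r.random(n) < 1.0 / (1.0 + np.exp(-(-0.94 + 0.8 * zpd)))
    cohort = pd.DataFrame({"outcome": np.where(y, "IC", "SC"), "pd": pdv})
    table = pd.DataFrame({"F1": pdv + r.normal(0, 2.0, n)})
    model = CaseCaseModel(cohort, {"otsu": table})
    res = model.per_feature_tests().iloc[0]
    assert abs(res.estimate) < 2.5 * res.se + 0.1


def test_constant_feature_flagged_not_crashing():
    cohort, table = simple_cohort(500, 0, n_feats=2)
    table["F1"] = 1.0
    model = CaseCaseModel(cohort, {"otsu": table})
    res = model.per_feature_tests()
    row = res[res.feature == "F1"].iloc[0]
    assert not row.converged and np.isnan(row.p)
    assert res[res.feature == "F2"].iloc[0].converged


def test_wald_and_lr_pvalues_agree_in_rank():
    """Across replicate datasets the Wald p of the feature term tracks the
    likelihood-ratio p almost perfectly in rank."""
    wald, lrt = [], []
    for seed in range(50):
        cohort, table = simple_cohort(
            2000, 100 + seed, n_feats=1,
            feature_effects={0: 0.1 * (seed % 4)})
        y = (cohort.outcome == "IC").to_numpy(float)
        z = (table.F1 - table.F1.mean()).to_numpy() / table.F1.std()
        zpd = (cohort.pd - cohort.pd.mean()).to_numpy() / cohort.pd.std()
        X = np.column_stack([np.ones(len(y)), z, zpd])
        beta, cov, ll1, _ = _logit_fit(X, y)
        _, _, ll0, _ = _logit_fit(X[:, [0, 2]], y)
        wald.append(2 * sp_stats.norm.sf(abs(beta[1] / math.sqrt(cov[1, 1]))))
        lrt.append(sp_stats.chi2.sf(2 * (ll1 - ll0), df=1))
    rho = sp_stats.spearmanr(wald, lrt).statistic
    assert rho > 0.99


# ---------------------------------------------------------------------------
# global permutation test
# ---------------------------------------------------------------------------

def test_maximal_observed_statistic_gives_p_zero():
    """When every test is already significant no permutation can exceed the
    observed count."""
    cohort, table = simple_cohort(1500, 3, n_feats=2,
                                  feature_effects={0: 1.2, 1: 1.2})
    model = CaseCaseModel(cohort, {"otsu": table})
    res = model.global_test(n_perm=100, seed=0)
    assert res.statistic == res.n_tests
    assert res.p_value == 0.0


def test_permutation_p_deterministic_and_seed_stable():
    cohort, table = simple_cohort(600, 4, n_feats=6,
                                  feature_effects={0: 0.35})
    model = CaseCaseModel(cohort, {"otsu": table})
    r1 = model.global_test(n_perm=150, seed=7)
    r2 = model.global_test(n_perm=150, seed=7)
    assert r1.p_value == r2.p_value
    r3 = model.global_test(n_perm=150, seed=8)
    p = max(r1.p_value, 1 / 150)
    assert abs(r3.p_value - r1.p_value) < 3 * math.sqrt(p * (1 - p) / 150) + 1e-9


def test_add_one_correction_variant():
    cohort, table = simple_cohort(400, 6, n_feats=3)
    model = CaseCaseModel(cohort, {"otsu": table})
    plain = model.global_test(n_perm=99, seed=1)
    corrected = model.global_test(n_perm=99, seed=1, add_one=True)
    assert corrected.p_value == pytest.approx(
        (plain.p_value * 99 + 1) / 100)


def test_invalid_permutation_count():
    cohort, table = simple_cohort(200, 0, n_feats=2)
    model = CaseCaseModel(cohort, {"otsu": table})
    with pytest.raises(ValueError):
        model.global_test(n_perm=0)


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

def test_forward_selection_without_candidates_returns_base():
    cohort, table = simple_cohort(800, 1, n_feats=2)
    model = CaseCaseModel(cohort, {"otsu": table})
    sel = model.forward_select("otsu", candidates=[])
    assert sel.selected == []
    assert sel.aic == pytest.approx(sel.base_aic)
    assert {r.term for r in sel.results} == {"pd", "age_dx", "bmi", "hrt"}


def test_forward_selection_finds_true_signal():
    hits = 0
    for seed in range(20):
        cohort, table = simple_cohort(3000, 200 + seed, n_feats=10,
                                      feature_effects={3: math.log(1.5)})
        model = CaseCaseModel(cohort, {"otsu": table})
        sel = model.forward_select("otsu")
        hits += "F4" in sel.selected
    assert hits >= 18


def test_duplicate_candidate_selected_once():
    cohort, table = simple_cohort(2000, 2, n_feats=1,
                                  feature_effects={0: 0.5})
    table["F2"] = table["F1"].copy()
    model = CaseCaseModel(cohort, {"otsu": table})
    sel = model.forward_select("otsu")
    assert sel.selected.count("F1") + sel.selected.count("F2") == 1


# ---------------------------------------------------------------------------
# final model
# ---------------------------------------------------------------------------

def test_final_model_reports_per_sd_odds_ratios():
    table, _ = md.generate_cohort(md.CohortSimParams(n=2500, seed=21))
    model = CaseCaseModel.from_cohort(table)
    res = model.fit_final(features=("F40", "F21"), method="latent")
    terms = [r.term for r in res.results]
    assert terms == ["pd", "age_dx", "bmi", "hrt", "F40", "F21"]
    r40 = res["F40"]
    assert r40.ci_low < r40.effect < r40.ci_high
    assert 0.0 <= r40.p <= 1.0
    text = res.summary()
    assert "F40" in text and "OR" in text


def test_final_model_time_adjustment_adds_covariate():
    table, _ = md.generate_cohort(md.CohortSimParams(n=2000, seed=22))
    model = CaseCaseModel.from_cohort(table)
    res = model.fit_final(features=("F40", "F21"), method="latent",
                          include_time=True)
    assert res.results[-1].term == "months_to_dx"


def test_final_model_null_effects_cover_one():
    covered = 0
    for seed in range(20):
        table, _ = md.generate_cohort(md.CohortSimParams(
            n=1500, beta_f40=0.0, beta_f21=0.0, seed=300 + seed))
        model = CaseCaseModel.from_cohort(table)
        res = model.fit_final(features=("F40", "F21"), method="latent")
        r = res["F40"]
        covered += r.ci_low <= 1.0 <= r.ci_high
    assert covered >= 16      # ~95% nominal coverage


# ---------------------------------------------------------------------------
# tumor size and risk-factor models
# ---------------------------------------------------------------------------

def test_tumor_size_null_feature_covers_zero():
    covered = 0
    for seed in range(20):
        table, _ = md.generate_cohort(md.CohortSimParams(
            n=1500, gamma_sc_f40=0.0, seed=400 + seed))
        res = tumor_size_regression(table, table.f40, "SC")
        covered += res.ci_low <= 0.0 <= res.ci_high
    assert covered >= 16


def test_tumor_size_zero_size_rejected():
    table, _ = md.generate_cohort(md.CohortSimParams(n=200, seed=1))
    table.loc[0, "tumor_size"] = 0.0
    with pytest.raises(ValueError, match="positive"):
        tumor_size_regression(table, table.f40, "all")


def test_tumor_size_empty_stratum_rejected():
    table, _ = md.generate_cohort(md.CohortSimParams(n=200, seed=1))
    table["outcome"] = "SC"
    with pytest.raises(ValueError, match="empty"):
        tumor_size_regression(table, table.f40, "IC")


def test_risk_factor_identity_slope_one():
    table, _ = md.generate_cohort(md.CohortSimParams(n=800, seed=5))
    z, _ = box_cox_standardize(table.f40.to_numpy())
    table["riskcol"] = z
    res = feature_risk_factor_models(table, table.f40, "riskcol")[0]
    assert res.estimate == pytest.approx(1.0, abs=1e-8)


def test_risk_factor_independent_covers_zero():
    table, _ = md.generate_cohort(md.CohortSimParams(n=2000, seed=6))
    res = feature_risk_factor_models(table, table.f40, "bmi")[0]
    assert res.ci_low <= 0.0 <= res.ci_high


def test_risk_factor_single_level_rejected():
    table, _ = md.generate_cohort(md.CohortSimParams(n=200, seed=7))
    table["hrt"] = "no"
    with pytest.raises(ValueError):
        feature_risk_factor_models(table, table.f40, "hrt")


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def test_cohort_summary_structure_and_pvalues():
    table, _ = md.generate_cohort(md.CohortSimParams(
        n=1403, seed=8, missing_rates={"bmi": 0.03, "hrt": 0.05}))
    summary = cohort_summary(table)
    assert {"variable", "level", "ic", "sc", "p", "pct_missing"} <= \
        set(summary.columns)
    ps = summary.p.dropna()
    assert ((ps >= 0) & (ps <= 1)).all()
    hrt_missing = summary[summary.variable == "hrt"].pct_missing.iloc[0]
    assert hrt_missing == pytest.approx(5.0, abs=2.0)


def test_cohort_summary_all_missing_group_rejected():
    table, _ = md.generate_cohort(md.CohortSimParams(n=300, seed=9))
    table.loc[table.outcome == "IC", "bmi"] = np.nan
    with pytest.raises(ValueError):
        cohort_summary(table, variables=[("bmi", "continuous", "mean")])


def test_summarize_counts_percentages_and_chisq():
    out = summarize_counts({"no": (280, 802), "yes": (93, 156)})
    yes = out[out.level == "yes"].iloc[0]
    assert yes.ic_pct == 25 and yes.sc_pct == 16
    assert 0 < yes.p < 1
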