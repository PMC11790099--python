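"""Estimator arithmetic, cross-fitting contracts, oracle checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ehrtrial as et
from ehrtrial.estimators import NuisancePredictions


def _preds(e, mu1=None, mu0=None, clip=(0.01, 0.99)):
    e = np.asarray(e, dtype=float)
    n = len(e)
    mu1 = np.zeros(n) if mu1 is None else np.asarray(mu1, dtype=float)
    mu0 = np.zeros(n) if mu0 is None else np.asarray(mu0, dtype=float)
    return NuisancePredictions(e, mu1, mu0, np.zeros(n, dtype=int), clip, 0)


# --- hand-computed six-patient IPW fixture --------------------------------
# patients: (arm, outcome, propensity)
SIX = dict(
    arm=np.array([1, 1, 1, 0, 0, 0]),
    outcome=np.array([1, 0, 1, 1, 0, 0]),
    e=np.array([0.2, 0.5, 0.8, 0.2, 0.5, 0.8]),
)
# treated weights 1/e = (5, 2, 1.25), sum 8.25, weighted deaths 5+0+1.25
# control weights 1/(1-e) = (1.25, 2, 5), sum 8.25, weighted deaths 1.25
SIX_Y1 = 6.25 / 8.25
SIX_Y0 = 1.25 / 8.25


def test_ipw_matches_hand_computed_fixture():
    est = et.estimate_ipw(_preds(SIX["e"]), SIX["arm"], SIX["outcome"])
    assert est.arm_means[0] == pytest.approx(SIX_Y1, abs=1e-15)
    assert est.arm_means[1] == pytest.approx(SIX_Y0, abs=1e-15)
    assert est.point == pytest.approx(SIX_Y1 - SIX_Y0, abs=1e-15)


def test_ipw_with_uniform_propensity_equals_naive():
    a = np.array([1, 1, 0, 0, 0, 1])
    y = np.array([1, 0, 1, 0, 1, 1])
    ipw = et.estimate_ipw(_preds(np.full(6, 0.5)), a, y)
    naive = et.naive_contrast(a, y)
    assert ipw.point == pytest.approx(naive.point, abs=1e-15)


def test_ipw_rejects_boundary_propensities():
    with pytest.raises(et.PositivityError):
        et.estimate_ipw(_preds([0.0, 0.5, 0.5]), np.array([1, 1, 0]), np.array([1, 0, 1]))


def test_gformula_constant_shift():
    mu0 = np.array([0.1, 0.4, 0.25])
    same = et.estimate_gformula_t(_preds([0.5] * 3, mu1=mu0, mu0=mu0))
    assert same.point == 0.0
    shifted = et.estimate_gformula_t(_preds([0.5] * 3, mu1=mu0 + 0.1, mu0=mu0))
    assert shifted.point == pytest.approx(0.1, abs=1e-12)


def test_transform_estimand_arithmetic():
    vals = et.transform_estimand((0.2, 0.4))
    assert vals["risk_difference"] == pytest.approx(-0.2)
    assert vals["risk_ratio"] == pytest.approx(0.5)
    assert vals["odds_ratio"] == pytest.approx(0.375)
    null = et.transform_estimand((0.3, 0.3))
    assert (null["risk_difference"], null["risk_ratio"], null["odds_ratio"]) == (0.0, 1.0, 1.0)
    assert et.transform_estimand((0.5, 0.5))["odds_ratio"] == 1.0
    with pytest.raises(ValueError, match="boundary"):
        et.transform_estimand((0.0, 0.5))


@settings(max_examples=200, deadline=None)
@given(
    p1=st.floats(min_value=0.01, max_value=0.99),
    p0=st.floats(min_value=0.01, max_value=0.99),
)
def test_estimand_signs_always_agree(p1, p0):
    vals = et.transform_estimand((p1, p0))
    signs = {
        np.sign(vals["risk_difference"]),
        np.sign(np.log(vals["risk_ratio"])),
        np.sign(np.log(vals["odds_ratio"])),
    }
    assert len(signs - {0.0}) <= 1
    assert -1 <= vals["risk_difference"] <= 1
    assert vals["risk_ratio"] > 0 and vals["odds_ratio"] > 0


@settings(max_examples=100, deadline=None)
@given(st.data())
def test_hajek_ipw_is_bounded(data):
    n = data.draw(st.integers(min_value=4, max_value=40))
    a = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    if a.sum() in (0, n):
        a[0], a[-1] = 1, 0
    y = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    e = np.array(
        data.draw(
            st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=n, max_size=n)
        )
    )
    est = et.estimate_ipw(_preds(e), a, y)
    assert -1.0 <= est.point <= 1.0


def test_cross_fitting_requires_at_least_two_folds(small_features, small_cohort):
    cohort, _ = small_cohort
    with pytest.raises(ValueError, match="k_folds"):
        et.fit_nuisances(
            small_features.data.to_numpy(float),
            cohort.table["treated"].to_numpy(),
            cohort.table["outcome"].to_numpy(),
            k_folds=1,
        )


def test_single_arm_training_fold_raises():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 3))
    a = np.zeros(40, dtype=int)
    a[0] = 1  # one treated patient: some training folds have no treated
    y = rng.integers(0, 2, 40)
    with pytest.raises(ValueError, match="single arm|folds"):
        et.fit_nuisances(X, a, y, et.NuisanceSpec(search_budget=1), k_folds=5)


def test_out_of_fold_predictions_cover_everyone(small_features, small_cohort):
    cohort, _ = small_cohort
    preds = et.fit_nuisances(
        small_features.data.to_numpy(float),
        cohort.table["treated"].to_numpy(),
        cohort.table["outcome"].to_numpy(),
        et.NuisanceSpec("ridge_logistic", search_budget=1),
        k_folds=5,
        seed=1,
    )
    assert not np.isnan(preds.e_hat).any()
    assert not np.isnan(preds.mu1).any()
    assert set(np.unique(preds.folds)) == set(range(5))
    preds.validate()


def test_ridge_propensity_tracks_true_propensity():
    """Calibration: cross-fitted ridge propensities sit close to the
    generator's true treatment probabilities."""
    tables, gt = et.simulate(et.SimConfig(n_patients=10000, seed=4))
    cohort, _ = et.build_cohort(tables, et.CohortSpec())
    fm = et.build_features(cohort, tables, strategy="first_and_last")
    preds = et.fit_nuisances(
        fm.data.to_numpy(float),
        cohort.table["treated"].to_numpy(),
        cohort.table["outcome"].to_numpy(),
        et.NuisanceSpec("ridge_logistic", search_budget=1),
        seed=0,
    )
    e_true = (
        gt.table.set_index("patient_id")
        .loc[cohort.table["patient_id"], "propensity"]
        .to_numpy()
    )
    assert np.mean(np.abs(preds.e_hat - e_true)) < 0.04


def test_aipw_with_oracle_nuisances_recovers_null(small_sim, small_cohort):
    tables, gt = small_sim
    cohort, _ = small_cohort
    g = gt.table.set_index("patient_id").loc[cohort.table["patient_id"]]
    preds = _preds(
        np.clip(g["propensity"].to_numpy(), 0.01, 0.99),
        mu1=g["p1"].to_numpy(),
        mu0=g["p0"].to_numpy(),
    )
    a = cohort.table["treated"].to_numpy()
    y = cohort.table["outcome"].to_numpy()
    est = et.estimate_aipw(preds, a, y)
    assert abs(est.point) < 0.05  # n ~ 3,700: a few Monte-Carlo SEs around 0
    assert est.psi is not None and len(est.psi) == len(a)


def test_double_robustness_directions(small_sim, small_cohort, small_features):
    """AIPW survives a constant outcome model (propensity leg intact);
    the T-learner under the same degradation collapses to the naive
    contrast and inherits its confounding bias."""
    tables, _ = small_sim
    cohort, _ = small_cohort
    a = cohort.table["treated"].to_numpy()
    y = cohort.table["outcome"].to_numpy()
    preds = et.fit_nuisances(
        small_features.data.to_numpy(float), a, y,
        et.NuisanceSpec("ridge_logistic", search_budget=1), seed=2,
    )
    broken = et.misspecified_predictions(preds, a, y, "constant_outcome")
    aipw = et.estimate_aipw(broken, a, y)
    tlearner = et.estimate_gformula_t(broken)
    naive = et.naive_contrast(a, y)
    assert tlearner.point == pytest.approx(naive.point, abs=1e-12)
    assert abs(aipw.point) < abs(tlearner.point)


def test_dml_recovers_effect_under_randomization():
    tables, gt = et.simulate(
        et.SimConfig(n_patients=10000, seed=6, confounding_strength=0.0, true_ate_rd=-0.05)
    )
    cohort, _ = et.build_cohort(tables, et.CohortSpec())
    fm = et.build_features(cohort, tables, strategy="first_and_last")
    est = et.estimate_dml(
        fm.data.to_numpy(float),
        cohort.table["treated"].to_numpy(),
        cohort.table["outcome"].to_numpy(),
        et.NuisanceSpec("ridge_logistic", search_budget=1),
        seed=0,
    )
    true_cohort_ate = (
        gt.table.set_index("patient_id").loc[cohort.table["patient_id"], "tau"].mean()
    )
    assert abs(est.point - true_cohort_ate) < 0.035
    assert est.arm_means is None  # partially linear model identifies only the RD


def test_oracle_estimators_converge_with_sample_size():
    """With true nuisances injected, IPW, G-formula and AIPW all shrink
    their error toward the known null as n grows."""
    errors = {n: [] for n in (2_000, 20_000)}
    for n in errors:
        for seed in (0, 1, 2):
            tables, gt = et.simulate(et.SimConfig(n_patients=n, seed=seed))
            cohort, _ = et.build_cohort(tables, et.CohortSpec())
            g = gt.table.set_index("patient_id").loc[cohort.table["patient_id"]]
            preds = _preds(
                np.clip(g["propensity"].to_numpy(), 0.01, 0.99),
                mu1=g["p1"].to_numpy(),
                mu0=g["p0"].to_numpy(),
            )
            a = cohort.table["treated"].to_numpy()
            y = cohort.table["outcome"].to_numpy()
            errs = [
                abs(et.estimate_ipw(preds, a, y).point),
                abs(et.estimate_gformula_t(preds).point),
                abs(et.estimate_aipw(preds, a, y).point),
            ]
            errors[n].append(np.mean(errs))
    assert np.mean(errors[20_000]) < np.mean(errors[2_000])
    assert np.mean(errors[20_000]) < 0.02


def test_dml_estimate_brackets_subgroup_effects():
    """On a heterogeneous-effect simulation the constant-effect DML
    estimate lies between the extreme subgroup true effects."""
    mods = {"septic_shock": -0.05, "age_ge_60": -0.03}
    tables, gt = et.simulate(et.SimConfig(n_patients=10000, seed=17, modifier_effects=mods))
    cohort, _ = et.build_cohort(tables, et.CohortSpec())
    fm = et.build_features(cohort, tables, strategy="first_and_last")
    est = et.estimate_dml(
        fm.data.to_numpy(float),
        cohort.table["treated"].to_numpy(),
        cohort.table["outcome"].to_numpy(),
        et.NuisanceSpec("ridge_logistic", search_budget=1),
        seed=0,
    )
    tau = gt.table.set_index("patient_id").loc[cohort.table["patient_id"], "tau"]
    slack = 0.02  # Monte-Carlo allowance around the subgroup extremes
    assert tau.min() - slack <= est.point <= tau.max() + slack


def test_bootstrap_percentiles_and_degenerate_case():
    res = et.bootstrap_ci(lambda idx: 0.42, n=50, B=50, level=0.95, seed=0)
    assert res.lower == res.upper == 0.42
    assert res.n_effective == 50

    rng_values = {}

    def noisy(idx):
        key = tuple(idx[:3])
        return rng_values.setdefault(key, float(np.mean(idx)) / 50.0)

    res = et.bootstrap_ci(noisy, n=50, B=50, level=0.9, seed=1)
    assert res.lower <= res.upper
    ref_lo, ref_hi = np.percentile(res.estimates, [5, 95])
    assert res.lower == pytest.approx(ref_lo) and res.upper == pytest.approx(ref_hi)


def test_bootstrap_validates_and_counts_failures():
    with pytest.raises(ValueError):
        et.bootstrap_ci(lambda idx: 0.0, n=10, B=1)
    with pytest.raises(ValueError):
        et.bootstrap_ci(lambda idx: 0.0, n=10, B=10, level=1.5)

    def flaky(idx):
        if idx[0] % 2:  # roughly half the replicates degenerate
            raise ValueError("single arm")
        return 0.0

    with pytest.raises(RuntimeError, match="replicates"):
        et.bootstrap_ci(flaky, n=100, B=40, seed=3)


def test_overlap_diagnostic_flags_separable_data():
    rng = np.random.default_rng(0)
    z = rng.normal(size=400)
    X = z.reshape(-1, 1)
    a = (z > 0).astype(int)
    y = rng.integers(0, 2, 400)
    with pytest.warns(RuntimeWarning, match="overlap"):
        preds = et.fit_nuisances(
            X, a, y,
            et.NuisanceSpec("random_forest", fixed_params={"n_estimators": 20, "min_samples_leaf": 5}),
            k_folds=2,
        )
    report = et.overlap_diagnostic(preds, a)
    assert report["flag"]
    assert report["clipped_fraction"] > 0.5


def test_overlap_clean_under_randomization():
    tables, _ = et.simulate(et.SimConfig(n_patients=4000, seed=8, confounding_strength=0.0))
    cohort, _ = et.build_cohort(tables, et.CohortSpec())
    fm = et.build_features(cohort, tables, strategy="last")
    a = cohort.table["treated"].to_numpy()
    preds = et.fit_nuisances(
        fm.data.to_numpy(float), a, cohort.table["outcome"].to_numpy(),
        et.NuisanceSpec("ridge_logistic", search_budget=1), seed=0,
    )
    report = et.overlap_diagnostic(preds, a)
    assert report["clipped_fraction"] < 0.01
    assert not report["flag"]
    lo_t, hi_t = report["range_treated"]
    lo_c, hi_c = report["range_control"]
    assert max(lo_t, lo_c) < min(hi_t, hi_c)  # the supports overlap


def test_pipeline_estimates_are_reproducible(small_sim):
    tables, _ = small_sim
    cfg = et.AnalysisConfig(
        estimator="AIPW",
        nuisance=et.NuisanceSpec("ridge_logistic", search_budget=1),
        n_bootstrap=10,
        seed=5,
    )
    e1, _ = et.estimate_effect(tables, et.CohortSpec(), cfg)
    e2, _ = et.estimate_effect(tables, et.CohortSpec(), cfg)
    assert e1.point == e2.point
    assert e1.ci == e2.ci


def test_bootstrap_with_per_resample_imputation_runs(small_sim):
    tables, _ = small_sim
    cfg = et.AnalysisConfig(
        nuisance=et.NuisanceSpec("ridge_logistic", search_budget=1),
        n_bootstrap=5,
        seed=3,
        refit_imputation_per_resample=True,
    )
    est, _ = et.estimate_effect(tables, et.CohortSpec(), cfg)
    assert est.ci is not None and np.isfinite(est.ci).all()


def test_random_search_runs_and_beats_nothing(small_cohort, small_features):
    """A tiny random-search budget still returns usable cross-fitted
    predictions (hyperparameter selection is exercised end to end)."""
    cohort, _ = small_cohort
    preds = et.fit_nuisances(
        small_features.data.to_numpy(float)[:1500],
        cohort.table["treated"].to_numpy()[:1500],
        cohort.table["outcome"].to_numpy()[:1500],
        et.NuisanceSpec("ridge_logistic", search_budget=3, cv_folds=2),
        k_folds=2,
        seed=0,
    )
    assert ((preds.e_hat > 0) & (preds.e_hat < 1)).all()
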