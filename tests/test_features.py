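"""Aggregation, imputation, encoding and the post-baseline leakage guard."""

import numpy as np
import pandas as pd
import pytest

import ehrtrial as et


def _toy_cohort(toy):
    cohort, _ = et.build_cohort(toy, et.CohortSpec())
    return cohort


@pytest.mark.parametrize(
    "strategy,expected",
    [
        ("last", {"sofa_last": 9.0}),
        ("first", {"sofa_first": 5.0}),
        ("first_and_last", {"sofa_first": 5.0, "sofa_last": 9.0}),
        ("mean", {"sofa_mean": 7.0}),
    ],
)
def test_aggregation_strategies_on_two_readings(toy, strategy, expected):
    # patient 3 has sofa readings (t=0: 5), (t=0.5: 9) before t0=1h
    fm = et.aggregate(_toy_cohort(toy), toy, strategy=strategy)
    row = fm.data.loc[3]
    for col, val in expected.items():
        assert row[col] == val


def test_unknown_strategy_lists_valid_options(toy):
    with pytest.raises(ValueError, match="first_and_last"):
        et.aggregate(_toy_cohort(toy), toy, strategy="median")


def test_post_cutoff_reading_changes_nothing(toy):
    """Adding a measurement after the cutoff leaves the matrix untouched."""
    extra = pd.concat(
        [
            toy.measurements,
            pd.DataFrame(
                {"patient_id": [3], "time_h": [30.0], "variable": ["sofa"], "value": [20.0]}
            ),
        ],
        ignore_index=True,
    )
    with_extra = et.EventTables(toy.static, extra, toy.interventions, toy.outcomes)
    base = et.aggregate(_toy_cohort(toy), toy, strategy="first_and_last")
    plus = et.aggregate(_toy_cohort(with_extra), with_extra, strategy="first_and_last")
    pd.testing.assert_frame_equal(base.data, plus.data)


def test_leakage_guard_holds_on_simulated_data(small_sim, small_cohort):
    """Deleting every post-baseline event never changes the feature matrix."""
    tables, _ = small_sim
    cohort, _ = small_cohort
    t0 = cohort.table.set_index("patient_id")["t0_h"]
    cut = tables.measurements["patient_id"].map(t0)
    truncated_meas = tables.measurements[tables.measurements["time_h"] < cut.fillna(0)]
    cut_iv = tables.interventions["patient_id"].map(t0)
    truncated_iv = tables.interventions[tables.interventions["time_h"] < cut_iv.fillna(np.inf)]
    truncated = et.EventTables(tables.static, truncated_meas, truncated_iv, tables.outcomes)
    full = et.build_features(cohort, tables, strategy="first_and_last")
    trunc = et.build_features(cohort, truncated, strategy="first_and_last")
    pd.testing.assert_frame_equal(full.data, trunc.data)


def test_first_equals_last_for_single_reading(toy):
    fm = et.aggregate(_toy_cohort(toy), toy, strategy="first_and_last")
    row = fm.data.loc[4]  # single pre-cutoff sofa reading of 7
    assert row["sofa_first"] == row["sofa_last"] == 7.0


def test_strategy_changes_columns_not_rows(small_sim, small_cohort):
    tables, _ = small_sim
    cohort, _ = small_cohort
    fms = {s: et.aggregate(cohort, tables, strategy=s) for s in et.AGGREGATION_STRATEGIES}
    idx = [tuple(fm.data.index) for fm in fms.values()]
    assert all(i == idx[0] for i in idx)
    assert len(fms["first_and_last"].data.columns) > len(fms["last"].data.columns)


def test_median_imputation_matches_independent_percentile(small_sim, small_cohort):
    tables, _ = small_sim
    cohort, _ = small_cohort
    raw = et.aggregate(cohort, tables, strategy="last")
    done = et.impute_encode(raw)
    assert not done.data.isna().any().any()
    for col, med in done.medians.items():
        observed = raw.data[col].dropna().to_numpy()
        observed.sort()
        k = len(observed)
        independent = (
            observed[(k - 1) // 2] if k % 2 else (observed[k // 2 - 1] + observed[k // 2]) / 2
        )
        assert med == pytest.approx(independent)


def test_impute_trivial_median():
    fm = et.FeatureMatrix(
        pd.DataFrame({"x": [1.0, np.nan, 3.0]}, index=pd.Index([0, 1, 2], name="patient_id")),
        {"x": "confounder"},
        {"x": "labs"},
        "last",
    )
    out = et.impute_encode(fm)
    assert list(out.data["x"]) == [1.0, 2.0, 3.0]
    assert out.medians == {"x": 2.0}


def test_all_missing_column_raises_by_name():
    fm = et.FeatureMatrix(
        pd.DataFrame({"lactate_last": [np.nan, np.nan]}, index=pd.Index([0, 1], name="patient_id")),
        {"lactate_last": "confounder"},
        {"lactate_last": "labs"},
        "last",
    )
    with pytest.raises(ValueError, match="lactate_last"):
        et.impute_encode(fm)


def test_one_hot_drops_reference_level(toy):
    fm = et.impute_encode(et.aggregate(_toy_cohort(toy), toy, strategy="last"))
    sex_cols = [c for c in fm.data.columns if c.startswith("sex_")]
    assert sex_cols == ["sex_M"]  # two levels -> one indicator
    onehot_groups = [c for c in fm.data.columns if c.startswith("race_")]
    assert (fm.data[onehot_groups].sum(axis=1) <= 1).all()


def test_confounder_subsets_select_by_group(small_features):
    fm = small_features
    socio = et.confounder_subset(fm, "sociodemographic_only")
    assert all(fm.groups[c] == "sociodemographic" for c in socio.data.columns)
    nodrugs = et.confounder_subset(fm, "no_drugs")
    assert not any(c.startswith("drug_") for c in nodrugs.data.columns)
    assert set(et.confounder_subset(fm, "full").data.columns) == set(fm.data.columns)
    with pytest.raises(ValueError, match="confounder set"):
        et.confounder_subset(fm, "everything")


def test_feature_matrix_round_trip(tmp_path, small_features):
    fm = small_features
    fm.to_csv(tmp_path / "fm.csv", tmp_path / "fm.json")
    back = et.FeatureMatrix.from_csv(tmp_path / "fm.csv", tmp_path / "fm.json")
    assert back.strategy == fm.strategy
    assert back.roles == fm.roles
    assert np.allclose(back.data.to_numpy(), fm.data.to_numpy())
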