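import numpy as np
import pandas as pd
import pytest

from sulfurflux.metabolome_stats import (
    SingularDesignError,
    classify_trajectory,
    fit_trajectory_model,
    interaction_effect,
    interaction_screen,
    levodopa_auc,
    medication_change_model,
    medication_global_test,
    preprocess,
    trajectory_screen,
    updrs_association,
    updrs_prediction,
)
from sulfurflux.synthetic_data import (
    CohortSpec,
    generate_longitudinal_metabolome,
    generate_updrs_scores,
)


def _cohort(seed, **kwargs):
    defaults = dict(trajectory_assignments={"m1": "null"}, include_levodopa=True)
    defaults.update(kwargs)
    return generate_longitudinal_metabolome(CohortSpec(seed=seed, **defaults))


# ---------------------------------------------------------- preprocess ----

def test_preprocess_no_outliers_is_identity(cohort_table):
    # generator output rarely contains 4-SD outliers; check idempotence
    once = preprocess(cohort_table)
    twice = preprocess(once)
    assert len(twice) == len(once)


def test_preprocess_removes_planted_outlier(cohort_table):
    tab = cohort_table.copy()
    target = tab[tab["metabolite_id"] == "serine"].index[0]
    col = tab.columns.get_loc("log_concentration")
    sd = tab[tab["metabolite_id"] == "serine"]["log_concentration"].std()
    tab.iloc[target, col] = tab["log_concentration"].mean() + 8 * sd
    cleaned = preprocess(tab)
    assert len(cleaned) == len(tab) - 1


# ------------------------------------------------------- trajectories ----

def test_trajectory_null_size_calibrated():
    """Global Wald test size stays near the nominal 5% under the null."""
    n_sims = 300
    rejections = 0
    for seed in range(n_sims):
        tab = _cohort(3000 + seed, include_levodopa=False)
        fit = fit_trajectory_model(tab, "m1")
        rejections += fit.global_p < 0.05
    assert abs(rejections / n_sims - 0.05) <= 0.03


@pytest.mark.parametrize(
    "ttype,expected",
    [("type1", "type1"), ("type2", "type2"), ("type3", "type3")],
)
def test_trajectory_templates_recovered_and_classified(ttype, expected):
    labels = []
    coefs = []
    for seed in range(40):
        tab = _cohort(
            4000 + seed,
            trajectory_assignments={"m1": ttype},
            include_levodopa=False,
        )
        fit = fit_trajectory_model(tab, "m1")
        labels.append(classify_trajectory(fit, fdr_gate=False))
        coefs.append((fit.beta_group, fit.beta_gw1, fit.beta_gw2))
    coefs = np.array(coefs)
    delta = 0.4
    truth = {
        "type1": (delta, 0, 0),
        "type2": (0, delta, 2 * delta),
        "type3": (delta, -delta, -2 * delta),
    }[ttype]
    assert np.allclose(coefs.mean(axis=0), truth, atol=0.06)
    # classification is right in the clear majority of replicates
    assert labels.count(expected) / len(labels) >= 0.7


def test_single_group_raises():
    tab = _cohort(1)
    with pytest.raises(SingularDesignError):
        fit_trajectory_model(tab[tab["group"] == "PD"], "m1")


def test_trajectory_screen_fdr_gate(cohort_table):
    fits = trajectory_screen(preprocess(cohort_table))
    by_met = {f.metabolite_id: f for f in fits}
    assert by_met["homoserine"].type_label == "type1"
    assert by_met["methionine"].type_label == "type3"
    assert by_met["cystathionine"].type_label == "type2"


# -------------------------------------------------------- interactions ----

def test_interaction_recovery_mean():
    ests = [
        interaction_effect(
            preprocess(_cohort(5000 + s, interaction_effects=[("a", "b", -0.36)])),
            "a", "b",
        ).estimate
        for s in range(40)
    ]
    assert np.mean(ests) == pytest.approx(-0.36, abs=0.06)


def test_interaction_screen_pair_count():
    tab = _cohort(
        7,
        trajectory_assignments={f"m{i}": "null" for i in range(5)},
        include_levodopa=True,
    )
    out = interaction_screen(tab)
    # 6 metabolites (5 declared + 3omd): 30 ordered pairs
    assert len(out) == 30


def test_interaction_screen_null_fdr_control():
    discoveries = 0
    n_sims = 30
    for seed in range(n_sims):
        tab = _cohort(
            6000 + seed,
            trajectory_assignments={"a": "null", "b": "null", "c": "null"},
            include_levodopa=False,
        )
        out = interaction_screen(tab, adjust_medication=False)
        discoveries += int((out["q"] < 0.05).sum())
    assert discoveries / n_sims <= 0.3  # near-zero false pairs per screen


def test_interaction_insufficient_cases_raises(cohort_table):
    head = cohort_table.head(40)  # too few complete subject-waves
    with pytest.raises((ValueError, KeyError)):
        interaction_effect(head, "sm1", "sm2")


# ---------------------------------------------------------- medication ----

def test_medication_slope_recovered_single_cohort(cohort_table):
    out = medication_change_model(preprocess(cohort_table), metabolites=["3omd"])
    est = out["estimate"].iloc[0]
    assert est == pytest.approx(0.614, abs=0.1)


def test_medication_change_needs_consecutive_waves(cohort_table):
    tab = cohort_table[cohort_table["wave"] == "BL"]
    out = medication_change_model(tab, metabolites=["3omd"])
    assert len(out) == 0  # a single wave yields no change records


def test_medication_global_null_and_power():
    null_sig = 0
    power_joint = 0
    for seed in range(25):
        tab = _cohort(8000 + seed)
        null = medication_global_test(tab, metabolites=["m1"])
        if len(null):
            null_sig += int(null["p"].iloc[0] < 0.05)
        hit = medication_global_test(tab, metabolites=["3omd"])
        power_joint += int(hit["p"].iloc[0] < 0.05)
    assert null_sig <= 5
    assert power_joint >= 23  # dose-driven 3-OMD is detected essentially always


def test_duplicated_predictor_raises(cohort_table):
    tab = preprocess(cohort_table).copy()
    tab["equivalent_dose_other"] = tab["levodopa_dose"]  # identical predictors
    with pytest.raises(SingularDesignError):
        medication_global_test(tab, metabolites=["3omd"]).pipe(lambda x: x)


# --------------------------------------------------------------- UPDRS ----

def test_updrs_association_sign_recovery(cohort_table):
    tab = preprocess(cohort_table)
    ests = []
    for seed in range(10):
        scores = generate_updrs_scores(tab, effects={"serine": 2.0}, seed=seed)
        out = updrs_association(tab, scores, "III", metabolites=["serine"])
        ests.append(out["estimate"].iloc[0])
    assert np.mean(ests) == pytest.approx(2.0, abs=0.8)
    assert np.mean(np.array(ests) > 0) >= 0.9


def test_updrs_ordinal_scale_runs(cohort_table):
    tab = preprocess(cohort_table)
    scores = generate_updrs_scores(tab, seed=3)
    out = updrs_association(tab, scores, "II", metabolites=["serine"])
    assert len(out) == 1 and 0 <= out["p"].iloc[0] <= 1


def test_updrs_constant_score_rejected(cohort_table):
    tab = preprocess(cohort_table)
    scores = generate_updrs_scores(tab, seed=3)
    scores["updrs_total"] = 7.0
    with pytest.raises(ValueError, match="no variation"):
        updrs_association(tab, scores, "total", metabolites=["serine"])


def test_updrs_prediction_family_size(cohort_table):
    tab = preprocess(cohort_table)
    scores = generate_updrs_scores(tab, seed=4)
    out = updrs_prediction(
        tab, scores, ["serine", "homoserine", "methionine", "cystathionine",
                      "sm1"],
    )
    assert len(out) == 15  # 5 metabolites x 3 lags


# ----------------------------------------------------------------- AUC ----

def test_levodopa_auc_is_perfect_with_generator_separation(cohort_table):
    assert levodopa_auc(preprocess(cohort_table)) == 1.0


def test_auc_invariant_under_monotone_transform(cohort_table):
    tab = preprocess(cohort_table)
    transformed = tab.copy()
    mask = transformed["metabolite_id"] == "3omd"
    transformed.loc[mask, "log_concentration"] = np.exp(
        transformed.loc[mask, "log_concentration"] / 3.0
    )
    assert levodopa_auc(transformed) == levodopa_auc(tab)


def test_auc_near_half_when_signal_removed(cohort_table):
    tab = cohort_table.copy()
    rng = np.random.default_rng(0)
    mask = tab["metabolite_id"] == "3omd"
    tab.loc[mask, "log_concentration"] = rng.normal(size=mask.sum())
    assert abs(levodopa_auc(tab) - 0.5) < 0.25


def test_auc_requires_both_classes(cohort_table):
    tab = cohort_table[cohort_table["levodopa_dose"] > 0]
    with pytest.raises(ValueError):
        levodopa_auc(tab)
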