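import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sulfurflux.community_builder import Diet, apply_diet_standalone
from sulfurflux.fba_engine import fba
from sulfurflux.recon_core import models_equal
from sulfurflux.synthetic_data import (
    KEYSTONES,
    MUCIN_DEGRADER,
    CohortSpec,
    GenerationError,
    PanelSpec,
    SurvivalSpec,
    generate_abundance_profiles,
    generate_coverage_table,
    generate_longitudinal_metabolome,
    generate_strain_panel,
    generate_survival_cohort,
)


# ---------------------------------------------------------------- panel ----

def test_single_keystone_panel_grows():
    panel = generate_strain_panel(PanelSpec(0, True, False, seed=1))
    assert len(panel) == 1
    assert panel[0].strain_id == MUCIN_DEGRADER


def test_panel_sulfur_content(panel):
    assert len(panel) == 5
    sulfurous = [
        r.strain_id for r in panel if any(m.is_sulfur for m in r.metabolites)
    ]
    assert sorted(sulfurous) == sorted(KEYSTONES)


def test_empty_panel_spec_rejected():
    with pytest.raises(ValueError):
        PanelSpec(0, False, False)


def test_mucin_degrader_secretes_methionine(panel):
    recon = next(r for r in panel if r.strain_id == MUCIN_DEGRADER)
    constrained = apply_diet_standalone(
        recon, Diet("d", {"glc_D": 20.0, "asp_L": 5.0, "cys_L": 2.0})
    )
    sol = fba(constrained, "EX_met_L", "max")
    assert sol.ok and sol.objective_value > 0


def test_growth_self_check_enforced(panel):
    with pytest.raises(GenerationError):
        generate_strain_panel(PanelSpec(1, True, True, seed=0), Diet("empty", {}))


def test_panel_deterministic(panel):
    again = generate_strain_panel(PanelSpec(3, True, True, seed=1))
    for a, b in zip(panel, again):
        assert models_equal(a, b)


# ----------------------------------------------------------- abundances ----

def test_profiles_sum_to_one_and_deterministic(panel):
    p1, g1 = generate_abundance_profiles(panel, 5, 5, 0.7, seed=9)
    p2, g2 = generate_abundance_profiles(panel, 5, 5, 0.7, seed=9)
    for a, b in zip(p1, p2):
        assert a.abundances == b.abundances
        assert sum(a.abundances.values()) == pytest.approx(1.0, abs=1e-9)
    assert (g1 == g2).all()


def test_null_shift_equal_expected_abundance(panel):
    profiles, groups = generate_abundance_profiles(panel, 400, 400, 0.0, seed=3)
    key = np.array(
        [sum(p.abundances[k] for k in KEYSTONES) for p in profiles]
    )
    g = (groups.to_numpy() == "PD")
    _, p = stats.ttest_ind(key[g], key[~g], equal_var=False)
    assert p > 0.01  # no systematic difference under the null


def test_keystone_shift_detected_in_most_seeds(panel):
    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        profiles, groups = generate_abundance_profiles(panel, 200, 200, 0.7, seed=seed)
        key = np.array(
            [sum(p.abundances[k] for k in KEYSTONES) for p in profiles]
        )
        g = (groups.to_numpy() == "PD")
        _, p = stats.ttest_ind(
            key[g], key[~g], equal_var=False, alternative="greater"
        )
        hits += p < 0.05
    assert hits / n_seeds >= 0.95


def test_empty_panel_rejected():
    with pytest.raises(ValueError):
        generate_abundance_profiles([], 2, 2)


# ------------------------------------------------------------- coverage ----

def test_coverage_dropout_fraction(panel):
    cov = generate_coverage_table(panel, 200, dropout_rate=0.5, seed=4)
    vals = cov.to_numpy().ravel()
    assert (vals >= 0).all()
    n_below = int((vals < 0.1).sum())
    assert 450 <= n_below <= 550  # 1000 entries, binomial(0.5)


def test_zero_dropout_keeps_all_strains(panel):
    from sulfurflux.community_builder import coverage_to_abundance

    cov = generate_coverage_table(panel, 10, dropout_rate=0.0, seed=4)
    for _, row in cov.iterrows():
        assert len(coverage_to_abundance(row.to_dict())) == len(panel)


# ------------------------------------------------------------ metabolome ----

def test_metabolome_shape_and_determinism(cohort_table):
    spec = CohortSpec(
        trajectory_assignments={
            "homoserine": "type1",
            "cystathionine": "type2",
            "methionine": "type3",
            "serine": "null",
        },
        interaction_effects=[("sm1", "sm2", -0.53)],
        include_levodopa=True,
        seed=11,
    )
    again = generate_longitudinal_metabolome(spec)
    pd.testing.assert_frame_equal(cohort_table, again)
    # one record per subject x wave x metabolite
    assert not cohort_table.duplicated(
        ["subject_id", "wave", "metabolite_id"]
    ).any()
    assert len(cohort_table) == 60 * 3 * 7


def test_unknown_trajectory_label_rejected():
    with pytest.raises(ValueError, match="unknown trajectory"):
        CohortSpec(trajectory_assignments={"x": "type9"})


def test_levodopa_fold_change_range(cohort_table):
    omd = cohort_table[cohort_table["metabolite_id"] == "3omd"]
    takers = omd[omd["levodopa_dose"] > 0]
    folds = np.exp(0.614 * takers["levodopa_dose"])
    assert folds.min() >= 10.0 - 1e-9
    assert folds.max() <= 600.0 + 1e-9
    # baseline is drug-naive
    assert (omd[omd["wave"] == "BL"]["levodopa_dose"] == 0).all()


def test_controls_receive_no_levodopa(cohort_table):
    ctrl = cohort_table[cohort_table["group"] == "control"]
    assert (ctrl["levodopa_dose"] == 0).all()


def test_interaction_predictor_response_constraints():
    with pytest.raises(ValueError):
        CohortSpec(interaction_effects=[("a", "a", 0.5)])
    with pytest.raises(ValueError):
        CohortSpec(interaction_effects=[("a", "b", 0.5), ("a", "c", 0.2)])
    with pytest.raises(ValueError):
        CohortSpec(interaction_effects=[("a", "b", 0.5), ("b", "c", 0.2)])


# -------------------------------------------------------------- survival ----

def test_survival_event_calibration():
    df = generate_survival_cohort(SurvivalSpec(seed=7))
    assert len(df) == 10034
    assert 133 <= int(df["event"].sum()) <= 181  # target 157 +- 15%


def test_survival_null_hazard_recovers_unit_hr():
    from sulfurflux.incidence_cox import cox_per_sd

    hrs = []
    for seed in range(40):
        df = generate_survival_cohort(
            SurvivalSpec(n_subjects=2500, target_events=150,
                         log_hazard_per_sd=0.0, seed=seed)
        )
        df["log_crp"] = np.log(df["crp"])
        hrs.append(
            cox_per_sd(df, "exposure", ("age", "sex", "bmi", "smoking", "log_crp")).hr
        )
    assert 0.97 <= float(np.mean(hrs)) <= 1.03


def test_doubling_n_roughly_doubles_events():
    e1 = generate_survival_cohort(
        SurvivalSpec(n_subjects=3000, target_events=100, seed=8)
    )["event"].sum()
    # same hazard scale: calibrate on 3000, then draw 6000 with doubled target
    e2 = generate_survival_cohort(
        SurvivalSpec(n_subjects=6000, target_events=200, seed=8)
    )["event"].sum()
    assert 1.6 <= e2 / e1 <= 2.4


def test_infeasible_event_target_rejected():
    with pytest.raises(ValueError):
        SurvivalSpec(n_subjects=100, target_events=100)
    with pytest.raises(GenerationError):
        generate_survival_cohort(
            SurvivalSpec(n_subjects=100, target_events=99,
                         max_followup_years=0.001, seed=0)
        )
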