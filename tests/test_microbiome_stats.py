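import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats, special

from sulfurflux.microbiome_stats import (
    bh_fdr,
    fisher_exact_enumeration,
    fractional_regression,
    reaction_abundances,
    secretion_group_test,
    sulfur_enrichment,
    variance_explained,
)


# ------------------------------------------------------ reaction abundances

def test_reaction_in_all_strains_has_abundance_one(panel, profiles_and_groups):
    profiles, _ = profiles_and_groups
    out = reaction_abundances(panel, profiles, ["BIOMASS"])
    assert np.allclose(out["abundance"], 1.0)


def test_keystone_reaction_abundance_equals_keystone_abundance(
    panel, profiles_and_groups
):
    profiles, _ = profiles_and_groups
    out = reaction_abundances(panel, profiles, ["METS"])
    for prof in profiles:
        ab = out[out["subject_id"] == prof.subject_id]["abundance"].iloc[0]
        assert ab == pytest.approx(prof.abundances["mucin_degrader"])


def test_carriage_partition_conserves_abundance(panel, profiles_and_groups):
    """Carriers + non-carriers of any reaction partition each community."""
    profiles, _ = profiles_and_groups
    out = reaction_abundances(panel, profiles, ["DSR"])
    for prof in profiles:
        ab = out[out["subject_id"] == prof.subject_id]["abundance"].iloc[0]
        non_carriers = sum(
            a for s, a in prof.abundances.items() if s != "taurine_respirer"
        )
        assert ab + non_carriers == pytest.approx(1.0, abs=1e-9)


def test_unknown_reaction_rejected(panel, profiles_and_groups):
    profiles, _ = profiles_and_groups
    with pytest.raises(KeyError):
        reaction_abundances(panel, profiles, ["NOT_A_REACTION"])


# ------------------------------------------------- fractional regression --

def test_two_point_closed_form():
    y = np.array([0.8] * 6 + [0.2] * 6)
    group = np.array([1] * 6 + [0] * 6)
    res = fractional_regression(y, group, n_boot=50, seed=1)
    assert res.estimate == pytest.approx(2 * np.log(4), abs=1e-6)


def test_identical_groups_give_unit_odds_ratio():
    y = np.array([0.3, 0.5, 0.7, 0.3, 0.5, 0.7])
    group = np.array([1, 1, 1, 0, 0, 0])
    res = fractional_regression(y, group, n_boot=200, seed=2)
    assert res.estimate == pytest.approx(0.0, abs=1e-8)
    assert res.p > 0.5


def test_degenerate_constant_response():
    res = fractional_regression(
        np.full(10, 0.4), np.array([1] * 5 + [0] * 5), n_boot=10, seed=0
    )
    assert res.estimate == 0.0 and res.p == 1.0


def test_out_of_range_response_rejected():
    with pytest.raises(ValueError):
        fractional_regression(np.array([0.5, 1.2]), np.array([0, 1]))


def test_bootstrap_reproducible_under_seed():
    rng = np.random.default_rng(0)
    y = np.clip(rng.beta(2, 5, 40), 1e-6, 1 - 1e-6)
    group = rng.integers(0, 2, 40)
    a = fractional_regression(y, group, n_boot=100, seed=5)
    b = fractional_regression(y, group, n_boot=100, seed=5)
    assert (a.se, a.ci_low, a.ci_high) == (b.se, b.ci_low, b.ci_high)


def test_keystone_abundance_group_shift_detected(panel):
    """At the reported group means (0.20% vs 0.34%) and sample sizes (31/28),
    the fractional regression flags the keystone in most replicates."""
    from sulfurflux.synthetic_data import generate_abundance_profiles

    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        profiles, groups = generate_abundance_profiles(
            panel, 31, 28, keystone_shift=0.7, seed=seed
        )
        y = np.array([p.abundances["taurine_respirer"] for p in profiles])
        res = fractional_regression(y, groups.to_numpy(), n_boot=200, seed=seed)
        hits += (res.p < 0.05) and (res.estimate > 0)
    assert hits / n_seeds >= 0.8


# ------------------------------------------------------ secretion tests --

def _toy_potentials(seed, shift=1.0):
    rng = np.random.default_rng(seed)
    n = 30
    group = pd.Series(
        ["PD"] * (n // 2) + ["control"] * (n // 2),
        index=[f"S{i}" for i in range(n)], name="group",
    )
    base = rng.lognormal(0, 0.5, n) * np.where(group == "PD", shift, 1.0)
    pots = pd.DataFrame({"met_L": base, "flat": np.zeros(n)}, index=group.index)
    return pots, group


def test_secretion_group_shift_recovered():
    pots, group = _toy_potentials(3, shift=2.0)
    out = secretion_group_test(pots, group, n_boot=300, seed=1)
    row = out[out["metabolite"] == "met_L"].iloc[0]
    assert row["estimate"] > 0 and row["p"] < 0.05
    # all-zero metabolite is skipped with a log entry
    assert "flat" not in set(out["metabolite"])


def test_secretion_null_calibration():
    sig = 0
    n_perm = 60
    for seed in range(n_perm):
        pots, group = _toy_potentials(100 + seed, shift=1.0)
        out = secretion_group_test(
            pots[["met_L"]], group, n_boot=200, seed=seed
        )
        sig += int(out["p"].iloc[0] < 0.05)
    assert sig / n_perm <= 0.15  # size near nominal under the null


def test_secretion_ci_reproducible():
    pots, group = _toy_potentials(9, shift=1.5)
    a = secretion_group_test(pots, group, n_boot=200, seed=4)
    b = secretion_group_test(pots, group, n_boot=200, seed=4)
    pd.testing.assert_frame_equal(a, b)


# ------------------------------------------------------ variance explained

def test_perfect_linear_fit():
    x = np.linspace(1, 5, 30)
    out = variance_explained(x, 2.0 + 3.0 * x)
    assert out["r2"] == pytest.approx(1.0, abs=1e-9)


def test_independent_noise_low_r2():
    rng = np.random.default_rng(0)
    r2s = [
        variance_explained(rng.normal(0, 1, 59), rng.normal(0, 1, 59))["r2"]
        for _ in range(50)
    ]
    assert float(np.mean(r2s)) < 0.15


def test_fp_power_selection_consistency():
    rng = np.random.default_rng(1)
    hits = 0
    n_sims = 50
    for _ in range(n_sims):
        x = rng.uniform(0.5, 4.0, 80)
        y = 2.0 * x ** (-0.5) + rng.normal(0, 0.02, 80)
        out = variance_explained(x, y)
        hits += -0.5 in out["powers"]
    assert hits / n_sims >= 0.7


def test_constant_predictor_gives_zero():
    out = variance_explained(np.full(12, 3.0), np.arange(12.0))
    assert out["r2"] == 0.0


def test_too_few_subjects_rejected():
    with pytest.raises(ValueError):
        variance_explained(np.arange(5.0), np.arange(5.0))


# ------------------------------------------------------------- Fisher ----

def test_fisher_small_table_enumeration():
    assert fisher_exact_enumeration([[2, 0], [0, 2]]) == pytest.approx(1 / 3)


def test_no_significant_metabolites_p_one():
    out = sulfur_enrichment({"a": 0.5, "b": 0.9}, {"a": True, "b": False})
    assert out["p"] == pytest.approx(1.0)


def test_fisher_matches_scipy_on_all_small_tables():
    """Enumeration equals the closed-form hypergeometric test for every 2x2
    table with total n <= 20 (plus a sample of larger tables up to n = 40)."""
    def check(t):
        ours = fisher_exact_enumeration(t)
        ref = stats.fisher_exact(t, alternative="two-sided")[1]
        assert ours == pytest.approx(ref, abs=1e-9), t

    for n in range(1, 21):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    check([[a, b], [c, d]])
    rng = np.random.default_rng(0)
    for _ in range(300):
        t = rng.multinomial(int(rng.integers(21, 41)), [0.25] * 4).reshape(2, 2)
        check(t.tolist())


def test_enrichment_on_screen_counts():
    """5/10 sulfur vs 6/161 non-sulfur significant at p < 0.01: strong
    enrichment by the exact test."""
    p_values = {}
    sulfur = {}
    for i in range(10):
        p_values[f"s{i}"] = 0.001 if i < 5 else 0.5
        sulfur[f"s{i}"] = True
    for i in range(161):
        p_values[f"n{i}"] = 0.001 if i < 6 else 0.5
        sulfur[f"n{i}"] = False
    out = sulfur_enrichment(p_values, sulfur, alpha=0.01)
    assert out["table"] == [[5, 5], [6, 155]]
    ref = stats.fisher_exact([[5, 5], [6, 155]])[1]
    assert out["p"] == pytest.approx(ref, abs=1e-9)
    assert out["p"] < 0.01


def test_enrichment_empty_rejected():
    with pytest.raises(ValueError):
        sulfur_enrichment({}, {})


# ----------------------------------------------------------------- BH ----

def test_bh_single_p_identity():
    assert bh_fdr([0.03])[0] == pytest.approx(0.03)


def test_bh_step_up_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_declared_family_size():
    # with family 8 and 4 observed tests: q = p * 8 / rank, step-up
    q = bh_fdr([0.01, 0.02, 0.03, 0.04], family_size=8)
    assert np.allclose(q, [0.08, 0.08, 0.08, 0.08])
    with pytest.raises(ValueError):
        bh_fdr([0.1, 0.2], family_size=1)


def test_bh_controls_fdr_on_uniform_nulls():
    rng = np.random.default_rng(42)
    fdp = []
    for _ in range(500):
        p = rng.uniform(size=50)
        rejected = bh_fdr(p) < 0.05
        fdp.append(rejected.mean() > 0)  # all nulls: any rejection is false
    assert float(np.mean(fdp)) <= 0.07
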