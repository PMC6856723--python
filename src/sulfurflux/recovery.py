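"""Parameter-recovery simulation protocols.

Each protocol embeds a published effect size as generator truth, replays the
corresponding analysis on replicate synthetic cohorts, and reports the mean
recovered estimate.  They validate that the analysis stack is unbiased under
the study conditions (cohort sizes, wave structure, variance components) the
generators emulate.
"""

from __future__ import annotations

import numpy as np

from . import incidence_cox, metabolome_stats, synthetic_data


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def recover_interaction(
    beta: float,
    n_reps: int = 200,
    n_cases: int = 30,
    n_controls: int = 30,
    adjust_medication: bool = True,
    seed: int = 0,
) -> dict:
    """Mean recovered metabolite-by-group interaction coefficient.

    Each replicate simulates a 3-wave case/control cohort with ``beta``
    embedded between a metabolite pair, refits the interaction mixed model,
    and contributes one estimate.
    """
    seeds = _spawn_seeds(seed, n_reps)
    ests = []
    for s in seeds:
        spec = synthetic_data.CohortSpec(
            n_cases=n_cases,
            n_controls=n_controls,
            interaction_effects=[("resp", "pred", beta)],
            include_levodopa=adjust_medication,
            seed=s,
        )
        table = metabolome_stats.preprocess(
            synthetic_data.generate_longitudinal_metabolome(spec)
        )
        r = metabolome_stats.interaction_effect(
            table, "resp", "pred", adjust_medication=adjust_medication
        )
        ests.append(r.estimate)
    ests = np.asarray(ests)
    return {
        "mean": float(ests.mean()),
        "mc_se": float(ests.std(ddof=1) / np.sqrt(len(ests))),
        "n_reps": n_reps,
        "truth": beta,
    }


def recover_medication_slope(
    slope: float = synthetic_data.LEVODOPA_SLOPE,
    n_reps: int = 200,
    n_cases: int = 30,
    seed: int = 0,
) -> dict:
    """Mean recovered change-on-change dosage slope for 3-OMD."""
    seeds = _spawn_seeds(seed, n_reps)
    ests = []
    for s in seeds:
        spec = synthetic_data.CohortSpec(
            n_cases=n_cases,
            n_controls=0,
            trajectory_assignments={},
            include_levodopa=True,
            levodopa_slope=slope,
            seed=s,
        )
        table = metabolome_stats.preprocess(
            synthetic_data.generate_longitudinal_metabolome(spec)
        )
        out = metabolome_stats.medication_change_model(table, metabolites=["3omd"])
        ests.append(float(out["estimate"].iloc[0]))
    ests = np.asarray(ests)
    return {
        "mean": float(ests.mean()),
        "mc_se": float(ests.std(ddof=1) / np.sqrt(len(ests))),
        "n_reps": n_reps,
        "truth": slope,
    }


def recover_cox_hr(
    hr: float = 0.80,
    n_reps: int = 100,
    n_subjects: int = 10034,
    target_events: int = 157,
    seed: int = 0,
) -> dict:
    """Mean recovered per-SD hazard ratio from adjusted Cox fits."""
    seeds = _spawn_seeds(seed, n_reps)
    hrs = []
    for s in seeds:
        df = synthetic_data.generate_survival_cohort(
            synthetic_data.SurvivalSpec(
                n_subjects=n_subjects,
                target_events=target_events,
                log_hazard_per_sd=float(np.log(hr)),
                seed=s,
            )
        )
        df["log_crp"] = np.log(df["crp"])
        res = incidence_cox.cox_per_sd(
            df, "exposure", ("age", "sex", "bmi", "smoking", "log_crp")
        )
        hrs.append(res.hr)
    hrs = np.asarray(hrs)
    return {
        "mean": float(hrs.mean()),
        "mc_se": float(hrs.std(ddof=1) / np.sqrt(len(hrs))),
        "n_reps": n_reps,
        "truth": hr,
    }


def levodopa_auc_protocol(n_cases: int = 30, seed: int = 0) -> float:
    """ROC AUC of 3-OMD for follow-up levodopa intake on one simulated
    case wave (fold-change log-uniform on [10, 600])."""
    spec = synthetic_data.CohortSpec(
        n_cases=n_cases,
        n_controls=0,
        trajectory_assignments={},
        include_levodopa=True,
        seed=seed,
    )
    table = synthetic_data.generate_longitudinal_metabolome(spec)
    return metabolome_stats.levodopa_auc(table)
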