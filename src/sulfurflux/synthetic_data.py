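"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions end to end:

* a toy strain panel with two keystone archetypes — a mucin-degrader carrying
  the aspartate -> homoserine -> methionine chain, cysteine/H2S lysis and an
  assimilatory sulfite reductase (EC 1.8.2.2), emulating *A. muciniphila*;
  and a taurine-respirer deconjugating taurocholate and dissimilating taurine
  to sulfite and hydrogen sulfide (EC 1.8.7.1), emulating *B. wadsworthia* —
  plus generic glucose-fermenting background strains with no sulfur reactions;
* group-shifted Dirichlet relative-abundance profiles (keystones enriched in
  cases) and subject x strain coverage tables feeding the 0.1 detection
  threshold;
* three-wave case/control longitudinal metabolomes with the three disease
  trajectory templates, embedded metabolite-by-group interaction effects,
  and levodopa dosing with 10-600-fold 3-O-methyldopa (3-OMD) elevation in
  takers;
* large survival cohorts with rare incident events for per-SD Cox recovery.

All generators are deterministic under their integer ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_builder import (
    AbundanceProfile,
    Diet,
    TOY_EUROPEAN_DIET,
    apply_diet_standalone,
)
from .fba_engine import fba
from .recon_core import Metabolite, Reaction, Reconstruction

MUCIN_DEGRADER = "mucin_degrader"
TAURINE_RESPIRER = "taurine_respirer"
KEYSTONES = (MUCIN_DEGRADER, TAURINE_RESPIRER)

WAVES = ("BL", "FU1", "FU2")

#: trajectory templates on (group, group x FU1, group x FU2), log scale
TRAJECTORY_TEMPLATES = {
    "type1": (1.0, 0.0, 0.0),
    "type2": (0.0, 1.0, 2.0),
    "type3": (1.0, -1.0, -2.0),
    "null": (0.0, 0.0, 0.0),
}

LEVODOPA_FOLD_RANGE = (10.0, 600.0)
LEVODOPA_SLOPE = 0.614  # log-concentration change in 3-OMD per dosage unit


class GenerationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# strain panel
# --------------------------------------------------------------------------

@dataclass
class PanelSpec:
    n_background_strains: int = 3
    include_mucin_degrader: bool = True
    include_taurine_respirer: bool = True
    seed: int = 0

    def __post_init__(self):
        total = (
            self.n_background_strains
            + int(self.include_mucin_degrader)
            + int(self.include_taurine_respirer)
        )
        if total < 1:
            raise ValueError("panel must contain at least one strain")


_SULFUR_METS = {"cys_L", "cyst_L", "hcys_L", "met_L", "h2s", "so3", "taur",
                "tchola", "cgly"}


def _met(mid: str, name: str = "") -> Metabolite:
    return Metabolite(mid, "c", name or mid, mid in _SULFUR_METS)


def _rxn(rid, stoich, lb=0.0, ub=1000.0, ec=()):
    return Reaction(rid, stoich, lb, ub, list(ec))


def _exchanges(met_ids):
    return [
        Reaction(f"EX_{m}", {m: -1.0}, -1000.0, 1000.0) for m in met_ids
    ]


def _mucin_degrader() -> Reconstruction:
    mets = [_met(m) for m in (
        "glc_D", "ac", "asp_L", "aspsa", "hom_L", "cys_L", "cyst_L",
        "hcys_L", "met_L", "asn_L", "h2s", "so3", "gly", "cgly", "biomass",
    )]
    rxns = [
        _rxn("BIOMASS", {"glc_D": -1.0, "biomass": 1.0}),
        _rxn("FERM_glc", {"glc_D": -1.0, "ac": 2.0}),
        _rxn("ASPK", {"asp_L": -1.0, "aspsa": 1.0}, ec=["2.7.2.4"]),
        _rxn("HSDH", {"aspsa": -1.0, "hom_L": 1.0}, ec=["1.1.1.3"]),
        _rxn("SHSL", {"hom_L": -1.0, "cys_L": -1.0, "cyst_L": 1.0}, ec=["2.5.1.48"]),
        _rxn("CYSTL", {"cyst_L": -1.0, "hcys_L": 1.0}, ec=["4.4.1.8"]),
        _rxn("METS", {"hcys_L": -1.0, "met_L": 1.0}, ec=["2.1.1.13"]),
        _rxn("CYSDS", {"cys_L": -1.0, "h2s": 1.0}, ec=["4.4.1.1"]),
        _rxn("SO3R", {"so3": -1.0, "h2s": 1.0}, ec=["1.8.2.2"]),
        _rxn("ASNS", {"asp_L": -1.0, "asn_L": 1.0}, ec=["6.3.5.4"]),
        _rxn("CGLYS", {"cys_L": -1.0, "gly": -1.0, "cgly": 1.0}),
        Reaction("EX_biomass", {"biomass": -1.0}, 0.0, 1000.0),
    ] + _exchanges(
        ["glc_D", "ac", "asp_L", "cys_L", "so3", "met_L", "asn_L", "h2s",
         "hom_L", "gly", "cgly"]
    )
    return Reconstruction(MUCIN_DEGRADER, mets, rxns, "BIOMASS")


def _taurine_respirer() -> Reconstruction:
    mets = [_met(m) for m in (
        "glc_D", "ac", "tchola", "chola", "taur", "so3", "h2s", "biomass",
    )]
    rxns = [
        _rxn("BIOMASS", {"glc_D": -1.0, "biomass": 1.0}),
        _rxn("FERM_glc", {"glc_D": -1.0, "ac": 2.0}),
        _rxn("BSH", {"tchola": -1.0, "chola": 1.0, "taur": 1.0}, ec=["3.5.1.24"]),
        _rxn("TAURDS", {"taur": -1.0, "so3": 1.0}, ec=["2.6.1.55"]),
        _rxn("DSR", {"so3": -1.0, "h2s": 1.0}, ec=["1.8.7.1"]),
        Reaction("EX_biomass", {"biomass": -1.0}, 0.0, 1000.0),
    ] + _exchanges(["glc_D", "ac", "tchola", "chola", "taur", "so3", "h2s"])
    return Reconstruction(TAURINE_RESPIRER, mets, rxns, "BIOMASS")


def _background(k: int) -> Reconstruction:
    mets = [_met(m) for m in ("glc_D", "ac", "biomass")]
    rxns = [
        _rxn("BIOMASS", {"glc_D": -1.0, "biomass": 1.0}),
        _rxn("FERM_glc", {"glc_D": -1.0, "ac": 2.0}),
        Reaction("EX_biomass", {"biomass": -1.0}, 0.0, 1000.0),
    ] + _exchanges(["glc_D", "ac"])
    return Reconstruction(f"background_{k:02d}", mets, rxns, "BIOMASS")


def generate_strain_panel(
    spec: PanelSpec, diet: Diet = TOY_EUROPEAN_DIET
) -> list[Reconstruction]:
    """Build the toy panel; every member must grow standalone on the diet."""
    panel: list[Reconstruction] = []
    if spec.include_mucin_degrader:
        panel.append(_mucin_degrader())
    if spec.include_taurine_respirer:
        panel.append(_taurine_respirer())
    panel.extend(_background(k) for k in range(spec.n_background_strains))
    for recon in panel:
        constrained = apply_diet_standalone(recon, diet)
        sol = fba(constrained, recon.biomass_reaction_id, "max")
        if not sol.ok or sol.objective_value <= 1e-6:
            raise GenerationError(
                f"strain {recon.strain_id} cannot grow on diet {diet.name} "
                f"(status {sol.status})"
            )
    return panel


# --------------------------------------------------------------------------
# abundances and coverage
# --------------------------------------------------------------------------

KEYSTONE_BASE_PROPORTION = 0.003  # 0.3% each, anchored on reported means
#: total Dirichlet concentration (alpha = concentration * base proportions).
#: Calibrated once by Monte Carlo so that the reported case/control keystone
#: difference (0.20% vs 0.34%) is detectable at the metagenomic cohort's
#: sample sizes (31/28) in >= 80% of seeds: this puts the keystone abundance
#: coefficient of variation near 0.65, in the range of real taxon abundances,
#: where smaller concentrations make rare taxa implausibly over-dispersed.
DIRICHLET_CONCENTRATION = 800.0


def _base_proportions(panel, keystone_factor: float = 1.0) -> np.ndarray:
    ids = [r.strain_id for r in panel]
    p = np.empty(len(ids))
    n_key = sum(1 for s in ids if s in KEYSTONES)
    n_bg = len(ids) - n_key
    key_p = KEYSTONE_BASE_PROPORTION * keystone_factor
    bg_p = (1.0 - n_key * KEYSTONE_BASE_PROPORTION) / max(n_bg, 1)
    for i, s in enumerate(ids):
        p[i] = key_p if s in KEYSTONES else bg_p
    return p / p.sum()


def generate_abundance_profiles(
    panel: list[Reconstruction],
    n_cases: int,
    n_controls: int,
    keystone_shift: float = 0.7,
    seed: int = 0,
) -> tuple[list[AbundanceProfile], pd.Series]:
    """Dirichlet abundance profiles with keystone enrichment in cases.

    Expected keystone abundance is multiplied by ``1 + keystone_shift`` in
    cases (before renormalisation), matching the direction of the reported
    case/control abundance difference for the taurine-respiring keystone.
    Returns (profiles, group labels indexed by subject id).
    """
    if not panel:
        raise ValueError("empty panel")
    if keystone_shift < 0:
        raise ValueError("keystone_shift must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [r.strain_id for r in panel]
    p_ctrl = _base_proportions(panel, 1.0)
    p_case = _base_proportions(panel, 1.0 + keystone_shift)
    profiles, groups = [], {}
    for i in range(n_cases + n_controls):
        is_case = i < n_cases
        p = p_case if is_case else p_ctrl
        draw = rng.dirichlet(DIRICHLET_CONCENTRATION * p)
        draw = draw / draw.sum()
        sid = f"S{i + 1:03d}"
        profiles.append(AbundanceProfile(sid, dict(zip(ids, draw))))
        groups[sid] = "PD" if is_case else "control"
    return profiles, pd.Series(groups, name="group")


def generate_coverage_table(
    panel: list[Reconstruction],
    n_subjects: int,
    dropout_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject x strain genome coverage; ~dropout_rate of entries fall below
    the 0.1 detection threshold, the rest lie in [0.1, 2]."""
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = [r.strain_id for r in panel]
    below = rng.random((n_subjects, len(ids))) < dropout_rate
    low = rng.uniform(0.0, 0.1, size=below.shape)
    high = rng.uniform(0.1, 2.0, size=below.shape)
    cov = np.where(below, low, high)
    return pd.DataFrame(
        cov, index=[f"S{i + 1:03d}" for i in range(n_subjects)], columns=ids
    )


# --------------------------------------------------------------------------
# longitudinal metabolome
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    n_cases: int = 30
    n_controls: int = 30
    n_waves: int = 3
    trajectory_assignments: dict[str, str] = field(default_factory=dict)
    interaction_effects: list[tuple[str, str, float]] = field(default_factory=list)
    residual_sd: float = 0.3
    subject_sd: float = 0.3
    trajectory_delta: float = 0.4
    include_levodopa: bool = False
    levodopa_slope: float = LEVODOPA_SLOPE
    levodopa_fold_range: tuple[float, float] = LEVODOPA_FOLD_RANGE
    levodopa_intake_prob: float = 0.8
    adjust_interactions_for_medication: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.residual_sd <= 0 or self.subject_sd <= 0:
            raise ValueError("residual_sd and subject_sd must be > 0")
        if self.n_waves < 2 or self.n_waves > len(WAVES):
            raise ValueError("n_waves must be 2 or 3")
        for label in self.trajectory_assignments.values():
            if label not in TRAJECTORY_TEMPLATES:
                raise ValueError(f"unknown trajectory type {label!r}")
        for a, b, _ in self.interaction_effects:
            if a == b:
                raise ValueError("interaction pair must be two distinct metabolites")
        resp = [a for a, _, _ in self.interaction_effects]
        preds = {b for _, b, _ in self.interaction_effects}
        if len(set(resp)) != len(resp):
            raise ValueError("each response metabolite may appear in one pair only")
        if preds & set(resp):
            raise ValueError("a pair's predictor cannot be another pair's response")

    @property
    def metabolites(self) -> list[str]:
        out = list(self.trajectory_assignments)
        for a, b, _ in self.interaction_effects:
            for m in (a, b):
                if m not in out:
                    out.append(m)
        if self.include_levodopa and "3omd" not in out:
            out.append("3omd")
        return out


AGE_EFFECT = 0.005   # per year of age, log scale
SEX_EFFECT = 0.10    # male vs female, log scale
WAVE_EFFECT = 0.05   # secular drift per follow-up wave, both groups
INTERACTION_CONTROL_SLOPE = 0.5


def generate_longitudinal_metabolome(spec: CohortSpec) -> pd.DataFrame:
    """Long-format table of (subject, wave, metabolite) log-concentrations.

    Log-concentrations follow a random-intercept model with the assigned
    trajectory template scaled by ``trajectory_delta``, age/sex covariate
    effects, embedded pairwise group-interaction terms, and levodopa-driven
    3-OMD elevation (takers' 3-OMD multiplied by a fold-change drawn
    log-uniformly from ``levodopa_fold_range``; the dosage column is the
    fold-change's log divided by ``levodopa_slope``, so the intra-individual
    change-on-change slope equals ``levodopa_slope`` by construction).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    waves = WAVES[: spec.n_waves]
    subjects = [f"P{i + 1:03d}" for i in range(n)]
    is_case = np.array([i < spec.n_cases for i in range(n)])
    age = rng.normal(65.0, 8.0, n)
    sex = rng.integers(0, 2, n)
    disease_length = np.where(is_case, rng.uniform(0.5, 2.0, n), np.nan)

    # per-wave levodopa dosing (cases only, drug-naive at baseline)
    dose = np.zeros((n, len(waves)))
    other_dose = np.zeros((n, len(waves)))
    if spec.include_levodopa:
        lo, hi = spec.levodopa_fold_range
        for w in range(1, len(waves)):
            takes = is_case & (rng.random(n) < spec.levodopa_intake_prob)
            fold = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
            dose[:, w] = np.where(takes, np.log(fold) / spec.levodopa_slope, 0.0)
            other_dose[:, w] = np.where(
                is_case & (rng.random(n) < 0.3), rng.uniform(0.5, 2.0, n), 0.0
            )

    mets = spec.metabolites
    templates = {
        m: TRAJECTORY_TEMPLATES[spec.trajectory_assignments.get(m, "null")]
        for m in mets
    }
    pairs = {a: (b, beta) for a, b, beta in spec.interaction_effects}

    # draw every metabolite's base signal first (responses consume predictors)
    base: dict[str, np.ndarray] = {}
    order = [m for m in mets if m not in pairs] + [m for m in mets if m in pairs]
    for m in order:
        u = rng.normal(0.0, spec.subject_sd, n)
        eps = rng.normal(0.0, spec.residual_sd, (n, len(waves)))
        g, gw1, gw2 = templates[m]
        y = np.empty((n, len(waves)))
        for w in range(len(waves)):
            gw = (0.0, gw1, gw2)[w] if len(waves) == 3 else (0.0, gw1)[w]
            y[:, w] = (
                u
                + AGE_EFFECT * (age - 65.0)
                + SEX_EFFECT * sex
                + WAVE_EFFECT * w
                + spec.trajectory_delta * (g + gw) * is_case
                + eps[:, w]
            )
        if m in pairs:
            b_met, beta = pairs[m]
            x = base[b_met]
            y = y + (INTERACTION_CONTROL_SLOPE + beta * is_case[:, None]) * x
        if m == "3omd" and spec.include_levodopa:
            y = y + spec.levodopa_slope * dose
        base[m] = y

    records = []
    for i, sid in enumerate(subjects):
        for w, wave in enumerate(waves):
            for m in mets:
                records.append(
                    (
                        sid,
                        "PD" if is_case[i] else "control",
                        wave,
                        age[i],
                        int(sex[i]),
                        disease_length[i],
                        dose[i, w],
                        other_dose[i, w],
                        m,
                        base[m][i, w],
                    )
                )
    return pd.DataFrame(
        records,
        columns=[
            "subject_id", "group", "wave", "age", "sex", "disease_length",
            "levodopa_dose", "equivalent_dose_other", "metabolite_id",
            "log_concentration",
        ],
    )


def generate_updrs_scores(
    table: pd.DataFrame,
    effects: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic motor-scale scores for the PD subjects of a metabolome table.

    The motor-examination scale (III) is a linear function of the (optionally)
    named metabolites plus noise; scales I/II/IV are ordinal cuts of a latent
    normal; ``total`` sums all four.
    """
    effects = effects or {}
    rng = np.random.default_rng(seed)
    pd_rows = table[table["group"] == "PD"]
    idx = pd_rows[["subject_id", "wave", "age", "sex"]].drop_duplicates()
    wide = pd_rows.pivot_table(
        index=["subject_id", "wave"], columns="metabolite_id",
        values="log_concentration",
    )
    out = []
    u3 = {s: rng.normal(0, 2.0) for s in idx["subject_id"].unique()}
    for _, row in idx.iterrows():
        key = (row["subject_id"], row["wave"])
        wave_idx = WAVES.index(row["wave"])
        signal = sum(
            beta * wide.loc[key, m] for m, beta in effects.items() if m in wide.columns
        )
        iii = 18.0 + 1.5 * wave_idx + u3[row["subject_id"]] + signal + rng.normal(0, 3.0)
        latent = rng.normal(0, 1) + 0.3 * wave_idx
        cuts = [-0.5, 0.5, 1.5]
        ordinal = int(np.searchsorted(cuts, latent))
        out.append(
            (
                row["subject_id"], row["wave"],
                ordinal, ordinal, max(iii, 0.0), ordinal,
            )
        )
    df = pd.DataFrame(
        out, columns=["subject_id", "wave", "updrs_i", "updrs_ii", "updrs_iii",
                      "updrs_iv"],
    )
    df["updrs_total"] = (
        df["updrs_i"] + df["updrs_ii"] + df["updrs_iii"] + df["updrs_iv"]
    )
    return df


# --------------------------------------------------------------------------
# survival cohort
# --------------------------------------------------------------------------

@dataclass
class SurvivalSpec:
    n_subjects: int = 10034
    target_events: int = 157
    log_hazard_per_sd: float = math.log(0.80)
    max_followup_years: float = 23.0
    covariate_spec: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_events < self.n_subjects:
            raise ValueError("target_events must be in (0, n_subjects)")


#: modest covariate log-hazard effects used by the generator
COVARIATE_LOG_HAZARDS = {
    "age": 0.03,       # per year, centered
    "sex": -0.10,
    "bmi": 0.02,       # per unit, centered
    "smoking": 0.30,
    "log_crp": 0.10,
}


def generate_survival_cohort(spec: SurvivalSpec) -> pd.DataFrame:
    """Exponential event times with administrative censoring calibrated so the
    expected event count equals ``target_events``.

    The exposure column is standard normal (its raw, pre-processing analogue
    ``exposure_raw`` is lognormal); ``event`` marks incident cases within the
    follow-up window.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cov = spec.covariate_spec or {}
    age = rng.normal(*cov.get("age", (59.8, 8.9)), n)
    sex = (rng.random(n) < cov.get("sex_p_female", 0.53)).astype(int)
    bmi = rng.normal(*cov.get("bmi", (26.3, 3.9)), n)
    smoking = (rng.random(n) < cov.get("smoking_p", 0.12)).astype(int)
    log_crp = rng.normal(*cov.get("log_crp", (0.7, 0.9)), n)
    exposure = rng.standard_normal(n)
    batch = rng.integers(1, 3, n)

    eta = (
        spec.log_hazard_per_sd * exposure
        + COVARIATE_LOG_HAZARDS["age"] * (age - age.mean())
        + COVARIATE_LOG_HAZARDS["sex"] * sex
        + COVARIATE_LOG_HAZARDS["bmi"] * (bmi - bmi.mean())
        + COVARIATE_LOG_HAZARDS["smoking"] * smoking
        + COVARIATE_LOG_HAZARDS["log_crp"] * (log_crp - log_crp.mean())
    )
    rate_mult = np.exp(eta)
    tau = spec.max_followup_years

    def expected_events(lam0: float) -> float:
        return float(np.sum(1.0 - np.exp(-lam0 * rate_mult * tau)))

    lo, hi = 1e-12, 1.0
    if expected_events(hi) < spec.target_events:
        raise GenerationError(
            f"target_events={spec.target_events} unreachable within "
            f"{tau} years for n={n}"
        )
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if expected_events(mid) < spec.target_events:
            lo = mid
        else:
            hi = mid
    lam0 = math.sqrt(lo * hi)

    t_event = rng.exponential(1.0 / (lam0 * rate_mult))
    event = (t_event <= tau).astype(int)
    time = np.minimum(t_event, tau)

    return pd.DataFrame(
        {
            "subject_id": [f"E{i + 1:05d}" for i in range(n)],
            "followup_time": time,
            "event": event,
            "exposure": exposure,
            "exposure_raw": np.exp(0.8 * exposure + 2.0),
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
            "crp": np.exp(log_crp),
            "batch": batch,
        }
    )
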