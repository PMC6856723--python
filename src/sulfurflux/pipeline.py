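"""End-to-end orchestration: generators -> community FBA -> statistics.

One :class:`RunConfig` (YAML-serializable) drives every stage; a single
global seed is split into independent per-module seeds through
``numpy.random.SeedSequence.spawn`` so each stage is reproducible in
isolation.  Outputs land in a deterministic directory layout::

    <out>/config.yaml        verbatim record of the configuration
    <out>/data/              generated inputs (panel JSON, tables)
    <out>/potentials.tsv     per-subject secretion potentials
    <out>/stats/*.csv        one CSV per analysis family
    <out>/report.md          summary with family sizes and seeds
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    cohort_matching,
    community_builder,
    fba_engine,
    incidence_cox,
    metabolome_stats,
    microbiome_stats,
    synthetic_data,
)
from .community_builder import TOY_EUROPEAN_DIET, build_community
from .recon_core import write_reconstruction

logger = logging.getLogger(__name__)

SULFUR_SCREEN_SET = ("met_L", "h2s", "so3", "taur", "cgly", "asn_L", "hom_L", "ac")

#: reactions of the aspartate -> methionine chain and sulfur dissimilation
PATHWAY_REACTIONS = ("ASPK", "HSDH", "SHSL", "CYSTL", "METS", "SO3R", "DSR", "BSH")

CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    seed: int = 0
    # microbiome arm (sizes follow the metagenomic cohort: 31 PD / 28 controls)
    n_background_strains: int = 3
    micro_n_cases: int = 31
    micro_n_controls: int = 28
    keystone_shift: float = 0.7
    n_boot: int = 200
    # metabolome arm
    cohort_n_cases: int = 30
    cohort_n_controls: int = 30
    trajectory_assignments: dict = field(
        default_factory=lambda: {
            "homoserine": "type1",
            "cystathionine": "type2",
            "methionine": "type3",
            "serine": "null",
        }
    )
    # the demo pair carries no trajectory of its own: the screen's model (per
    # the published analysis) has no group-wave terms, so trajectory-shaped
    # metabolites would confound an embedded interaction
    interaction_effects: list = field(
        default_factory=lambda: [["sm_d18_1_25_0", "sm_d18_1_25_1", -0.53]]
    )
    trajectory_delta: float = 0.4
    include_levodopa: bool = True
    # survival arm (kept desk-scale by default; the study-size run is a flag)
    survival_n: int = 2000
    survival_events: int = 120
    survival_hr: float = 0.80
    alpha: float = 0.05

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


def _module_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def run_all(config: RunConfig, out_dir) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(out_dir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    seeds = _module_seeds(config.seed)
    report = [
        "# sulfurflux run report", "",
        f"- global seed: {config.seed}",
        f"- module seeds: {seeds}", "",
    ]

    # ---- strain panel -----------------------------------------------------
    panel = synthetic_data.generate_strain_panel(
        synthetic_data.PanelSpec(
            config.n_background_strains, True, True, seed=seeds[0]
        )
    )
    for recon in panel:
        write_reconstruction(recon, out / "models" / f"{recon.strain_id}.json")
    report.append(f"## Panel\n\n- {len(panel)} strains: "
                  + ", ".join(r.strain_id for r in panel) + "\n")

    # ---- abundances + coverage -------------------------------------------
    profiles, groups = synthetic_data.generate_abundance_profiles(
        panel, config.micro_n_cases, config.micro_n_controls,
        config.keystone_shift, seed=seeds[1],
    )
    coverage = synthetic_data.generate_coverage_table(
        panel, len(profiles), dropout_rate=0.2, seed=seeds[1]
    )
    coverage.to_csv(out / "data" / "coverage.tsv", sep="\t",
                    float_format=CSV_FLOAT_FORMAT)
    abund = pd.DataFrame(
        {p.subject_id: p.abundances for p in profiles}
    ).T.rename_axis("subject_id")
    abund.to_csv(out / "data" / "abundances.tsv", sep="\t",
                 float_format=CSV_FLOAT_FORMAT)

    # ---- community models + secretion screen -----------------------------
    rows = {}
    for prof in profiles:
        model = build_community(panel, prof, TOY_EUROPEAN_DIET)
        rows[prof.subject_id] = fba_engine.secretion_screen(
            model, SULFUR_SCREEN_SET, prof.subject_id
        )
    potentials = pd.DataFrame(rows).T.rename_axis("subject_id")
    potentials.to_csv(out / "potentials.tsv", sep="\t",
                      float_format=CSV_FLOAT_FORMAT)
    report.append(f"## Secretion screen\n\n- {len(SULFUR_SCREEN_SET)} "
                  f"metabolites x {len(profiles)} subjects\n")

    # ---- microbiome statistics -------------------------------------------
    frac_rows = []
    for strain in synthetic_data.KEYSTONES:
        y = abund[strain].to_numpy()
        r = microbiome_stats.fractional_regression(
            y, groups.loc[abund.index].to_numpy(), n_boot=config.n_boot,
            seed=seeds[2],
        )
        frac_rows.append(
            (strain, r.estimate, r.se, r.ci_low, r.ci_high, r.p, r.n_boot)
        )
    frac = pd.DataFrame(
        frac_rows,
        columns=["strain", "log_or", "se", "ci_low", "ci_high", "p", "n_boot"],
    )
    frac["q"] = microbiome_stats.bh_fdr(frac["p"].to_numpy())
    _write_csv(frac, out / "stats" / "species_fractional.csv")

    ra = microbiome_stats.reaction_abundances(panel, profiles, PATHWAY_REACTIONS)
    _write_csv(ra, out / "stats" / "reaction_abundances.csv")
    ra_rows = []
    wide_ra = ra.pivot(index="subject_id", columns="reaction_id", values="abundance")
    for rid in PATHWAY_REACTIONS:
        r = microbiome_stats.fractional_regression(
            wide_ra[rid].to_numpy(), groups.loc[wide_ra.index].to_numpy(),
            n_boot=config.n_boot, seed=seeds[2],
        )
        ra_rows.append((rid, r.estimate, r.se, r.p))
    ra_tests = pd.DataFrame(ra_rows, columns=["reaction", "log_or", "se", "p"])
    ra_tests["q"] = microbiome_stats.bh_fdr(
        ra_tests["p"].to_numpy(), family_size=22
    )
    _write_csv(ra_tests, out / "stats" / "reaction_tests.csv")

    sec = microbiome_stats.secretion_group_test(
        potentials, groups, n_boot=config.n_boot, seed=seeds[3]
    )
    _write_csv(sec, out / "stats" / "secretion_tests.csv")
    n_sig = int((sec["q"] < config.alpha).sum()) if len(sec) else 0
    report.append(
        f"## Microbiome statistics\n\n"
        f"- fractional regressions: {len(frac)} species, BH family {len(frac)}\n"
        f"- reaction tests: {len(ra_tests)} reactions, BH family 22\n"
        f"- secretion tests: {len(sec)} metabolites, "
        f"{n_sig} significant at FDR {config.alpha}\n"
    )

    ve = microbiome_stats.variance_explained(
        np.log(abund[synthetic_data.MUCIN_DEGRADER].to_numpy()),
        np.log(potentials["met_L"].clip(lower=1e-9).to_numpy()),
    )
    report.append(
        f"- variance explained (mucin-degrader -> methionine potential): "
        f"R2 = {ve['r2']:.3f}, powers {ve['powers']}\n"
    )

    # ---- longitudinal metabolome -----------------------------------------
    spec = synthetic_data.CohortSpec(
        n_cases=config.cohort_n_cases,
        n_controls=config.cohort_n_controls,
        trajectory_assignments=dict(config.trajectory_assignments),
        interaction_effects=[tuple(e) for e in config.interaction_effects],
        trajectory_delta=config.trajectory_delta,
        include_levodopa=config.include_levodopa,
        seed=seeds[4],
    )
    table = synthetic_data.generate_longitudinal_metabolome(spec)
    table.to_csv(out / "data" / "metabolome.csv", index=False,
                 float_format=CSV_FLOAT_FORMAT)
    table = metabolome_stats.preprocess(table)

    fits = metabolome_stats.trajectory_screen(table)
    traj = pd.DataFrame(
        [
            (f.metabolite_id, f.beta_group, f.beta_gw1, f.beta_gw2,
             f.global_wald_chi2, f.global_p, f.q, f.type_label)
            for f in fits
        ],
        columns=["metabolite", "beta_group", "beta_gw1", "beta_gw2",
                 "wald_chi2", "global_p", "q", "type"],
    )
    _write_csv(traj, out / "stats" / "trajectories.csv")

    screen = metabolome_stats.interaction_screen(table)
    _write_csv(screen, out / "stats" / "interaction_screen.csv")

    med = metabolome_stats.medication_change_model(table)
    _write_csv(med, out / "stats" / "medication_change.csv")

    auc = metabolome_stats.levodopa_auc(table) if config.include_levodopa else float("nan")
    n_disc = int((traj["q"] < config.alpha).sum())
    n_int = int((screen["q"] < config.alpha).sum()) if len(screen) else 0
    report.append(
        f"## Longitudinal metabolome\n\n"
        f"- {traj.shape[0]} trajectory tests (BH family {traj.shape[0]}), "
        f"{n_disc} discoveries at FDR {config.alpha}\n"
        f"- interaction screen: {screen.shape[0]} ordered pairs, "
        f"{n_int} discoveries\n"
        f"- medication change-on-change: {med.shape[0]} metabolites "
        f"(BH family {med.shape[0]})\n"
        f"- levodopa-intake classification by 3-OMD: AUC = {auc:.2f}\n"
        if config.include_levodopa else
        f"## Longitudinal metabolome\n\n- {traj.shape[0]} trajectory tests, "
        f"{n_disc} discoveries at FDR {config.alpha}\n"
    )

    # ---- survival arm -----------------------------------------------------
    surv = synthetic_data.generate_survival_cohort(
        synthetic_data.SurvivalSpec(
            n_subjects=config.survival_n,
            target_events=config.survival_events,
            log_hazard_per_sd=float(np.log(config.survival_hr)),
            seed=seeds[5],
        )
    )
    surv.to_csv(out / "data" / "survival.csv", index=False,
                float_format=CSV_FLOAT_FORMAT)
    batch_fits = incidence_cox.cox_per_batch(surv)
    pooled = incidence_cox.fixed_effect_meta(batch_fits)
    cox_rows = [
        (r.target_id, r.log_hr, r.se, r.hr, r.ci_low, r.ci_high, r.p,
         r.n, r.n_events)
        for r in batch_fits
    ]
    cox_rows.append(
        ("pooled", pooled["log_hr"], pooled["se"], pooled["hr"],
         pooled["ci_low"], pooled["ci_high"], pooled["p"],
         int(surv.shape[0]), int(surv["event"].sum()))
    )
    cox = pd.DataFrame(
        cox_rows,
        columns=["batch", "log_hr", "se", "hr", "ci_low", "ci_high", "p",
                 "n", "events"],
    )
    _write_csv(cox, out / "stats" / "cox.csv")
    report.append(
        f"## Incidence analysis\n\n"
        f"- n = {surv.shape[0]}, events = {int(surv['event'].sum())}\n"
        f"- pooled HR per SD = {pooled['hr']:.3f} "
        f"({pooled['ci_low']:.3f}-{pooled['ci_high']:.3f}), "
        f"Cochran Q = {pooled['cochran_q']:.3f}\n"
    )

    (out / "report.md").write_text("\n".join(report))
    return out
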