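"""Assemble personalized, diet-constrained community models.

Mirrors the published community-assembly procedure for gut microbiome FBA:
strain reconstructions are copied with strain-prefixed reaction/metabolite
ids, joined through a shared lumen compartment ``[lu]``, and closed with one
diet exchange (``Diet_EX_met[d]``, uptake only, bounded by the diet) and one
fecal exchange (``EX_met[fe]``, secretion only) per lumen metabolite.  A
community biomass pseudo-reaction consumes each strain's biomass metabolite
with stoichiometric coefficient equal to that strain's relative abundance and
is bounded to [0.4, 1.0] per day (fecal excretion between every third day and
daily).

Strains below the coverage detection threshold (0.1 by default) are removed
before assembly and the surviving abundances renormalized to one.

No biomass-flux coupling constraints are applied beyond the community biomass
bounds; the builder exposes a ``coupling_hook`` for callers that want to add
rows, but ships without them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .recon_core import (
    CommunityModel,
    Metabolite,
    Reaction,
    Reconstruction,
    ReconstructionError,
)

logger = logging.getLogger(__name__)

COVERAGE_THRESHOLD = 0.1
BIOMASS_MET = "biomass"
COMMUNITY_BIOMASS_ID = "communityBiomass"
DEFAULT_BIOMASS_BOUNDS = (0.4, 1.0)
SECRETION_BOUND = 1000.0


class EmptyCommunityError(ValueError):
    pass


@dataclass
class AbundanceProfile:
    subject_id: str
    abundances: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError(f"{self.subject_id}: negative abundance")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.subject_id}: abundances sum to {total}, not 1")


@dataclass
class Diet:
    """Max uptake flux (mmol/person/day, non-negative) per diet metabolite."""

    name: str
    uptake_bounds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.uptake_bounds.values()):
            raise ValueError(f"diet {self.name}: negative uptake bound")


#: Desk-scale stand-in for the standard European diet applied in the study:
#: carbon source plus the sulfur-pathway precursors the toy panel transports.
TOY_EUROPEAN_DIET = Diet(
    "toy_european",
    {
        "glc_D": 20.0,
        "asp_L": 5.0,
        "cys_L": 2.0,
        "gly": 5.0,
        "so3": 2.0,
        "tchola": 1.0,
    },
)


def coverage_to_abundance(
    coverage_row: dict[str, float], threshold: float = COVERAGE_THRESHOLD
) -> dict[str, float]:
    """Detection filter + renormalisation: coverage below ``threshold`` is
    treated as absence; survivors are rescaled to sum to one."""
    if any(v < 0 for v in coverage_row.values()):
        raise ValueError("negative coverage")
    kept = {k: v for k, v in coverage_row.items() if v >= threshold}
    total = sum(kept.values())
    if not kept or total <= 0:
        raise EmptyCommunityError(
            f"empty community: all {len(coverage_row)} strains below "
            f"coverage threshold {threshold}"
        )
    return {k: v / total for k, v in kept.items()}


def apply_diet_standalone(recon: Reconstruction, diet: Diet) -> Reconstruction:
    """Copy of a single-strain model with exchange uptake limited by the diet.

    Exchange lower bounds become -diet[met] (0 for metabolites absent from the
    diet); secretion stays open.  The biomass sink is left untouched.
    """
    new_rxns = []
    for r in recon.reactions:
        if r.is_exchange and r.id != recon.biomass_reaction_id:
            (met,) = r.stoichiometry
            if met == BIOMASS_MET:
                new_rxns.append(r)
                continue
            lb = -float(diet.uptake_bounds.get(met, 0.0))
            new_rxns.append(
                Reaction(r.id, dict(r.stoichiometry), lb, SECRETION_BOUND,
                         list(r.ec_numbers), r.subsystem)
            )
        else:
            new_rxns.append(r)
    return Reconstruction(
        recon.strain_id, list(recon.metabolites), new_rxns, recon.biomass_reaction_id
    )


#: default strain<->lumen transporter capacity per unit relative abundance
#: (mmol/person/day); the desk-scale analogue of biomass-flux coupling: a
#: strain's exchange with the lumen is proportional to how much of the
#: community it makes up.
ABUNDANCE_CAPACITY = 100.0


def build_community(
    panel: list[Reconstruction],
    profile: AbundanceProfile,
    diet: Diet = TOY_EUROPEAN_DIET,
    biomass_bounds: tuple[float, float] = DEFAULT_BIOMASS_BOUNDS,
    abundance_capacity: float | None = ABUNDANCE_CAPACITY,
    coupling_hook=None,
) -> CommunityModel:
    """Join the profiled strains into one diet-constrained community model.

    Zero-abundance / absent strains do not enter the model.  Strain exchange
    reactions become reversible strain<->lumen transporters bounded at
    ``+-abundance_capacity * abundance`` (pass ``None`` for unconstrained
    +-1000 transporters); every lumen metabolite receives a diet and a fecal
    exchange.
    """
    by_id = {r.strain_id: r for r in panel}
    unknown = sorted(set(profile.abundances) - set(by_id))
    if unknown:
        raise KeyError(f"{profile.subject_id}: profile strains not in panel: {unknown}")

    strains = [
        (sid, ab) for sid, ab in sorted(profile.abundances.items()) if ab > 0
    ]
    if not strains:
        raise EmptyCommunityError(f"{profile.subject_id}: no strain with abundance > 0")

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    lumen_mets: dict[str, Metabolite] = {}
    biomass_stoich: dict[str, float] = {}

    for sid, ab in strains:
        recon = by_id[sid]
        prefix = f"{sid}__"
        sulfur = {m.id: m.is_sulfur for m in recon.metabolites}
        for m in recon.metabolites:
            metabolites.append(
                Metabolite(prefix + m.id, "c", m.name, m.is_sulfur)
            )
        for r in recon.reactions:
            if r.is_exchange:
                (met,) = r.stoichiometry
                if met == BIOMASS_MET:
                    continue  # replaced by the community biomass reaction
                # strain <-> lumen transporter
                if met not in lumen_mets:
                    lumen_mets[met] = Metabolite(
                        f"{met}[lu]", "lu", met, sulfur.get(met, False)
                    )
                cap = (
                    SECRETION_BOUND
                    if abundance_capacity is None
                    else abundance_capacity * ab
                )
                reactions.append(
                    Reaction(
                        f"{prefix}IEX_{met}",
                        {prefix + met: -1.0, f"{met}[lu]": 1.0},
                        -cap,
                        cap,
                    )
                )
            else:
                reactions.append(
                    Reaction(
                        prefix + r.id,
                        {prefix + k: v for k, v in r.stoichiometry.items()},
                        r.lower_bound,
                        r.upper_bound,
                        list(r.ec_numbers),
                        r.subsystem,
                    )
                )
        biomass_stoich[prefix + BIOMASS_MET] = -ab

    metabolites.extend(lumen_mets[m] for m in sorted(lumen_mets))

    for met_name in diet.uptake_bounds:
        if met_name not in lumen_mets:
            logger.warning(
                "diet %s names metabolite %s with no lumen counterpart; ignored",
                diet.name, met_name,
            )
    for met_name in sorted(lumen_mets):
        uptake = float(diet.uptake_bounds.get(met_name, 0.0))
        reactions.append(
            Reaction(
                f"Diet_EX_{met_name}[d]",
                {f"{met_name}[lu]": -1.0},
                -uptake,
                0.0,
            )
        )
        reactions.append(
            Reaction(
                f"EX_{met_name}[fe]",
                {f"{met_name}[lu]": -1.0},
                0.0,
                SECRETION_BOUND,
            )
        )

    reactions.append(
        Reaction(
            COMMUNITY_BIOMASS_ID,
            biomass_stoich,
            float(biomass_bounds[0]),
            float(biomass_bounds[1]),
        )
    )

    model = CommunityModel(
        strains=strains,
        metabolites=metabolites,
        reactions=reactions,
        community_biomass_id=COMMUNITY_BIOMASS_ID,
    )
    if coupling_hook is not None:
        model = coupling_hook(model)
    return model


def community_report(model: CommunityModel) -> str:
    """Plain-text summary: strain count, reaction/metabolite counts."""
    lines = [
        f"strains: {len(model.strains)}",
        f"metabolites: {len(model.metabolites)}",
        f"reactions: {len(model.reactions)}",
        "abundances: "
        + ", ".join(f"{sid}={ab:.6f}" for sid, ab in model.strains),
    ]
    return "\n".join(lines) + "\n"
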