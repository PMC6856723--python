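"""Data model and JSON I/O for strain-level metabolic reconstructions.

A :class:`Reconstruction` is a desk-scale genome-scale metabolic model: a set
of metabolites (with compartment tags and a sulfur flag), a set of reactions
(stoichiometry + flux bounds), and a designated biomass reaction.  A
:class:`CommunityModel` is the multi-strain analogue produced by
:mod:`sulfurflux.community_builder`: strain-prefixed reactions joined through a
shared lumen compartment, plus diet/fecal exchange reactions and an
abundance-weighted community biomass reaction.

Conventions
-----------
* Exchange reactions have exactly one metabolite with coefficient -1 and are
  written ``met ->``: negative flux is uptake, positive flux is secretion.
* Flux units are mmol per person per day; biomass flux is 1/day.
* The native serialisation is a small JSON dialect (sorted keys, diffable);
  SBML is deliberately out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

COMPARTMENTS = ("c", "lu", "d", "fe")


class ReconstructionError(ValueError):
    """Raised when a model file or in-memory model violates an invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = "c"
    name: str = ""
    is_sulfur: bool = False

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ReconstructionError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    ec_numbers: list[str] = field(default_factory=list)
    subsystem: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise ReconstructionError(f"reaction {self.id!r}: empty stoichiometry")
        for v in (self.lower_bound, self.upper_bound):
            if not math.isfinite(v):
                raise ReconstructionError(f"reaction {self.id!r}: non-finite bound {v}")
        if self.lower_bound > self.upper_bound:
            raise ReconstructionError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


@dataclass
class Reconstruction:
    strain_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.reactions:
            raise ReconstructionError(f"{self.strain_id}: no reactions")
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ReconstructionError(f"{self.strain_id}: duplicate metabolites {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ReconstructionError(f"{self.strain_id}: duplicate reactions {dupes}")
        known = set(met_ids)
        dangling = sorted(
            {m for r in self.reactions for m in r.stoichiometry if m not in known}
        )
        if dangling:
            raise ReconstructionError(
                f"{self.strain_id}: reactions reference undeclared metabolites {dangling}"
            )
        if self.biomass_reaction_id not in set(rxn_ids):
            raise ReconstructionError(
                f"{self.strain_id}: biomass reaction {self.biomass_reaction_id!r} missing"
            )

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)


@dataclass
class CommunityModel:
    """Multi-strain model; structurally a Reconstruction plus abundances."""

    strains: list[tuple[str, float]]
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    community_biomass_id: str

    def __post_init__(self):
        total = sum(a for _, a in self.strains)
        if abs(total - 1.0) > 1e-9:
            raise ReconstructionError(f"strain abundances sum to {total}, not 1")
        if any(a < 0 for _, a in self.strains):
            raise ReconstructionError("negative strain abundance")
        # reuse structural validation
        Reconstruction.validate(self)  # type: ignore[arg-type]

    def validate(self) -> None:
        Reconstruction.validate(self)  # type: ignore[arg-type]

    # structural validation needs these two attributes
    @property
    def strain_id(self) -> str:  # pragma: no cover - naming shim
        return "community"

    @property
    def biomass_reaction_id(self) -> str:
        return self.community_biomass_id

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)


def stoichiometric_matrix(model):
    """Return (S, met_index, rxn_index) for a Reconstruction or CommunityModel.

    ``S`` is a CSR sparse matrix with S[i, j] the coefficient of metabolite i
    in reaction j (negative = consumed).  The index maps are bijections from
    id to row/column.
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    rows, cols, vals = [], [], []
    for r in model.reactions:
        j = rxn_index[r.id]
        for met, coef in r.stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coef))
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_index), len(rxn_index))
    )
    return S, met_index, rxn_index


def _met_to_json(m: Metabolite) -> dict:
    return {
        "id": m.id,
        "compartment": m.compartment,
        "name": m.name,
        "is_sulfur": bool(m.is_sulfur),
    }


def _rxn_to_json(r: Reaction) -> dict:
    return {
        "id": r.id,
        "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
        "lb": r.lower_bound,
        "ub": r.upper_bound,
        "ec": list(r.ec_numbers),
        "subsystem": r.subsystem,
    }


def write_reconstruction(recon: Reconstruction, path) -> None:
    """Serialise to the JSON dialect (sorted keys, deterministic bytes)."""
    recon.validate()
    payload = {
        "strain_id": recon.strain_id,
        "biomass_reaction_id": recon.biomass_reaction_id,
        "metabolites": [_met_to_json(m) for m in sorted(recon.metabolites, key=lambda m: m.id)],
        "reactions": [_rxn_to_json(r) for r in sorted(recon.reactions, key=lambda r: r.id)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_reconstruction(path) -> Reconstruction:
    """Load and validate a reconstruction from the JSON dialect."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ReconstructionError(f"{path}: malformed JSON: {exc}") from exc
    for key in ("strain_id", "biomass_reaction_id", "metabolites", "reactions"):
        if key not in payload:
            raise ReconstructionError(f"{path}: missing key {key!r}")
    mets = [
        Metabolite(
            id=m["id"],
            compartment=m.get("compartment", "c"),
            name=m.get("name", ""),
            is_sulfur=bool(m.get("is_sulfur", False)),
        )
        for m in payload["metabolites"]
    ]
    rxns = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r.get("lb", -1000.0)),
            upper_bound=float(r.get("ub", 1000.0)),
            ec_numbers=list(r.get("ec", [])),
            subsystem=r.get("subsystem", ""),
        )
        for r in payload["reactions"]
    ]
    return Reconstruction(
        strain_id=payload["strain_id"],
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=payload["biomass_reaction_id"],
    )


def models_equal(a, b) -> bool:
    """Structural equality: same ids, stoichiometry, bounds (order-free)."""
    if sorted(a.metabolite_ids) != sorted(b.metabolite_ids):
        return False
    if sorted(a.reaction_ids) != sorted(b.reaction_ids):
        return False
    ra = {r.id: r for r in a.reactions}
    rb = {r.id: r for r in b.reactions}
    for rid, r in ra.items():
        s = rb[rid]
        if r.stoichiometry != s.stoichiometry:
            return False
        if (r.lower_bound, r.upper_bound) != (s.lower_bound, s.upper_bound):
            return False
    ma = {m.id: m for m in a.metabolites}
    mb = {m.id: m for m in b.metabolites}
    for mid, m in ma.items():
        n = mb[mid]
        if (m.compartment, m.is_sulfur) != (n.compartment, n.is_sulfur):
            return False
    return True
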