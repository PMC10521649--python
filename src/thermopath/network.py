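"""Core containers for stoichiometric networks.

A :class:`MetabolicNetwork` holds metabolites and reactions and implies the
stoichiometric matrix S (metabolites x reactions).  For pathway search the
network is converted to a :class:`DirectedNetwork` in which every reversible
reaction is split into a forward and a backward copy so that all rates are
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ObjectiveSpec",
    "DirectedReaction",
    "DirectedNetwork",
    "NetworkError",
]

#: elements checked by elemental balance validation
BALANCED_ELEMENTS = ("C", "N", "P")


class NetworkError(ValueError):
    """Raised on malformed networks: duplicate ids, dangling references,
    empty or zero stoichiometries, unbalanced reactions."""


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(10**6)
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"cannot interpret stoichiometric coefficient {value!r}")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species; a column index of the concentration vector x.

    Parameters
    ----------
    id:
        Short unique identifier within a network.
    name:
        Free-text description.
    elemental_tally:
        Optional map element -> non-negative count (C, N, P at minimum).
        Used for balance checking; O and H are deliberately not tracked
        because water and protons are omitted from single-compartment
        networks under the transformed-energy convention.
    thermo_exempt:
        True for species (water, protons) excluded from the concentration
        term of the thermodynamic constraints.
    """

    id: str
    name: str = ""
    elemental_tally: Mapping[str, int] | None = None
    thermo_exempt: bool = False

    def __post_init__(self):
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")
        if self.elemental_tally is not None:
            for el, n in self.elemental_tally.items():
                if not (isinstance(n, int) and n >= 0):
                    raise NetworkError(
                        f"metabolite {self.id}: elemental tally {el}={n!r} "
                        "must be a non-negative integer"
                    )


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion; a row of ``S v = 0``.

    ``stoichiometry`` maps metabolite id to a signed rational coefficient
    (negative = consumed).  ``delta_g_standard`` is the transformed standard
    reaction Gibbs energy in kJ/mol and is required for thermodynamically
    constrained runs.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    delta_g_standard: float | None = None
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.id:
            raise NetworkError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id}: stoichiometry is empty")
        stoich = {m: _as_fraction(c) for m, c in self.stoichiometry.items()}
        for m, c in stoich.items():
            if c == 0:
                raise NetworkError(
                    f"reaction {self.id}: zero coefficient for {m}"
                )
        object.__setattr__(self, "stoichiometry", stoich)
        object.__setattr__(self, "tags", frozenset(self.tags))

    @property
    def is_objective(self) -> bool:
        return "objective" in self.tags

    def reversed(self, new_id: str) -> "Reaction":
        """Mirror image: negated stoichiometry and Gibbs energy."""
        return Reaction(
            id=new_id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            reversible=False,
            delta_g_standard=(
                None if self.delta_g_standard is None else -self.delta_g_standard
            ),
            tags=self.tags,
        )


@dataclass
class MetabolicNetwork:
    """Metabolites plus reactions; houses the stoichiometric matrix S."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]

    def __post_init__(self):
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise NetworkError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise NetworkError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise NetworkError(
                    f"reaction {r.id} references undeclared metabolite(s): "
                    f"{sorted(missing)}"
                )

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    @property
    def objective_reaction(self) -> Reaction | None:
        for r in self.reactions:
            if r.is_objective:
                return r
        return None

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with shape (n_metabolites, n_reactions)."""
        index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                S[index[met], j] = float(coeff)
        return S

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(list(self.metabolites), list(self.reactions))

    # -- validation ------------------------------------------------------
    def check_elemental_balance(
        self, elements: Iterable[str] = BALANCED_ELEMENTS
    ) -> dict[str, dict[str, Fraction]]:
        """Return per-reaction elemental imbalances (empty dict = balanced).

        Reactions with any participant lacking a tally are skipped, as are
        objective reactions (which are deliberately unbalanced in cofactors
        when the required ATP yield n is nonzero).
        """
        tallies = {
            m.id: m.elemental_tally
            for m in self.metabolites
            if m.elemental_tally is not None
        }
        problems: dict[str, dict[str, Fraction]] = {}
        for r in self.reactions:
            if r.is_objective:
                continue
            if any(m not in tallies for m in r.stoichiometry):
                continue
            imbalance = {}
            for el in elements:
                total = sum(
                    c * tallies[m].get(el, 0) for m, c in r.stoichiometry.items()
                )
                if total != 0:
                    imbalance[el] = total
            if imbalance:
                problems[r.id] = imbalance
        return problems


@dataclass(frozen=True)
class ObjectiveSpec:
    """Definition of the injected net-conversion (objective) reaction.

    The reaction reads ``source + n ADP + n Pi -> sink + n ATP`` where n is
    the required ATP yield; for negative n the cofactor terms flip sides.
    Its rate is later fixed at -1 so the rest of the network must supply the
    conversion at unit rate.
    """

    source_metabolite: str = "glycerol"
    sink_metabolite: str = "pyruvate"
    atp_yield: int = 0
    cofactor_ids: Mapping[str, str] = field(
        default_factory=lambda: {"ATP": "ATP", "ADP": "ADP", "Pi": "Pi"}
    )

    def __post_init__(self):
        if self.source_metabolite == self.sink_metabolite:
            raise NetworkError("objective source and sink must differ")
        if self.atp_yield != 0:
            for role in ("ATP", "ADP", "Pi"):
                if role not in self.cofactor_ids:
                    raise NetworkError(f"cofactor role {role} not configured")

    def stoichiometry(self) -> dict[str, Fraction]:
        n = Fraction(self.atp_yield)
        stoich = {
            self.source_metabolite: Fraction(-1),
            self.sink_metabolite: Fraction(1),
        }
        if n != 0:
            stoich[self.cofactor_ids["ADP"]] = -n
            stoich[self.cofactor_ids["Pi"]] = -n
            stoich[self.cofactor_ids["ATP"]] = n
        return stoich


@dataclass(frozen=True)
class DirectedReaction:
    """One direction of a parent reaction; carries g0 in RT units."""

    id: str
    parent_id: str
    direction: str  # "fwd" | "bwd"
    stoichiometry: Mapping[str, Fraction]
    g0_rt: float | None

    def __post_init__(self):
        if self.direction not in ("fwd", "bwd"):
            raise NetworkError(f"bad direction {self.direction!r}")


@dataclass
class DirectedNetwork:
    """Unidirectional view of a network with an injected objective reaction.

    ``directed_reactions`` excludes the objective reaction, which is carried
    separately (fixed rate -1, no indicator, no flux cap, no thermodynamic
    constraint).
    """

    metabolites: list[Metabolite]
    directed_reactions: list[DirectedReaction]
    pairing: dict[str, tuple[str, str | None]]
    objective_reaction: Reaction
    beta: float

    def __post_init__(self):
        if self.beta <= 0:
            raise NetworkError("beta must be positive")
        for parent, (fwd, bwd) in self.pairing.items():
            if bwd is None:
                continue
            f = self.directed(fwd)
            b = self.directed(bwd)
            for met, c in f.stoichiometry.items():
                if b.stoichiometry.get(met) != -c:
                    raise NetworkError(
                        f"{parent}: backward stoichiometry is not the negated "
                        "forward stoichiometry"
                    )

    @property
    def directed_ids(self) -> list[str]:
        return [d.id for d in self.directed_reactions]

    def directed(self, did: str) -> DirectedReaction:
        for d in self.directed_reactions:
            if d.id == did:
                return d
        raise KeyError(did)

    def parent_of(self, did: str) -> str:
        return self.directed(did).parent_id

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def thermo_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.thermo_exempt]


def net_parent_fluxes(
    directed: DirectedNetwork, fluxes: Mapping[str, float]
) -> dict[str, float]:
    """Collapse directed fluxes back to net parent fluxes (fwd - bwd)."""
    net: dict[str, float] = {}
    for parent, (fwd, bwd) in directed.pairing.items():
        v = fluxes.get(fwd, 0.0)
        if bwd is not None:
            v -= fluxes.get(bwd, 0.0)
        net[parent] = v
    return net
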