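"""Reading, writing and transforming stoichiometric models.

Three input dialects are supported:

``fixture_json``
    The package's own schema: ``{"metabolites": [...], "reactions": [...]}``
    with stoichiometry maps, a ``reversible`` flag and an optional
    ``delta_g_kJ_mol`` per reaction.  Round-trips losslessly.
``bigg_json``
    BiGG-style JSON genome-scale models (read through COBRApy);
    ``lower_bound < 0`` marks a reaction reversible.
``sbml``
    SBML Level 3 with FBC flux bounds (read through COBRApy).

Genome-scale inputs have their boundary/exchange reactions removed by
default so the converted network is internally balanced; pass
``keep_boundary`` ids to retain specific ones.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .network import (
    DirectedNetwork,
    DirectedReaction,
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    ObjectiveSpec,
    Reaction,
)
from .thermodynamics import gibbs_to_rt

__all__ = [
    "read_model",
    "write_fixture_json",
    "apply_alterations",
    "add_objective_reaction",
    "split_reactions",
    "write_directed_tsv",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_model(
    path: str | Path,
    format: str = "fixture_json",
    keep_boundary: Iterable[str] = (),
) -> MetabolicNetwork:
    """Read a stoichiometric model from ``path`` in the declared format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fixture_json":
        return _read_fixture_json(path)
    if format in ("bigg_json", "sbml"):
        return _read_cobra(path, format, keep_boundary=set(keep_boundary))
    raise ValueError(f"unknown model format {format!r}")


def _read_fixture_json(path: Path) -> MetabolicNetwork:
    with open(path) as fh:
        doc = json.load(fh)
    metabolites = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            elemental_tally=m.get("elemental_tally"),
            thermo_exempt=bool(m.get("thermo_exempt", False)),
        )
        for m in doc["metabolites"]
    ]
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry={k: Fraction(str(v)) for k, v in r["stoichiometry"].items()},
            reversible=bool(r.get("reversible", False)),
            delta_g_standard=r.get("delta_g_kJ_mol"),
            tags=frozenset(r.get("tags", [])),
        )
        for r in doc["reactions"]
    ]
    return MetabolicNetwork(metabolites, reactions)


def write_fixture_json(network: MetabolicNetwork, path: str | Path) -> None:
    """Serialize to the fixture JSON schema (lossless round-trip)."""
    doc = {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                **(
                    {"elemental_tally": dict(m.elemental_tally)}
                    if m.elemental_tally is not None
                    else {}
                ),
                **({"thermo_exempt": True} if m.thermo_exempt else {}),
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {
                    k: (int(v) if v.denominator == 1 else str(v))
                    for k, v in r.stoichiometry.items()
                },
                "reversible": r.reversible,
                **(
                    {"delta_g_kJ_mol": r.delta_g_standard}
                    if r.delta_g_standard is not None
                    else {}
                ),
                **({"tags": sorted(r.tags)} if r.tags else {}),
            }
            for r in network.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def _read_cobra(path: Path, format: str, keep_boundary: set[str]) -> MetabolicNetwork:
    import cobra.io

    if format == "bigg_json":
        model = cobra.io.load_json_model(str(path))
    else:
        model = cobra.io.read_sbml_model(str(path))

    boundary_ids = {r.id for r in model.boundary} - keep_boundary
    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            elemental_tally=(
                {el: int(n) for el, n in m.elements.items() if float(n).is_integer()}
                if m.elements
                else None
            ),
            thermo_exempt=m.id.split("_")[0] in ("h", "h2o"),
        )
        for m in model.metabolites
    ]
    reactions = []
    for r in model.reactions:
        if r.id in boundary_ids:
            continue
        stoich = {m.id: Fraction(str(c)) for m, c in r.metabolites.items()}
        if not stoich:
            continue
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                reversible=r.lower_bound < 0,
            )
        )
    return MetabolicNetwork(metabolites, reactions)


# ---------------------------------------------------------------------------
# model alterations
# ---------------------------------------------------------------------------

def apply_alterations(
    network: MetabolicNetwork, alterations: Sequence[Mapping]
) -> MetabolicNetwork:
    """Apply an ordered list of model edits and return a new network.

    Each alteration is a mapping with an ``action`` key:

    - ``{"action": "remove_reaction", "id": ...}``
    - ``{"action": "add_reaction", "record": {...fixture reaction schema...}}``
    - ``{"action": "set_reversibility", "id": ..., "reversible": bool}``
    - ``{"action": "set_delta_g", "id": ..., "delta_g_kJ_mol": float}``
    """
    reactions = list(network.reactions)

    def _index_of(rid: str) -> int:
        for i, r in enumerate(reactions):
            if r.id == rid:
                return i
        raise NetworkError(f"alteration references unknown reaction {rid!r}")

    for alt in alterations:
        action = alt.get("action")
        if action == "remove_reaction":
            reactions.pop(_index_of(alt["id"]))
        elif action == "add_reaction":
            rec = alt["record"]
            reactions.append(
                Reaction(
                    id=rec["id"],
                    stoichiometry={
                        k: Fraction(str(v)) for k, v in rec["stoichiometry"].items()
                    },
                    reversible=bool(rec.get("reversible", False)),
                    delta_g_standard=rec.get("delta_g_kJ_mol"),
                    tags=frozenset(rec.get("tags", [])),
                )
            )
        elif action == "set_reversibility":
            i = _index_of(alt["id"])
            r = reactions[i]
            reactions[i] = Reaction(
                id=r.id,
                stoichiometry=r.stoichiometry,
                reversible=bool(alt["reversible"]),
                delta_g_standard=r.delta_g_standard,
                tags=r.tags,
            )
        elif action == "set_delta_g":
            i = _index_of(alt["id"])
            r = reactions[i]
            reactions[i] = Reaction(
                id=r.id,
                stoichiometry=r.stoichiometry,
                reversible=r.reversible,
                delta_g_standard=float(alt["delta_g_kJ_mol"]),
                tags=r.tags,
            )
        else:
            raise NetworkError(f"unknown alteration action {action!r}")
    return MetabolicNetwork(list(network.metabolites), reactions)


# ---------------------------------------------------------------------------
# objective injection and direction splitting
# ---------------------------------------------------------------------------

OBJECTIVE_REACTION_ID = "OBJ"


def add_objective_reaction(
    network: MetabolicNetwork, spec: ObjectiveSpec
) -> MetabolicNetwork:
    """Inject the net-conversion reaction source + n ADP + n Pi -> sink + n ATP.

    The added reaction is irreversible, tagged ``objective``, and later fixed
    at rate -1 by the MILP so the network must supply the conversion.
    """
    if network.objective_reaction is not None:
        raise NetworkError("objective already injected")
    stoich = spec.stoichiometry()
    known = set(network.metabolite_ids)
    missing = set(stoich) - known
    if missing:
        raise NetworkError(f"objective references missing metabolite(s): {sorted(missing)}")
    obj = Reaction(
        id=OBJECTIVE_REACTION_ID,
        stoichiometry=stoich,
        reversible=False,
        tags=frozenset({"objective", f"atp_yield={spec.atp_yield}"}),
    )
    return MetabolicNetwork(list(network.metabolites), list(network.reactions) + [obj])


def split_reactions(
    network: MetabolicNetwork,
    beta: float = 10.0,
    require_thermo: bool = True,
    thermo_unconstrained_ids: Iterable[str] = (),
    split_irreversible: bool = False,
) -> DirectedNetwork:
    """Split reversible reactions into forward/backward unidirectional pairs.

    Every directed reaction gets flux bounds [0, beta].  The objective
    reaction is exempt: it is carried separately with fixed rate semantics.
    Irreversible reactions keep a single forward copy unless
    ``split_irreversible`` forces a literal two-way split.

    With ``require_thermo`` (the default), a missing standard Gibbs energy on
    a non-objective reaction is an error unless the reaction id is listed in
    ``thermo_unconstrained_ids``.
    """
    if beta <= 0:
        raise NetworkError("beta must be positive")
    obj = network.objective_reaction
    if obj is None:
        raise NetworkError("no objective reaction injected")
    unconstrained = set(thermo_unconstrained_ids)

    directed: list[DirectedReaction] = []
    pairing: dict[str, tuple[str, str | None]] = {}
    for r in network.reactions:
        if r.is_objective:
            continue
        if r.delta_g_standard is None and require_thermo and r.id not in unconstrained:
            raise NetworkError(
                f"reaction {r.id} lacks a standard Gibbs energy; supply one, "
                "list it in thermo_unconstrained_ids, or run thermo-free"
            )
        g0 = None if r.delta_g_standard is None else gibbs_to_rt(r.delta_g_standard)
        fwd_id = r.id
        directed.append(
            DirectedReaction(fwd_id, r.id, "fwd", dict(r.stoichiometry), g0)
        )
        if r.reversible or split_irreversible:
            bwd_id = f"{r.id}__rev"
            directed.append(
                DirectedReaction(
                    bwd_id,
                    r.id,
                    "bwd",
                    {m: -c for m, c in r.stoichiometry.items()},
                    None if g0 is None else -g0,
                )
            )
            pairing[r.id] = (fwd_id, bwd_id)
        else:
            pairing[r.id] = (fwd_id, None)

    return DirectedNetwork(
        metabolites=list(network.metabolites),
        directed_reactions=directed,
        pairing=pairing,
        objective_reaction=obj,
        beta=beta,
    )


def write_directed_tsv(directed: DirectedNetwork, path: str | Path) -> None:
    """Debug dump of the unidirectional split."""
    with open(path, "w") as fh:
        fh.write("directed_id\tparent_id\tdirection\tg0_RT\tstoichiometry\n")
        for d in directed.directed_reactions:
            stoich = ";".join(
                f"{m}:{c}" for m, c in sorted(d.stoichiometry.items())
            )
            g0 = "" if d.g0_rt is None else f"{d.g0_rt:.6g}"
            fh.write(f"{d.id}\t{d.parent_id}\t{d.direction}\t{g0}\t{stoich}\n")
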