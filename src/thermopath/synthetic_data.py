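"""Test networks: the curated central-carbon fixture, planted-pathway random
networks, thermodynamically blocked variants and a brute-force oracle.

The central-carbon fixture is a single-compartment transcription of the
glycerol -> pyruvate portion of E. coli central metabolism: EMP lower
glycolysis, the Entner-Doudoroff route (reached gluconeogenically from
triose phosphates), the methylglyoxal bypass with its three
methylglyoxal -> pyruvate branches, and the serine shunt, plus redox/amine
closure reactions (transhydrogenase, NADH dehydrogenase, quinol oxidase,
glutamate dehydrogenase, adenylate kinase) so cofactors balance at steady
state without any ATP-synthesizing respiration — ATP accounting is purely
substrate-level.

Packaged standard Gibbs energies are curated stand-ins on the kJ/mol scale
chosen for their feasibility class (e.g. 3-phosphoglycerate dehydrogenase
strongly endergonic, pyruvate kinase and serine deaminase strongly
exergonic); analyses should rely on feasibility classes, not exact values.
Water and protons are omitted throughout (transformed-energy convention),
so only C, N and P are balanced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from .network import (
    DirectedNetwork,
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    ObjectiveSpec,
    Reaction,
)
from .model_io import add_objective_reaction, split_reactions
from .thermodynamics import ThermoParams, build_thermo_params

__all__ = [
    "build_central_carbon_fixture",
    "generate_planted_network",
    "generate_parallel_routes",
    "block_thermodynamically",
    "brute_force_enumerate",
    "PlantedNetwork",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Random network generation failed within the rejection budget."""


# ---------------------------------------------------------------------------
# curated central-carbon fixture
# ---------------------------------------------------------------------------

# id -> (name, {element: count})
_FIXTURE_METABOLITES: dict[str, tuple[str, dict[str, int]]] = {
    "glycerol": ("glycerol", {"C": 3}),
    "ATP": ("ATP", {"C": 10, "N": 5, "P": 3}),
    "ADP": ("ADP", {"C": 10, "N": 5, "P": 2}),
    "AMP": ("AMP", {"C": 10, "N": 5, "P": 1}),
    "Pi": ("orthophosphate", {"P": 1}),
    "glycerol3P": ("sn-glycerol 3-phosphate", {"C": 3, "P": 1}),
    "Q": ("ubiquinone-8", {"C": 49}),
    "QH2": ("ubiquinol-8", {"C": 49}),
    "DHAP": ("dihydroxyacetone phosphate", {"C": 3, "P": 1}),
    "GAP": ("glyceraldehyde 3-phosphate", {"C": 3, "P": 1}),
    "FBP": ("fructose 1,6-bisphosphate", {"C": 6, "P": 2}),
    "F6P": ("fructose 6-phosphate", {"C": 6, "P": 1}),
    "G6P": ("glucose 6-phosphate", {"C": 6, "P": 1}),
    "NADP": ("NADP+", {"C": 21, "N": 7, "P": 3}),
    "NADPH": ("NADPH", {"C": 21, "N": 7, "P": 3}),
    "6PG": ("6-phosphogluconate", {"C": 6, "P": 1}),
    "KDPG": ("2-keto-3-deoxy-6-phosphogluconate", {"C": 6, "P": 1}),
    "pyruvate": ("pyruvate", {"C": 3}),
    "NAD": ("NAD+", {"C": 21, "N": 7, "P": 2}),
    "NADH": ("NADH", {"C": 21, "N": 7, "P": 2}),
    "13BPG": ("1,3-bisphosphoglycerate", {"C": 3, "P": 2}),
    "3PG": ("3-phosphoglycerate", {"C": 3, "P": 1}),
    "2PG": ("2-phosphoglycerate", {"C": 3, "P": 1}),
    "PEP": ("phosphoenolpyruvate", {"C": 3, "P": 1}),
    "methylglyoxal": ("methylglyoxal", {"C": 3}),
    "GSH": ("glutathione", {"C": 10, "N": 3}),
    "lactoylGSH": ("(R)-S-lactoylglutathione", {"C": 13, "N": 3}),
    "Dlactate": ("D-lactate", {"C": 3}),
    "lactaldehyde": ("lactaldehyde", {"C": 3}),
    "Llactate": ("L-lactate", {"C": 3}),
    "3PHP": ("3-phosphohydroxypyruvate", {"C": 3, "P": 1}),
    "glutamate": ("L-glutamate", {"C": 5, "N": 1}),
    "pserine": ("O-phospho-L-serine", {"C": 3, "N": 1, "P": 1}),
    "2KG": ("2-ketoglutarate", {"C": 5}),
    "serine": ("L-serine", {"C": 3, "N": 1}),
    "NH3": ("ammonia", {"N": 1}),
}

# id -> (stoichiometry, reversible, delta_g_kJ_mol, tags)
_FIXTURE_REACTIONS: dict[str, tuple[dict[str, int], bool, float, tuple[str, ...]]] = {
    "GLPK": ({"glycerol": -1, "ATP": -1, "glycerol3P": 1, "ADP": 1}, False, -25.0, ()),
    "GLPD": ({"glycerol3P": -1, "Q": -1, "DHAP": 1, "QH2": 1}, False, -60.0, ()),
    "TPI": ({"DHAP": -1, "GAP": 1}, True, 5.5, ()),
    "FBA": ({"DHAP": -1, "GAP": -1, "FBP": 1}, True, -20.0, ()),
    "FBPASE": ({"FBP": -1, "F6P": 1, "Pi": 1}, False, -10.0, ()),
    "PGI": ({"F6P": -1, "G6P": 1}, True, -2.5, ()),
    "ZWF_L": (
        {"G6P": -1, "NADP": -1, "6PG": 1, "NADPH": 1}, False, -30.0,
        ("lumped:ZWF+PGL",),
    ),
    "EDD": ({"6PG": -1, "KDPG": 1}, False, -40.0, ()),
    "EDA": ({"KDPG": -1, "pyruvate": 1, "GAP": 1}, False, 15.0, ()),
    "GAPD": (
        {"GAP": -1, "NAD": -1, "Pi": -1, "13BPG": 1, "NADH": 1}, True, 7.0, (),
    ),
    "PGK": ({"13BPG": -1, "ADP": -1, "3PG": 1, "ATP": 1}, True, -19.0, ()),
    "PGM": ({"3PG": -1, "2PG": 1}, True, 4.2, ()),
    "ENO": ({"2PG": -1, "PEP": 1}, True, -4.0, ()),
    "PYK": ({"PEP": -1, "ADP": -1, "pyruvate": 1, "ATP": 1}, False, -25.0, ()),
    "PPSA": (
        {"pyruvate": -1, "ATP": -1, "PEP": 1, "AMP": 1, "Pi": 1}, False, -10.0, (),
    ),
    "ADK": ({"ATP": -1, "AMP": -1, "ADP": 2}, True, 0.0, ()),
    "MGSA": ({"DHAP": -1, "methylglyoxal": 1, "Pi": 1}, False, -20.0, ()),
    "MGGSH": (
        {"methylglyoxal": -1, "GSH": -1, "lactoylGSH": 1}, False, -25.0,
        ("lumped:hemithioacetal+GloA",),
    ),
    "GLOB": ({"lactoylGSH": -1, "Dlactate": 1, "GSH": 1}, False, -15.0, ()),
    "HCHA": ({"methylglyoxal": -1, "Dlactate": 1}, False, -40.0, ()),
    "GLDA": (
        {"methylglyoxal": -1, "NADH": -1, "lactaldehyde": 1, "NAD": 1},
        False, -25.0, (),
    ),
    "ALDA": (
        {"lactaldehyde": -1, "NAD": -1, "Llactate": 1, "NADH": 1}, False, -35.0, (),
    ),
    "LLDD": ({"Llactate": -1, "Q": -1, "pyruvate": 1, "QH2": 1}, False, -30.0, ()),
    "DLD": ({"Dlactate": -1, "Q": -1, "pyruvate": 1, "QH2": 1}, False, -30.0, ()),
    "SERA": ({"3PG": -1, "NAD": -1, "3PHP": 1, "NADH": 1}, True, 30.0, ()),
    "SERC": (
        {"3PHP": -1, "glutamate": -1, "pserine": 1, "2KG": 1}, False, -5.0, (),
    ),
    "SERB": ({"pserine": -1, "serine": 1, "Pi": 1}, False, -10.0, ()),
    "SDAA": ({"serine": -1, "pyruvate": 1, "NH3": 1}, False, -35.0, ()),
    "GLUDY": (
        {"2KG": -1, "NH3": -1, "NADPH": -1, "glutamate": 1, "NADP": 1},
        False, -30.0, (),
    ),
    "THD": ({"NADH": -1, "NADP": -1, "NAD": 1, "NADPH": 1}, True, 0.0, ()),
    "NDH": ({"NADH": -1, "Q": -1, "NAD": 1, "QH2": 1}, False, -80.0, ()),
    "QOX": ({"QH2": -1, "Q": 1}, False, -100.0, ()),
}


def build_central_carbon_fixture() -> MetabolicNetwork:
    """The curated glycerol -> pyruvate central-carbon network
    (36 metabolites, 32 reactions; C/N/P balance exactly)."""
    metabolites = [
        Metabolite(id=mid, name=name, elemental_tally=tally)
        for mid, (name, tally) in _FIXTURE_METABOLITES.items()
    ]
    reactions = [
        Reaction(
            id=rid,
            stoichiometry={m: Fraction(c) for m, c in stoich.items()},
            reversible=rev,
            delta_g_standard=dg,
            tags=frozenset(tags),
        )
        for rid, (stoich, rev, dg, tags) in _FIXTURE_REACTIONS.items()
    ]
    network = MetabolicNetwork(metabolites, reactions)
    problems = network.check_elemental_balance()
    assert not problems, f"fixture imbalance: {problems}"
    return network


def block_thermodynamically(
    network: MetabolicNetwork, reaction_id: str, g0_kj_mol: float
) -> MetabolicNetwork:
    """Copy of the network with one reaction's standard Gibbs energy
    replaced (a large positive value exceeds any concentration-box span and
    renders routes through the reaction infeasible)."""
    if not network.has_reaction(reaction_id):
        raise NetworkError(f"unknown reaction {reaction_id!r}")
    from .model_io import apply_alterations

    return apply_alterations(
        network,
        [{"action": "set_delta_g", "id": reaction_id, "delta_g_kJ_mol": g0_kj_mol}],
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _subset_flux_feasible(
    directed: DirectedNetwork, subset: tuple[str, ...], beta: float
) -> bool:
    """LP: does a flux vector supported on ``subset`` with v_obj = -1 and
    0 <= v <= beta balance every metabolite?"""
    met_index = {m.id: j for j, m in enumerate(directed.metabolites)}
    nm, ns = len(met_index), len(subset)
    A = np.zeros((nm, ns))
    for i, did in enumerate(subset):
        for met, coeff in directed.directed(did).stoichiometry.items():
            A[met_index[met], i] = float(coeff)
    b = np.zeros(nm)
    for met, coeff in directed.objective_reaction.stoichiometry.items():
        b[met_index[met]] = float(coeff)  # -(-1) * coeff
    res = linprog(
        c=np.zeros(ns), A_eq=A, b_eq=b, bounds=[(0.0, beta)] * ns, method="highs"
    )
    return res.status == 0


def _subset_thermo_feasible(
    directed: DirectedNetwork, subset: tuple[str, ...], thermo: ThermoParams
) -> bool:
    """LP: is there an in-box x giving every subset reaction a non-negative
    driving force?  (-g0 - S^T x >= 0  <=>  S^T x <= -g0)"""
    x_ids = [m for m in thermo.ln_c_min]
    x_index = {mid: k for k, mid in enumerate(x_ids)}
    rows = []
    rhs = []
    for did in subset:
        d = directed.directed(did)
        if d.g0_rt is None:
            continue
        row = np.zeros(len(x_ids))
        for met, coeff in d.stoichiometry.items():
            if met in x_index:
                row[x_index[met]] += float(coeff)
        rows.append(row)
        rhs.append(-d.g0_rt)
    if not rows:
        return True
    bounds = [(thermo.ln_c_min[m], thermo.ln_c_max[m]) for m in x_ids]
    res = linprog(
        c=np.zeros(len(x_ids)),
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        bounds=bounds,
        method="highs",
    )
    return res.status == 0


def brute_force_enumerate(
    directed: DirectedNetwork,
    thermo: ThermoParams | None,
    max_cardinality: int | None = None,
    beta: float | None = None,
) -> list[frozenset[str]]:
    """All minimum-cardinality feasible active sets, by exhaustive subset
    search in order of increasing cardinality.

    A subset is feasible iff a restricted flux LP balances the objective at
    rate -1 and (when thermodynamics are given) a concentration LP makes all
    subset reactions exergonic simultaneously.  Subsets containing both
    directions of one parent are skipped (the MILP forbids them).  Guarded
    to <= 20 directed reactions.
    """
    ids = directed.directed_ids
    if len(ids) > 20:
        raise ValueError("brute-force oracle guard: > 20 directed reactions")
    beta = directed.beta if beta is None else beta
    max_card = len(ids) if max_cardinality is None else max_cardinality
    both_dirs = [
        (fwd, bwd) for fwd, bwd in directed.pairing.values() if bwd is not None
    ]
    for k in range(1, max_card + 1):
        found = []
        for subset in itertools.combinations(ids, k):
            s = set(subset)
            if any(f in s and b in s for f, b in both_dirs):
                continue
            if not _subset_flux_feasible(directed, subset, beta):
                continue
            if thermo is not None and not _subset_thermo_feasible(
                directed, subset, thermo
            ):
                continue
            found.append(frozenset(subset))
        if found:
            return found
    return []


# ---------------------------------------------------------------------------
# random planted networks
# ---------------------------------------------------------------------------

@dataclass
class PlantedNetwork:
    """A random network whose unique shortest feasible source -> sink route
    is known by construction (rejection-checked against the oracle)."""

    network: MetabolicNetwork
    planted_path: list[str]
    source: str
    sink: str
    seed: int
    n_distractors: int


def _planted_directed(
    network: MetabolicNetwork, source: str, sink: str, beta: float = 10.0
) -> tuple[DirectedNetwork, ThermoParams]:
    spec = ObjectiveSpec(
        source_metabolite=source, sink_metabolite=sink, atp_yield=0
    )
    with_obj = add_objective_reaction(network, spec)
    directed = split_reactions(with_obj, beta=beta)
    thermo = build_thermo_params(directed)
    return directed, thermo


def generate_planted_network(
    n_metabolites: int,
    n_distractors: int,
    path_length: int,
    seed: int,
    max_attempts: int = 60,
) -> PlantedNetwork:
    """Random network with a planted linear source -> sink chain of
    ``path_length`` irreversible reactions (g0 uniform in [-5, -1] RT,
    guaranteed exergonic in the default box) plus random irreversible
    distractor reactions that never complete a route shorter than or as
    short as the planted one — enforced by re-running the brute-force
    oracle and rejecting offending draws.  Deterministic for a fixed seed.
    """
    if path_length < 1:
        raise ValueError("path_length must be >= 1")
    if n_metabolites < path_length + 1:
        raise ValueError("need at least path_length + 1 metabolites")
    from .thermodynamics import R_KJ_PER_MOL_K, DEFAULT_TEMPERATURE_K

    rt = R_KJ_PER_MOL_K * DEFAULT_TEMPERATURE_K
    rng = np.random.default_rng(seed)
    met_ids = [f"M{i}" for i in range(n_metabolites)]
    source, sink = met_ids[0], met_ids[path_length]
    metabolites = [Metabolite(id=m) for m in met_ids]

    chain = []
    for i in range(path_length):
        chain.append(
            Reaction(
                id=f"P{i}",
                stoichiometry={met_ids[i]: Fraction(-1), met_ids[i + 1]: Fraction(1)},
                reversible=False,
                delta_g_standard=float(rng.uniform(-5, -1)) * rt,
            )
        )
    planted_ids = [r.id for r in chain]

    for attempt in range(max_attempts):
        distractors = []
        for j in range(n_distractors):
            n_sub = int(rng.integers(1, 3))
            n_prod = int(rng.integers(1, 3))
            subs = rng.choice(n_metabolites, size=n_sub, replace=False)
            prods = rng.choice(n_metabolites, size=n_prod, replace=False)
            stoich: dict[str, Fraction] = {}
            for s in subs:
                stoich[met_ids[s]] = stoich.get(met_ids[s], Fraction(0)) - int(
                    rng.integers(1, 3)
                )
            for p in prods:
                stoich[met_ids[p]] = stoich.get(met_ids[p], Fraction(0)) + int(
                    rng.integers(1, 3)
                )
            stoich = {m: c for m, c in stoich.items() if c != 0}
            if not stoich:
                continue
            distractors.append(
                Reaction(
                    id=f"D{j}",
                    stoichiometry=stoich,
                    reversible=False,
                    delta_g_standard=float(rng.uniform(-5, -1)) * rt,
                )
            )
        try:
            network = MetabolicNetwork(list(metabolites), chain + distractors)
        except NetworkError:
            continue
        directed, thermo = _planted_directed(network, source, sink)
        if len(directed.directed_reactions) > 20:
            raise ValueError("too many directed reactions for the oracle guard")
        minima = brute_force_enumerate(directed, thermo, max_cardinality=path_length)
        if minima == [frozenset(planted_ids)]:
            return PlantedNetwork(
                network=network,
                planted_path=planted_ids,
                source=source,
                sink=sink,
                seed=seed,
                n_distractors=n_distractors,
            )
    raise GenerationError(
        f"no admissible distractor draw in {max_attempts} attempts (seed={seed})"
    )


def generate_parallel_routes(
    n_routes: int = 12, route_length: int = 3
) -> tuple[MetabolicNetwork, str, str]:
    """Network of ``n_routes`` metabolite-disjoint source -> sink chains of
    equal length; pairwise indicator distance between routes is
    2 * route_length.  Used to exercise the solution-cap stopping rule."""
    metabolites = [Metabolite(id="S"), Metabolite(id="T")]
    reactions = []
    for r in range(n_routes):
        prev = "S"
        for step in range(route_length):
            nxt = "T" if step == route_length - 1 else f"I{r}_{step}"
            if nxt != "T":
                metabolites.append(Metabolite(id=nxt))
            reactions.append(
                Reaction(
                    id=f"R{r}_{step}",
                    stoichiometry={prev: Fraction(-1), nxt: Fraction(1)},
                    reversible=False,
                    delta_g_standard=-7.5,
                )
            )
            prev = nxt
    return MetabolicNetwork(metabolites, reactions), "S", "T"
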