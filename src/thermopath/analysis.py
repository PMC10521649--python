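"""Post-processing of enumerated pathways.

Solver-independent verification, substrate-level ATP accounting, strategy
classification against committing-enzyme markers, carbon-route segment
extraction and route-variant counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .enumeration import PathwaySolution, SolutionSet
from .network import DirectedNetwork
from .thermodynamics import ThermoParams, driving_force

__all__ = [
    "StrategyMarkers",
    "DEFAULT_MARKERS",
    "DEFAULT_COFACTORS",
    "VerificationReport",
    "verify_solution",
    "net_atp_yield",
    "classify_strategy",
    "route_segment",
    "count_segment_variants",
    "count_strategies",
    "export_solutions",
    "NoPathError",
]


class NoPathError(LookupError):
    """No carbon route between the requested metabolites in the active set."""


@dataclass(frozen=True)
class StrategyMarkers:
    """Committing-enzyme markers defining each broad pathway strategy.

    A strategy label applies to a solution iff every marker reaction (and
    every co-required reaction) is active, in either direction.
    """

    markers: Mapping[str, frozenset[str]]
    co_required: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return sorted(self.markers)


#: classification defaults for the glycerol -> pyruvate search:
#: EMP lower glycolysis, Entner-Doudoroff, methylglyoxal bypass, serine shunt
DEFAULT_MARKERS = StrategyMarkers(
    markers={
        "EMP": frozenset({"PGM", "ENO", "PYK"}),
        "ED": frozenset({"EDA"}),
        "methylglyoxal": frozenset({"MGSA"}),
        "serine_shunt": frozenset({"SDAA"}),
    },
    co_required={"serine_shunt": frozenset({"SERA", "SERC", "SERB"})},
)

#: currency metabolites excluded from carbon-route path finding
DEFAULT_COFACTORS = frozenset(
    {
        "ATP", "ADP", "AMP", "Pi",
        "NAD", "NADH", "NADP", "NADPH",
        "Q", "QH2", "GSH", "glutamate", "2KG", "NH3", "CoA",
    }
)


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    """Raw-arithmetic re-check of a solution against all constraint families."""

    mass_balance_max_residual: float
    flux_bound_violations: int
    indicator_violations: int
    thermo_violations: list[tuple[str, float]]
    tolerance: float

    @property
    def passed(self) -> bool:
        return (
            self.mass_balance_max_residual <= self.tolerance
            and self.flux_bound_violations == 0
            and self.indicator_violations == 0
            and not self.thermo_violations
        )


def verify_solution(
    directed: DirectedNetwork,
    thermo: ThermoParams | None,
    solution: PathwaySolution,
    tolerance: float = 1e-6,
) -> VerificationReport:
    """Re-evaluate mass balance, flux bounds, indicator coupling and the
    second law for a solution, independently of any solver."""
    known = set(directed.directed_ids)
    bad = (set(solution.fluxes) | set(solution.active_set)) - known
    if bad:
        raise KeyError(f"solution references unknown directed ids: {sorted(bad)}")

    # mass balance including the fixed objective rate v_obj = -1
    balance: dict[str, float] = {m.id: 0.0 for m in directed.metabolites}
    for did, v in solution.fluxes.items():
        for met, coeff in directed.directed(did).stoichiometry.items():
            balance[met] += float(coeff) * v
    for met, coeff in directed.objective_reaction.stoichiometry.items():
        balance[met] += float(coeff) * (-1.0)
    max_residual = max((abs(r) for r in balance.values()), default=0.0)

    beta = directed.beta
    flux_bound_violations = sum(
        1 for v in solution.fluxes.values() if v < -tolerance or v > beta + tolerance
    )
    indicator_violations = sum(
        1
        for did, v in solution.fluxes.items()
        if v > tolerance and did not in solution.active_set
    )

    thermo_violations: list[tuple[str, float]] = []
    if thermo is not None:
        for did in sorted(solution.active_set):
            d = directed.directed(did)
            if d.g0_rt is None:
                continue
            df = driving_force(d, solution.ln_concentrations)
            if df < -tolerance:
                thermo_violations.append((did, -df))
    return VerificationReport(
        mass_balance_max_residual=max_residual,
        flux_bound_violations=flux_bound_violations,
        indicator_violations=indicator_violations,
        thermo_violations=thermo_violations,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# ATP accounting
# ---------------------------------------------------------------------------

def net_atp_yield(
    directed: DirectedNetwork,
    solution: PathwaySolution,
    atp_id: str = "ATP",
    max_denominator: int = 10**6,
) -> Fraction:
    """Net substrate-level ATP formed per unit sink production.

    Sums flux times the ATP stoichiometric coefficient over all active
    reactions (the injected objective reaction excluded) using exact
    rational arithmetic on denominator-limited fluxes.  For a valid solution
    this equals the injected ATP yield n, since the objective reaction is
    the only other ATP term in a balanced network.
    """
    if atp_id not in {m.id for m in directed.metabolites}:
        raise KeyError(f"no metabolite {atp_id!r} in network")
    total = Fraction(0)
    for did, v in solution.fluxes.items():
        coeff = directed.directed(did).stoichiometry.get(atp_id)
        if coeff is None:
            continue
        total += Fraction(v).limit_denominator(max_denominator) * coeff
    # sink production rate is 1 by construction (v_obj = -1), so the flux sum
    # is already per unit sink
    return total


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_strategy(
    solution: PathwaySolution,
    directed: DirectedNetwork,
    markers: StrategyMarkers = DEFAULT_MARKERS,
) -> frozenset[str]:
    """Strategy labels whose marker (and co-required) reactions are all
    active in the solution, matching parent reaction ids in either
    direction.  Empty set means unclassified."""
    parents = solution.parent_active_set(directed)
    labels = set()
    for label, marker_ids in markers.markers.items():
        required = set(marker_ids) | set(markers.co_required.get(label, ()))
        if required <= parents:
            labels.add(label)
    return frozenset(labels)


def count_strategies(
    solution_sets: Mapping[int, SolutionSet] | Iterable[SolutionSet],
    directed_by_yield: Mapping[int, DirectedNetwork],
    markers: StrategyMarkers = DEFAULT_MARKERS,
) -> tuple[int, frozenset[str]]:
    """Number (and set) of distinct strategy labels across all solutions."""
    sets = (
        solution_sets.values()
        if isinstance(solution_sets, Mapping)
        else solution_sets
    )
    seen: set[str] = set()
    for ss in sets:
        directed = directed_by_yield[ss.atp_yield]
        for sol in ss.solutions:
            seen |= classify_strategy(sol, directed, markers)
    return len(seen), frozenset(seen)


# ---------------------------------------------------------------------------
# route segments
# ---------------------------------------------------------------------------

def _active_carbon_graph(
    directed: DirectedNetwork,
    solution: PathwaySolution,
    cofactors: frozenset[str],
) -> nx.DiGraph:
    """Bipartite metabolite/reaction digraph over the active set, with
    cofactor metabolites removed so paths follow the main carbon skeleton."""
    g = nx.DiGraph()
    for did in solution.active_set:
        d = directed.directed(did)
        rnode = ("R", d.parent_id)
        for met, coeff in d.stoichiometry.items():
            if met in cofactors:
                continue
            mnode = ("M", met)
            if coeff < 0:
                g.add_edge(mnode, rnode)
            else:
                g.add_edge(rnode, mnode)
    return g


def route_segment(
    directed: DirectedNetwork,
    solution: PathwaySolution,
    from_metabolite: str,
    to_metabolite: str,
    cofactors: frozenset[str] = DEFAULT_COFACTORS,
    via: str | None = None,
) -> list[str]:
    """Shortest main-carbon reaction sequence between two metabolites
    within a solution's active subnetwork.

    ``via`` forces the path through a waypoint metabolite.  This anchors a
    segment at its namesake intermediate when a solution runs several
    branches in parallel (e.g. the serine-shunt segment of a solution that
    also carries lower EMP flux must pass through serine, not enolase).
    """
    g = _active_carbon_graph(directed, solution, cofactors)

    def leg(a: str, b: str) -> list[str]:
        src, dst = ("M", a), ("M", b)
        if src not in g or dst not in g:
            raise NoPathError(
                f"{a} -> {b}: metabolite absent from the active subnetwork"
            )
        try:
            path = nx.shortest_path(g, src, dst)
        except nx.NetworkXNoPath:
            raise NoPathError(f"no active route {a} -> {b}")
        return [name for kind, name in path if kind == "R"]

    if via is None:
        return leg(from_metabolite, to_metabolite)
    return leg(from_metabolite, via) + leg(via, to_metabolite)


def count_segment_variants(
    solution_sets: Mapping[int, SolutionSet] | Iterable[SolutionSet],
    directed_by_yield: Mapping[int, DirectedNetwork],
    from_metabolite: str,
    to_metabolite: str,
    cofactors: frozenset[str] = DEFAULT_COFACTORS,
) -> int:
    """Distinct reaction-id sets realising a segment across all solutions."""
    sets = (
        solution_sets.values()
        if isinstance(solution_sets, Mapping)
        else solution_sets
    )
    variants: set[frozenset[str]] = set()
    for ss in sets:
        directed = directed_by_yield[ss.atp_yield]
        for sol in ss.solutions:
            try:
                seg = route_segment(
                    directed, sol, from_metabolite, to_metabolite, cofactors
                )
            except NoPathError:
                continue
            variants.add(frozenset(seg))
    return len(variants)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def solution_set_to_dict(ss: SolutionSet) -> dict:
    return {
        "atp_yield": ss.atp_yield,
        "status": ss.status,
        "cuts_applied": ss.cuts_applied,
        "solutions": [
            {
                "active_set": sorted(sol.active_set),
                "fluxes": {k: sol.fluxes[k] for k in sorted(sol.fluxes)},
                "ln_concentrations": {
                    k: sol.ln_concentrations[k]
                    for k in sorted(sol.ln_concentrations)
                },
                "cardinality": sol.cardinality,
                "atp_yield": sol.atp_yield,
            }
            for sol in ss.solutions
        ],
    }


def export_solutions(
    solution_sets: Mapping[int, SolutionSet],
    directed_by_yield: Mapping[int, DirectedNetwork],
    out_dir: str | Path,
    markers: StrategyMarkers = DEFAULT_MARKERS,
    mg_segment: tuple[str, str, str | None] = ("methylglyoxal", "pyruvate", None),
    serine_segment: tuple[str, str, str | None] = ("3PG", "pyruvate", "serine"),
) -> list[Path]:
    """Write one JSON per solution set, a flat TSV of solutions, and an
    annotation table (strategies, net ATP, segment lengths)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for n, ss in sorted(solution_sets.items()):
        p = out_dir / f"solutions_atp{n:+d}.json"
        with open(p, "w") as fh:
            json.dump(solution_set_to_dict(ss), fh, indent=1)
            fh.write("\n")
        written.append(p)

    flat = out_dir / "solutions.tsv"
    with open(flat, "w") as fh:
        fh.write("solution_id\tatp_yield\tcardinality\treaction_ids\n")
        for n, ss in sorted(solution_sets.items()):
            for i, sol in enumerate(ss.solutions):
                fh.write(
                    f"atp{n:+d}_{i}\t{n}\t{sol.cardinality}\t"
                    + ",".join(sorted(sol.active_set))
                    + "\n"
                )
    written.append(flat)

    annot = out_dir / "annotations.tsv"
    with open(annot, "w") as fh:
        fh.write(
            "solution_id\tatp_yield\tcardinality\tstrategies\tnet_atp\t"
            "mg_segment_len\tserine_segment_len\n"
        )
        for n, ss in sorted(solution_sets.items()):
            directed = directed_by_yield[n]
            for i, sol in enumerate(ss.solutions):
                labels = classify_strategy(sol, directed, markers)
                strategies = ",".join(sorted(labels)) if labels else "unclassified"
                try:
                    atp = str(net_atp_yield(directed, sol))
                except KeyError:  # network without the ATP cofactor
                    atp = "NA"
                seg_lens = []
                for src, dst, via in (mg_segment, serine_segment):
                    try:
                        seg_lens.append(
                            str(len(route_segment(directed, sol, src, dst, via=via)))
                        )
                    except NoPathError:
                        seg_lens.append("NA")
                fh.write(
                    f"atp{n:+d}_{i}\t{n}\t{sol.cardinality}\t{strategies}\t"
                    f"{atp}\t{seg_lens[0]}\t{seg_lens[1]}\n"
                )
    written.append(annot)
    return written
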