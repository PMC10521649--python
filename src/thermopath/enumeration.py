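"""Minimal-pathway MILP and radius-limited integer-cut enumeration.

The search problem: find flux distributions v >= 0 on the unidirectional
network that balance the injected objective reaction at fixed rate -1
(S v = 0 including v_obj), respect per-reaction flux caps beta, and admit a
metabolite log-concentration vector x under which every active reaction is
thermodynamically favourable (second law).  Binary indicators z mark active
reactions; minimising sum(z) yields the shortest pathway.  Alternatives are
enumerated by adding integer cuts that exclude all indicator vectors within
a Hamming radius of each found solution, until a solution cap is hit or the
problem becomes infeasible.

Formulation per directed reaction i (objective reaction exempt):

    0 <= v_i <= beta
    v_i - beta * z_i <= 0          (inactive => zero flux)
    v_i >= eps * z_i               (active => carries measurable flux)
    -g0_i - (S^T x)_i + M_i (1 - z_i) >= 0     (second law, big-M)
    z_fwd + z_bwd <= 1             (no simultaneous two-way use)

plus S v = 0 per metabolite with v_obj fixed at -1, ln Cmin <= x <= ln Cmax,
objective min sum z.  The eps coupling (default 1e-3) pins indicators to the
flux support; without it an integer cut could be escaped by switching on
indicators of zero-flux reactions, yielding duplicate pathways dressed up as
new solutions.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .network import DirectedNetwork, MetabolicNetwork, ObjectiveSpec
from .model_io import add_objective_reaction, split_reactions
from .solvers import get_backend, SolverResult
from .thermodynamics import ThermoParams, build_thermo_params

logger = logging.getLogger(__name__)

__all__ = [
    "EnumerationConfig",
    "MILPProblem",
    "PathwaySolution",
    "SolutionSet",
    "build_milp",
    "solve_min_pathway",
    "add_integer_cut",
    "enumerate_pathways",
    "scan_atp_yields",
]


@dataclass(frozen=True)
class EnumerationConfig:
    """Knobs of the search.

    beta: per-reaction flux cap relative to the unit objective rate.
    max_solutions: stop after this many solutions per ATP yield.
    cut_radius: integer cuts exclude indicator vectors within this Hamming
        distance of found solutions (next solutions differ in > radius
        positions).
    atp_yields: yields n scanned by :func:`scan_atp_yields`.
    min_active_flux: eps of the v >= eps*z coupling.
    """

    beta: float = 10.0
    max_solutions: int = 10
    cut_radius: int = 2
    atp_yields: tuple[int, ...] = (-2, -1, 0, 1, 2)
    solver: str = "highs"
    time_limit_s: float | None = None
    tolerance: float = 1e-6
    min_active_flux: float = 1e-3

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.max_solutions < 1:
            raise ValueError("max_solutions must be >= 1")
        if self.cut_radius < 0:
            raise ValueError("cut_radius must be >= 0")


@dataclass
class PathwaySolution:
    """One enumerated pathway: active set, fluxes and concentrations."""

    active_set: frozenset[str]
    fluxes: dict[str, float]
    ln_concentrations: dict[str, float]
    atp_yield: int
    objective_value: float

    @property
    def cardinality(self) -> int:
        return len(self.active_set)

    def indicator_vector(self, directed_ids: list[str]) -> np.ndarray:
        return np.array([1 if d in self.active_set else 0 for d in directed_ids])

    def parent_active_set(self, directed: DirectedNetwork) -> frozenset[str]:
        return frozenset(directed.parent_of(d) for d in self.active_set)


@dataclass
class SolutionSet:
    """Enumerated solutions for one ATP yield."""

    atp_yield: int
    solutions: list[PathwaySolution]
    status: str  # "cap_reached" | "exhausted" | "time_limit"
    cuts_applied: int = 0


class MILPProblem:
    """Matrix form of the minimal-pathway MILP over a directed network.

    Variable layout: [v (per directed reaction) | z (same order) | x (per
    non-exempt metabolite)].  The objective reaction is not a variable: its
    fixed rate -1 enters the mass-balance right-hand side.
    """

    def __init__(
        self,
        directed: DirectedNetwork,
        thermo: ThermoParams | None,
        config: EnumerationConfig,
    ):
        if not directed.directed_reactions:
            raise ValueError("empty directed network")
        self.directed = directed
        self.thermo = thermo
        self.config = config
        self.directed_ids = directed.directed_ids
        self._build()
        self.cuts: list[tuple[frozenset[str], int]] = []

    # -- construction ----------------------------------------------------
    def _build(self) -> None:
        d = self.directed
        cfg = self.config
        nd = len(self.directed_ids)
        self.x_met_ids = (
            [m for m in d.thermo_metabolite_ids()] if self.thermo is not None else []
        )
        nx = len(self.x_met_ids)
        self.n_var = 2 * nd + nx
        self.iv = {did: i for i, did in enumerate(self.directed_ids)}
        self.iz = {did: nd + i for i, did in enumerate(self.directed_ids)}
        self.ix = {mid: 2 * nd + i for i, mid in enumerate(self.x_met_ids)}

        # objective: minimise sum of indicators
        self.c = np.zeros(self.n_var)
        self.c[nd : 2 * nd] = 1.0
        self.integrality = np.zeros(self.n_var)
        self.integrality[nd : 2 * nd] = 1

        self.lb = np.zeros(self.n_var)
        self.ub = np.full(self.n_var, cfg.beta)
        self.ub[nd : 2 * nd] = 1.0
        if self.thermo is not None:
            for mid, k in self.ix.items():
                self.lb[k] = self.thermo.ln_c_min[mid]
                self.ub[k] = self.thermo.ln_c_max[mid]

        # mass balance: sum_i S_ji v_i = S_j,obj  (because v_obj = -1)
        met_index = {m.id: j for j, m in enumerate(d.metabolites)}
        rows, cols, vals = [], [], []
        for did, i in self.iv.items():
            for met, coeff in d.directed(did).stoichiometry.items():
                rows.append(met_index[met])
                cols.append(i)
                vals.append(float(coeff))
        self.A_eq = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(d.metabolites), self.n_var)
        )
        self.b_eq = np.zeros(len(d.metabolites))
        for met, coeff in d.objective_reaction.stoichiometry.items():
            self.b_eq[met_index[met]] = float(coeff)

        # inequality block (rows appended in families)
        ub_rows, ub_cols, ub_vals, ub_rhs = [], [], [], []

        def add_row(entries: dict[int, float], rhs: float) -> None:
            r = len(ub_rhs)
            for col, val in entries.items():
                ub_rows.append(r)
                ub_cols.append(col)
                ub_vals.append(val)
            ub_rhs.append(rhs)

        for did in self.directed_ids:
            i, z = self.iv[did], self.iz[did]
            # v - beta z <= 0
            add_row({i: 1.0, z: -cfg.beta}, 0.0)
            # eps z - v <= 0  (active reactions carry measurable flux)
            if cfg.min_active_flux > 0:
                add_row({i: -1.0, z: cfg.min_active_flux}, 0.0)
            # second law: g0 + S^T x + M z <= M
            if self.thermo is not None and did in self.thermo.g0:
                M = self.thermo.big_m[did]
                entries = {z: M}
                for met, coeff in d.directed(did).stoichiometry.items():
                    if met in self.ix:
                        entries[self.ix[met]] = (
                            entries.get(self.ix[met], 0.0) + float(coeff)
                        )
                add_row(entries, M - self.thermo.g0[did])
        # direction exclusivity per reversible parent
        for parent, (fwd, bwd) in d.pairing.items():
            if bwd is not None:
                add_row({self.iz[fwd]: 1.0, self.iz[bwd]: 1.0}, 1.0)

        self._base_ub = sp.csr_matrix(
            (ub_vals, (ub_rows, ub_cols)), shape=(len(ub_rhs), self.n_var)
        )
        self._base_rhs = np.array(ub_rhs)

    # -- cuts ------------------------------------------------------------
    def add_cut(self, active_set: frozenset[str], radius: int) -> None:
        """Exclude all indicator vectors within Hamming ``radius`` of
        ``active_set``: sum_{i in A}(1-z_i) + sum_{i not in A} z_i >= radius+1.
        """
        unknown = active_set - set(self.iz)
        if unknown:
            raise KeyError(f"cut references unknown directed ids: {sorted(unknown)}")
        self.cuts.append((frozenset(active_set), int(radius)))

    def _cut_matrix(self) -> tuple[sp.csr_matrix | None, np.ndarray | None]:
        if not self.cuts:
            return None, None
        rows, cols, vals, rhs = [], [], [], []
        for r, (A, radius) in enumerate(self.cuts):
            # sum_{i in A} z_i - sum_{i not in A} z_i <= |A| - radius - 1
            for did, z in self.iz.items():
                rows.append(r)
                cols.append(z)
                vals.append(1.0 if did in A else -1.0)
            rhs.append(len(A) - radius - 1)
        return (
            sp.csr_matrix((vals, (rows, cols)), shape=(len(rhs), self.n_var)),
            np.array(rhs, dtype=float),
        )

    def assemble(self) -> tuple[sp.csr_matrix, np.ndarray]:
        cut_A, cut_b = self._cut_matrix()
        if cut_A is None:
            return self._base_ub, self._base_rhs
        return (
            sp.vstack([self._base_ub, cut_A]).tocsr(),
            np.concatenate([self._base_rhs, cut_b]),
        )

    # -- extraction ------------------------------------------------------
    def extract_solution(self, xvec: np.ndarray, atp_yield: int) -> PathwaySolution:
        nd = len(self.directed_ids)
        zvals = xvec[nd : 2 * nd]
        active = frozenset(
            did for did, z in zip(self.directed_ids, zvals) if z > 0.5
        )
        tol = self.config.tolerance
        fluxes = {
            did: float(xvec[self.iv[did]])
            for did in self.directed_ids
            if xvec[self.iv[did]] > tol
        }
        ln_conc = {mid: float(xvec[k]) for mid, k in self.ix.items()}
        return PathwaySolution(
            active_set=active,
            fluxes=fluxes,
            ln_concentrations=ln_conc,
            atp_yield=atp_yield,
            objective_value=float(np.round(zvals).sum()),
        )


def build_milp(
    directed: DirectedNetwork,
    thermo: ThermoParams | None,
    config: EnumerationConfig | None = None,
) -> MILPProblem:
    """Construct the minimal-pathway MILP for a directed network."""
    return MILPProblem(directed, thermo, config or EnumerationConfig())


def solve_min_pathway(
    problem: MILPProblem, config: EnumerationConfig | None = None
) -> tuple[str, PathwaySolution | None]:
    """Solve for the shortest pathway under the current cut pool.

    Returns ``(status, solution)`` where status is one of ``optimal``,
    ``infeasible``, ``time_limit`` or ``error``; solution is None unless
    optimal.
    """
    cfg = config or problem.config
    backend = get_backend(cfg.solver)
    A_ub, b_ub = problem.assemble()
    res: SolverResult = backend.solve(
        c=problem.c,
        integrality=problem.integrality,
        lb=problem.lb,
        ub=problem.ub,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=problem.A_eq,
        b_eq=problem.b_eq,
        time_limit_s=cfg.time_limit_s,
    )
    if res.status != "optimal":
        return res.status, None
    atp_yield = _atp_yield_of(problem.directed)
    return "optimal", problem.extract_solution(res.x, atp_yield)


def _atp_yield_of(directed: DirectedNetwork) -> int:
    for tag in directed.objective_reaction.tags:
        if tag.startswith("atp_yield="):
            return int(tag.split("=", 1)[1])
    return 0


def add_integer_cut(
    problem: MILPProblem, solution: PathwaySolution, radius: int | None = None
) -> MILPProblem:
    """Add a radius-limited integer cut around ``solution`` (in place)."""
    r = problem.config.cut_radius if radius is None else radius
    problem.add_cut(solution.active_set, r)
    return problem


def enumerate_pathways(
    directed: DirectedNetwork,
    thermo: ThermoParams | None,
    config: EnumerationConfig | None = None,
    verify: bool = True,
) -> SolutionSet:
    """Iterate solve -> record -> cut until exhaustion, cap or time limit."""
    cfg = config or EnumerationConfig()
    problem = build_milp(directed, thermo, cfg)
    atp_yield = _atp_yield_of(directed)
    solutions: list[PathwaySolution] = []
    status = "exhausted"
    t0 = time.monotonic()
    while True:
        if len(solutions) >= cfg.max_solutions:
            status = "cap_reached"
            break
        solve_status, sol = solve_min_pathway(problem, cfg)
        if solve_status == "infeasible":
            status = "exhausted"
            break
        if solve_status in ("time_limit", "error"):
            status = "time_limit" if solve_status == "time_limit" else "error"
            break
        assert sol is not None
        if verify and thermo is not None:
            from .analysis import verify_solution

            report = verify_solution(directed, thermo, sol, tolerance=1e-5)
            if not report.passed:
                # one retry with presolve disabled and tighter handling
                backend = get_backend(cfg.solver)
                A_ub, b_ub = problem.assemble()
                res = backend.solve(
                    problem.c, problem.integrality, problem.lb, problem.ub,
                    A_ub, b_ub, problem.A_eq, problem.b_eq,
                    time_limit_s=cfg.time_limit_s, presolve=False,
                )
                if res.status == "optimal":
                    sol = problem.extract_solution(res.x, atp_yield)
                    report = verify_solution(directed, thermo, sol, tolerance=1e-5)
                if not report.passed:
                    status = "verification_failed"
                    break
        solutions.append(sol)
        problem.add_cut(sol.active_set, cfg.cut_radius)
        logger.info(
            "yield=%+d iteration=%d cardinality=%d status=%s wall=%.2fs",
            atp_yield, len(solutions), sol.cardinality, solve_status,
            time.monotonic() - t0,
        )
        if cfg.time_limit_s is not None and time.monotonic() - t0 > cfg.time_limit_s:
            status = "time_limit"
            break
    return SolutionSet(
        atp_yield=atp_yield,
        solutions=solutions,
        status=status,
        cuts_applied=len(problem.cuts),
    )


def scan_atp_yields(
    network: MetabolicNetwork,
    config: EnumerationConfig | None = None,
    objective: ObjectiveSpec | None = None,
    concentration_overrides=None,
    thermo_free: bool = False,
) -> dict[int, SolutionSet]:
    """Enumerate pathways for every ATP yield in ``config.atp_yields``.

    ``network`` must not carry an injected objective; one is injected per
    yield and each yield gets an independent cut pool.
    """
    cfg = config or EnumerationConfig()
    base_spec = objective or ObjectiveSpec()
    results: dict[int, SolutionSet] = {}
    for n in cfg.atp_yields:
        spec = ObjectiveSpec(
            source_metabolite=base_spec.source_metabolite,
            sink_metabolite=base_spec.sink_metabolite,
            atp_yield=n,
            cofactor_ids=base_spec.cofactor_ids,
        )
        with_obj = add_objective_reaction(network, spec)
        directed = split_reactions(
            with_obj, beta=cfg.beta, require_thermo=not thermo_free
        )
        thermo = (
            None
            if thermo_free
            else build_thermo_params(directed, overrides=concentration_overrides)
        )
        results[n] = enumerate_pathways(directed, thermo, cfg)
    return results
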