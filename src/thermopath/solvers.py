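"""Pluggable MILP backends.

A backend is a callable object solving

    min c.x  s.t.  A_ub x <= b_ub,  A_eq x = b_eq,  lb <= x <= ub,
                   x_i integer where integrality_i = 1

and returning a :class:`SolverResult`.  The default backend wraps the HiGHS
solver shipped with SciPy; additional backends can be registered with
:func:`register_backend`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, Bounds, milp

__all__ = ["SolverResult", "SolverUnavailable", "get_backend", "register_backend"]


class SolverUnavailable(RuntimeError):
    """Requested backend is not registered or cannot run."""


@dataclass
class SolverResult:
    status: str  # "optimal" | "infeasible" | "time_limit" | "error"
    x: np.ndarray | None
    objective: float | None
    message: str = ""


class ScipyHighsBackend:
    """HiGHS branch-and-bound through :func:`scipy.optimize.milp`.

    Single-threaded and deterministic for a fixed problem.
    """

    name = "highs"

    def solve(
        self,
        c: np.ndarray,
        integrality: np.ndarray,
        lb: np.ndarray,
        ub: np.ndarray,
        A_ub: sp.spmatrix | None,
        b_ub: np.ndarray | None,
        A_eq: sp.spmatrix | None,
        b_eq: np.ndarray | None,
        time_limit_s: float | None = None,
        presolve: bool = True,
    ) -> SolverResult:
        constraints = []
        if A_ub is not None and A_ub.shape[0]:
            constraints.append(
                LinearConstraint(A_ub, -np.inf * np.ones(A_ub.shape[0]), b_ub)
            )
        if A_eq is not None and A_eq.shape[0]:
            constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
        options: dict = {"presolve": presolve}
        if time_limit_s is not None:
            options["time_limit"] = float(time_limit_s)
        res = milp(
            c=c,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(lb, ub),
            options=options,
        )
        if res.status == 0:
            return SolverResult("optimal", res.x, float(res.fun), res.message)
        if res.status == 2:
            return SolverResult("infeasible", None, None, res.message)
        if res.status == 1:
            return SolverResult("time_limit", None, None, res.message)
        return SolverResult("error", None, None, res.message)


_BACKENDS: dict[str, type] = {"highs": ScipyHighsBackend}


def register_backend(name: str, cls: type) -> None:
    _BACKENDS[name] = cls


def get_backend(name: str = "highs"):
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise SolverUnavailable(
            f"no MILP backend named {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
    return cls()
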