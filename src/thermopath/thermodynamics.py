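"""Thermodynamic bookkeeping for pathway search.

Standard reaction Gibbs energies are converted to dimensionless RT units,
g0 = deltaG'0 / RT.  Metabolite concentrations enter the constraints only
through their natural logarithms x = ln c, each confined to a box
[ln c_min, ln c_max].  The second law requires every active reaction to have
non-negative driving force -g0 - S^T x at some common concentration vector;
in the MILP this is linearised with a per-reaction big-M constant so the
constraint is vacuous for inactive reactions.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .network import DirectedNetwork, DirectedReaction, MetabolicNetwork

__all__ = [
    "R_KJ_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_C_MIN",
    "DEFAULT_C_MAX",
    "PHYSIOLOGICAL_OVERRIDES",
    "ThermoParams",
    "gibbs_to_rt",
    "build_concentration_bounds",
    "compute_big_m",
    "driving_force",
    "build_thermo_params",
    "read_concentration_overrides",
    "read_g0_tsv",
]

#: gas constant, kJ / (mol K)
R_KJ_PER_MOL_K = 8.314462618e-3
DEFAULT_TEMPERATURE_K = 298.15

#: default concentration box, mol/L: 1 uM to 10 mM
DEFAULT_C_MIN = 1e-6
DEFAULT_C_MAX = 1e-2

#: big-M safety margin, RT units
BIG_M_MARGIN = 1.0

# Literature-typical physiological ranges (mol/L) for central cofactors and
# intermediates, replaceable via a TSV override file.  These stand in for
# organism-specific measurements and are NOT applied unless requested.
PHYSIOLOGICAL_OVERRIDES: dict[str, tuple[float, float]] = {
    "ATP": (1e-3, 1e-2),
    "ADP": (1e-4, 1e-3),
    "AMP": (1e-5, 1e-3),
    "Pi": (1e-3, 1e-2),
    "NAD": (1e-3, 5e-3),
    "NADH": (5e-5, 5e-4),
    "NADP": (1e-5, 5e-4),
    "NADPH": (5e-5, 5e-4),
    "CoA": (1e-4, 1e-3),
    "acetyl_CoA": (1e-4, 1e-3),
    "glutamate": (1e-2, 1e-1),
    "2KG": (1e-4, 1e-3),
    "PEP": (1e-5, 1e-3),
    "pyruvate": (1e-4, 5e-3),
    "3PG": (1e-4, 5e-3),
    "FBP": (1e-4, 1e-2),
}


def gibbs_to_rt(
    delta_g_kj_mol: float, temperature_k: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Convert a Gibbs energy in kJ/mol to dimensionless RT units."""
    if not math.isfinite(delta_g_kj_mol):
        raise ValueError("Gibbs energy must be finite")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return delta_g_kj_mol / (R_KJ_PER_MOL_K * temperature_k)


@dataclass
class ThermoParams:
    """Thermodynamic side of the MILP: g0, concentration boxes and big-M."""

    g0: dict[str, float]
    ln_c_min: dict[str, float]
    ln_c_max: dict[str, float]
    big_m: dict[str, float]
    temperature_k: float = DEFAULT_TEMPERATURE_K

    @property
    def rt_kj_mol(self) -> float:
        return R_KJ_PER_MOL_K * self.temperature_k

    def __post_init__(self):
        for met in self.ln_c_min:
            if self.ln_c_min[met] > self.ln_c_max[met] + 1e-12:
                raise ValueError(f"ln_c_min > ln_c_max for {met}")


def build_concentration_bounds(
    network: MetabolicNetwork | DirectedNetwork,
    overrides: Mapping[str, tuple[float, float]] | None = None,
    c_min: float = DEFAULT_C_MIN,
    c_max: float = DEFAULT_C_MAX,
) -> tuple[dict[str, float], dict[str, float]]:
    """ln-concentration boxes for every non-exempt metabolite.

    Every metabolite gets [ln c_min, ln c_max] (defaults: 1 uM, 10 mM)
    unless an override (c_min, c_max) in mol/L is given for it.
    """
    overrides = dict(overrides or {})
    known = set(network.metabolite_ids)
    unknown = set(overrides) - known
    if unknown:
        raise KeyError(f"override(s) for unknown metabolite(s): {sorted(unknown)}")
    ln_min: dict[str, float] = {}
    ln_max: dict[str, float] = {}
    for m in network.metabolites:
        if m.thermo_exempt:
            continue
        lo, hi = overrides.get(m.id, (c_min, c_max))
        if lo <= 0 or hi <= 0:
            raise ValueError(f"non-positive concentration bound for {m.id}")
        if lo > hi:
            raise ValueError(f"c_min > c_max for {m.id}")
        ln_min[m.id] = math.log(lo)
        ln_max[m.id] = math.log(hi)
    return ln_min, ln_max


def compute_big_m(
    reaction: DirectedReaction,
    ln_c_min: Mapping[str, float],
    ln_c_max: Mapping[str, float],
    margin: float = BIG_M_MARGIN,
) -> float:
    """Smallest safe big-M (plus margin) for one directed reaction.

    M must dominate g0 + S^T x over the whole concentration box so the
    second-law constraint is vacuous when the indicator is off.  The
    box-corner maximum takes ln c_max for products and ln c_min for
    substrates.  Floored at zero (the constraint is already vacuous for
    strongly exergonic reactions).  Metabolites absent from the bound maps
    (thermo-exempt) do not contribute.
    """
    if reaction.g0_rt is None:
        raise ValueError(f"{reaction.id}: no g0")
    worst = reaction.g0_rt
    for met, coeff in reaction.stoichiometry.items():
        if met not in ln_c_min:
            if met in ln_c_max:
                raise KeyError(f"inconsistent bounds for {met}")
            continue  # thermo-exempt
        bound = ln_c_max[met] if coeff > 0 else ln_c_min[met]
        worst += float(coeff) * bound
    return max(0.0, worst + margin)


def driving_force(
    reaction: DirectedReaction, x: Mapping[str, float]
) -> float:
    """-g0 - S^T x in RT units; positive means exergonic at x.

    Thermo-exempt metabolites must simply be absent from ``x``; a missing
    concentration for any other participant is an error only if the caller
    supplied bounds for it elsewhere, so here absence means exemption.
    """
    if reaction.g0_rt is None:
        raise ValueError(f"{reaction.id}: no g0")
    total = -reaction.g0_rt
    for met, coeff in reaction.stoichiometry.items():
        if met in x:
            total -= float(coeff) * x[met]
    return total


def build_thermo_params(
    directed: DirectedNetwork,
    overrides: Mapping[str, tuple[float, float]] | None = None,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    margin: float = BIG_M_MARGIN,
) -> ThermoParams:
    """Assemble g0 / bounds / big-M for a directed network in one call."""
    ln_min, ln_max = build_concentration_bounds(directed, overrides)
    g0 = {}
    big_m = {}
    for d in directed.directed_reactions:
        if d.g0_rt is None:
            continue
        g0[d.id] = d.g0_rt
        big_m[d.id] = compute_big_m(d, ln_min, ln_max, margin=margin)
    return ThermoParams(
        g0=g0, ln_c_min=ln_min, ln_c_max=ln_max, big_m=big_m,
        temperature_k=temperature_k,
    )


# ---------------------------------------------------------------------------
# side-channel file formats
# ---------------------------------------------------------------------------

def read_concentration_overrides(path: str | Path) -> dict[str, tuple[float, float]]:
    """TSV with columns metabolite_id, c_min_molar, c_max_molar."""
    overrides = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            overrides[row["metabolite_id"]] = (
                float(row["c_min_molar"]),
                float(row["c_max_molar"]),
            )
    return overrides


def read_g0_tsv(path: str | Path) -> dict[str, float]:
    """TSV with columns reaction_id, delta_g_kJ_mol."""
    values = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            values[row["reaction_id"]] = float(row["delta_g_kJ_mol"])
    return values
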