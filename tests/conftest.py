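"""Shared fixtures: the central-carbon network, tiny hand-built networks,
and a session-wide enumeration scan reused by analysis and acceptance tests.
"""

from __future__ import annotations

from fractions import Fraction

import pytest

from thermopath import (
    EnumerationConfig,
    MetabolicNetwork,
    Metabolite,
    ObjectiveSpec,
    Reaction,
    add_objective_reaction,
    build_central_carbon_fixture,
    build_thermo_params,
    scan_atp_yields,
    split_reactions,
)
from thermopath.thermodynamics import R_KJ_PER_MOL_K, DEFAULT_TEMPERATURE_K

RT = R_KJ_PER_MOL_K * DEFAULT_TEMPERATURE_K  # kJ/mol at 298.15 K


def chain_network(g0_rt=(-1.0, -1.0), ids=("R1", "R2")) -> MetabolicNetwork:
    """Linear chain S -> B -> P of irreversible reactions with given g0 (RT)."""
    mets = [Metabolite(id="S"), Metabolite(id="B"), Metabolite(id="P")]
    hops = [("S", "B"), ("B", "P")]
    reactions = [
        Reaction(
            id=rid,
            stoichiometry={a: Fraction(-1), b: Fraction(1)},
            reversible=False,
            delta_g_standard=g * RT,
        )
        for rid, (a, b), g in zip(ids, hops, g0_rt)
    ]
    return MetabolicNetwork(mets, reactions)


def prepared(network, source="S", sink="P", n=0, beta=10.0):
    """Inject objective, split, and build thermo params."""
    spec = ObjectiveSpec(source_metabolite=source, sink_metabolite=sink, atp_yield=n)
    directed = split_reactions(add_objective_reaction(network, spec), beta=beta)
    return directed, build_thermo_params(directed)


@pytest.fixture(scope="session")
def fixture_network():
    return build_central_carbon_fixture()


@pytest.fixture(scope="session")
def scan_config():
    return EnumerationConfig(atp_yields=(-1, 0, 1))


@pytest.fixture(scope="session")
def fixture_scan(fixture_network, scan_config):
    """Full enumeration of the fixture at ATP yields -1, 0, +1."""
    return scan_atp_yields(fixture_network, scan_config)


@pytest.fixture(scope="session")
def fixture_directed(fixture_network, scan_config):
    """Directed networks (and thermo params) matching each scanned yield."""
    out = {}
    for n in scan_config.atp_yields:
        spec = ObjectiveSpec(atp_yield=n)
        directed = split_reactions(
            add_objective_reaction(fixture_network, spec), beta=scan_config.beta
        )
        out[n] = (directed, build_thermo_params(directed))
    return out
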