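"""Verification, ATP accounting, strategy classification and segments."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from thermopath import (
    DEFAULT_MARKERS,
    classify_strategy,
    count_segment_variants,
    count_strategies,
    export_solutions,
    net_atp_yield,
    route_segment,
    verify_solution,
)
from thermopath.analysis import DEFAULT_COFACTORS, NoPathError
from thermopath.enumeration import PathwaySolution


def solutions_with_label(fixture_scan, fixture_directed, label):
    for n, ss in fixture_scan.items():
        directed, _ = fixture_directed[n]
        for sol in ss.solutions:
            if label in classify_strategy(sol, directed):
                yield n, directed, sol


def first_with_label(fixture_scan, fixture_directed, label, require=None):
    for n, directed, sol in solutions_with_label(
        fixture_scan, fixture_directed, label
    ):
        if require is None or require(sol):
            return n, directed, sol
    raise AssertionError(f"no solution labelled {label}")


class TestVerification:
    def test_all_enumerated_solutions_pass(self, fixture_scan, fixture_directed):
        for n, ss in fixture_scan.items():
            directed, thermo = fixture_directed[n]
            for sol in ss.solutions:
                report = verify_solution(directed, thermo, sol, tolerance=1e-5)
                assert report.passed, report

    def test_perturbed_flux_breaks_mass_balance(self, fixture_scan, fixture_directed):
        directed, thermo = fixture_directed[0]
        sol = fixture_scan[0].solutions[0]
        did = next(iter(sol.fluxes))
        broken = PathwaySolution(
            active_set=sol.active_set,
            fluxes={**sol.fluxes, did: sol.fluxes[did] + 0.1},
            ln_concentrations=sol.ln_concentrations,
            atp_yield=sol.atp_yield,
            objective_value=sol.objective_value,
        )
        report = verify_solution(directed, thermo, broken, tolerance=1e-5)
        max_coeff = max(
            abs(float(c)) for c in directed.directed(did).stoichiometry.values()
        )
        assert report.mass_balance_max_residual == pytest.approx(
            0.1 * max_coeff, rel=1e-3
        )
        assert not report.passed

    def test_endergonic_active_reaction_is_flagged(self, fixture_directed):
        directed, thermo = fixture_directed[0]
        # activate the strongly endergonic dehydrogenase at mid-box
        # concentrations, where its driving force is clearly negative
        x = {m: -9.0 for m in thermo.ln_c_min}
        sol = PathwaySolution(
            active_set=frozenset({"SERA"}),
            fluxes={"SERA": 1.0},
            ln_concentrations=x,
            atp_yield=0,
            objective_value=1,
        )
        report = verify_solution(directed, thermo, sol, tolerance=1e-5)
        assert any(did == "SERA" for did, _ in report.thermo_violations)
        assert not report.passed

    def test_unresolvable_ids_rejected(self, fixture_directed):
        directed, thermo = fixture_directed[0]
        sol = PathwaySolution(
            active_set=frozenset({"GHOST"}),
            fluxes={"GHOST": 1.0},
            ln_concentrations={},
            atp_yield=0,
            objective_value=1,
        )
        with pytest.raises(KeyError):
            verify_solution(directed, thermo, sol)


class TestAtpAccounting:
    def test_serine_shunt_is_atp_neutral(self, fixture_scan, fixture_directed):
        _, directed, sol = first_with_label(
            fixture_scan, fixture_directed, "serine_shunt"
        )
        assert net_atp_yield(directed, sol) == Fraction(0)

    def test_methylglyoxal_route_wastes_one_atp(self, fixture_scan, fixture_directed):
        n, directed, sol = first_with_label(
            fixture_scan, fixture_directed, "methylglyoxal"
        )
        assert n == -1
        assert net_atp_yield(directed, sol) == Fraction(-1)

    def test_emp_yields_one_atp_on_glycerol(self, fixture_scan, fixture_directed):
        directed, _ = fixture_directed[1]
        sol = fixture_scan[1].solutions[0]
        assert "EMP" in classify_strategy(sol, directed)
        assert net_atp_yield(directed, sol) == Fraction(1)

    def test_accounting_reproduces_injected_yield_everywhere(
        self, fixture_scan, fixture_directed
    ):
        """Cross-check: the stoichiometric ATP flux sum equals the injected
        yield n exactly, for every enumerated solution."""
        for n, ss in fixture_scan.items():
            directed, _ = fixture_directed[n]
            for sol in ss.solutions:
                assert net_atp_yield(directed, sol) == Fraction(n)

    def test_missing_atp_id_rejected(self, fixture_scan, fixture_directed):
        directed, _ = fixture_directed[0]
        with pytest.raises(KeyError):
            net_atp_yield(directed, fixture_scan[0].solutions[0], atp_id="XTP")


class TestClassification:
    def test_committing_enzymes_drive_labels(self, fixture_scan, fixture_directed):
        directed, _ = fixture_directed[-1]
        sol = fixture_scan[-1].solutions[0]
        assert "MGSA" in sol.parent_active_set(directed)
        assert "methylglyoxal" in classify_strategy(sol, directed)

    def test_serine_label_requires_all_four_enzymes(
        self, fixture_scan, fixture_directed
    ):
        _, directed, sol = first_with_label(
            fixture_scan, fixture_directed, "serine_shunt"
        )
        parents = sol.parent_active_set(directed)
        assert {"SERA", "SERC", "SERB", "SDAA"} <= parents

    def test_empty_active_set_is_unclassified(self, fixture_directed):
        directed, _ = fixture_directed[0]
        sol = PathwaySolution(
            active_set=frozenset(), fluxes={}, ln_concentrations={},
            atp_yield=0, objective_value=0,
        )
        assert classify_strategy(sol, directed) == frozenset()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_labels_invariant_to_flux_rescaling(
        self, fixture_scan, fixture_directed, scale
    ):
        directed, _ = fixture_directed[0]
        sol = fixture_scan[0].solutions[0]
        rescaled = PathwaySolution(
            active_set=sol.active_set,
            fluxes={k: v * scale for k, v in sol.fluxes.items()},
            ln_concentrations=sol.ln_concentrations,
            atp_yield=sol.atp_yield,
            objective_value=sol.objective_value,
        )
        assert classify_strategy(rescaled, directed) == classify_strategy(
            sol, directed
        )

    def test_four_strategies_across_full_scan(self, fixture_scan, fixture_directed):
        directed = {n: d for n, (d, _) in fixture_directed.items()}
        count, labels = count_strategies(fixture_scan, directed)
        assert count == 4
        assert labels == {"EMP", "ED", "methylglyoxal", "serine_shunt"}

    def test_atp_filter_drops_cryptic_routes(self, fixture_scan, fixture_directed):
        """Restricting to yields >= 1 loses the methylglyoxal and serine
        labels (they are ATP-wasting / ATP-neutral)."""
        directed = {n: d for n, (d, _) in fixture_directed.items()}
        restricted = {n: ss for n, ss in fixture_scan.items() if n >= 1}
        _, labels = count_strategies(restricted, directed)
        assert "methylglyoxal" not in labels
        assert "serine_shunt" not in labels
        assert "EMP" in labels


class TestSegments:
    def test_serine_segment_is_the_four_enzyme_chain(
        self, fixture_scan, fixture_directed
    ):
        _, directed, sol = first_with_label(
            fixture_scan, fixture_directed, "serine_shunt"
        )
        seg = route_segment(directed, sol, "3PG", "pyruvate")
        assert seg == ["SERA", "SERC", "SERB", "SDAA"]

    def test_glutathione_route_segment(self, fixture_scan, fixture_directed):
        n, directed, sol = first_with_label(
            fixture_scan, fixture_directed, "methylglyoxal",
            require=lambda s: "MGGSH" in s.active_set and "GLDA" not in s.active_set,
        )
        seg = route_segment(directed, sol, "methylglyoxal", "pyruvate")
        assert seg == ["MGGSH", "GLOB", "DLD"]

    def test_direct_isomerase_route_segment(self, fixture_scan, fixture_directed):
        n, directed, sol = first_with_label(
            fixture_scan, fixture_directed, "methylglyoxal",
            require=lambda s: "HCHA" in s.active_set,
        )
        seg = route_segment(directed, sol, "methylglyoxal", "pyruvate")
        assert seg == ["HCHA", "DLD"]

    def test_segment_reactions_are_active_and_chained(
        self, fixture_scan, fixture_directed
    ):
        """Soundness: returned segments only use active reactions, and
        consecutive reactions share a non-cofactor metabolite."""
        for n, ss in fixture_scan.items():
            directed, _ = fixture_directed[n]
            for sol in ss.solutions:
                try:
                    seg = route_segment(directed, sol, "methylglyoxal", "pyruvate")
                except NoPathError:
                    continue
                parents = sol.parent_active_set(directed)
                assert set(seg) <= parents
                for a, b in zip(seg, seg[1:]):
                    sa = set(directed.directed(a).stoichiometry)
                    sb = set(directed.directed(b).stoichiometry)
                    assert (sa & sb) - DEFAULT_COFACTORS

    def test_no_path_raises_typed_error(self, fixture_scan, fixture_directed):
        directed, _ = fixture_directed[1]
        sol = fixture_scan[1].solutions[0]  # EMP: no methylglyoxal at all
        with pytest.raises(NoPathError):
            route_segment(directed, sol, "methylglyoxal", "pyruvate")

    def test_three_methylglyoxal_variants(self, fixture_scan, fixture_directed):
        directed = {n: d for n, (d, _) in fixture_directed.items()}
        assert count_segment_variants(
            fixture_scan, directed, "methylglyoxal", "pyruvate"
        ) == 3

    def test_single_serine_to_pyruvate_variant(self, fixture_scan, fixture_directed):
        directed = {n: d for n, (d, _) in fixture_directed.items()}
        assert count_segment_variants(
            fixture_scan, directed, "serine", "pyruvate"
        ) == 1

    def test_empty_solution_sets_count_zero(self, fixture_directed):
        directed = {n: d for n, (d, _) in fixture_directed.items()}
        assert count_segment_variants({}, directed, "methylglyoxal", "pyruvate") == 0


class TestExport:
    def test_export_writes_json_tsv_and_annotations(
        self, fixture_scan, fixture_directed, tmp_path
    ):
        directed = {n: d for n, (d, _) in fixture_directed.items()}
        written = export_solutions(fixture_scan, directed, tmp_path)
        names = {p.name for p in written}
        assert "solutions.tsv" in names
        assert "annotations.tsv" in names
        assert any(n.startswith("solutions_atp") for n in names)
        annot = (tmp_path / "annotations.tsv").read_text().splitlines()
        header = annot[0].split("\t")
        assert header == [
            "solution_id", "atp_yield", "cardinality", "strategies",
            "net_atp", "mg_segment_len", "serine_segment_len",
        ]
        n_solutions = sum(len(s.solutions) for s in fixture_scan.values())
        assert len(annot) == 1 + n_solutions
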