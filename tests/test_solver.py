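"""Topology enumeration, constraint filtering, and evidence combination."""

import itertools
import random

import pytest

from lanthirings import presets
from lanthirings.fragments import CleavageEvidence
from lanthirings.peptide import Topology
from lanthirings.solver import (
    RingTopologyModel,
    VariantObservation,
    apply_protection_assertions,
    combine_evidence,
    enumerate_topologies,
    filter_consistent,
    solve_variant,
)

CYS = [32, 34, 45, 50]
DEHYDRO = {31: "Dhb", 39: "Dhb", 43: "Dhb", 49: "Dha"}
SPAN = (18, 51)


def brute_force_solve(cys, dehydro, evidence_bonds, spans, complete):
    """Independent oracle: enumerate all injective pairings directly and
    re-test every constraint with interval arithmetic."""
    cys, dehydro = sorted(cys), sorted(dehydro)
    results = set()
    subsets = (
        [tuple(cys)]
        if complete
        else [s for r in range(len(cys) + 1) for s in itertools.combinations(cys, r)]
    )
    for subset in subsets:
        if len(subset) > len(dehydro):
            continue
        for partners in itertools.permutations(dehydro, len(subset)):
            rings = frozenset(zip(subset, partners))

            def spanned(bond):
                return any(min(r) <= bond < max(r) for r in rings)

            if any(spanned(b) for b in evidence_bonds):
                continue
            if any(
                not spanned(b) for a, e in spans for b in range(a, e)
            ):
                continue
            results.add(rings)
    return {frozenset(r) for r in results}


class TestEnumerateTopologies:
    def test_unconstrained_complete_count(self):
        """Four Cys and four dehydro sites admit 4! = 24 matchings."""
        tops = enumerate_topologies(CYS, DEHYDRO, complete=True)
        assert len(tops) == 24

    def test_required_rings_leave_two(self):
        """Fixing (34,39) and (45,49) leaves the two pairings of
        Cys{32,50} with dehydro{31,43}."""
        tops = enumerate_topologies(
            CYS, DEHYDRO, required_rings={(34, 39), (45, 49)}, complete=True
        )
        assert len(tops) == 2
        ring_sets = {t.rings for t in tops}
        assert frozenset({(32, 43), (34, 39), (45, 49), (50, 31)}) in ring_sets
        assert frozenset({(32, 31), (34, 39), (45, 49), (50, 43)}) in ring_sets

    def test_no_cys_yields_single_empty_topology(self):
        tops = enumerate_topologies([], DEHYDRO, complete=True)
        assert tops == [Topology()]

    def test_partial_includes_unpaired_cys(self):
        tops = enumerate_topologies([1, 5], [3, 8], complete=False)
        # subsets of {1,5}: {} (1), {1} (2), {5} (2), {1,5} (2) -> 7
        assert len(tops) == 7
        assert Topology() in tops

    def test_required_ring_with_missing_position_errors(self):
        with pytest.raises(ValueError):
            enumerate_topologies(CYS, DEHYDRO, required_rings={(32, 99)})

    def test_forbidden_pairs_excluded(self):
        tops = enumerate_topologies(
            CYS, DEHYDRO, forbidden_pairs={(32, 43)}, complete=True
        )
        assert len(tops) == 18  # 24 minus the 3! matchings containing (32,43)
        assert all((32, 43) not in t.rings for t in tops)

    def test_capacity_guard(self):
        cys = list(range(1, 19, 2))  # 9 Cys
        dehydro = list(range(2, 20, 2))
        with pytest.raises(ValueError, match="max_cys"):
            enumerate_topologies(cys, dehydro, complete=True)
        assert enumerate_topologies(
            cys[:2], dehydro[:2], complete=True, max_cys=2
        )

    def test_deterministic_order(self):
        a = enumerate_topologies(CYS, DEHYDRO, complete=True)
        b = enumerate_topologies(reversed(CYS), DEHYDRO, complete=True)
        assert a == b
        assert a == sorted(a, key=lambda t: t.sorted_rings())


class TestFilterConsistent:
    def test_ring_spanning_evidenced_bond_rejected(self):
        cand = [Topology({(32, 49)}), Topology({(45, 49)})]
        ev = CleavageEvidence("v", frozenset({43}))
        kept = filter_consistent(cand, ev, SPAN)
        assert kept == [Topology({(45, 49)})]  # 43 lies inside [32,49)

    def test_empty_evidence_keeps_all(self):
        cand = enumerate_topologies(CYS, DEHYDRO, complete=True)
        ev = CleavageEvidence("v", frozenset())
        assert filter_consistent(cand, ev, SPAN) == cand

    def test_wild_type_evidence_retains_deduced_topology(self):
        ev = CleavageEvidence("WT", frozenset(range(18, 31)) | {50})
        kept = filter_consistent([presets.VENEZUELIN_TOPOLOGY], ev, SPAN)
        assert kept == [presets.VENEZUELIN_TOPOLOGY]


class TestProtectionAssertions:
    def test_span_forces_covering_ring(self):
        cand = enumerate_topologies([34, 45, 50], DEHYDRO, complete=False)
        kept = apply_protection_assertions(cand, [(34, 39)])
        assert kept
        for t in kept:
            assert all(t.spans_bond(b) for b in range(34, 39))

    def test_empty_span_list_is_identity(self):
        cand = enumerate_topologies(CYS, DEHYDRO, complete=True)
        assert apply_protection_assertions(cand, []) == cand

    def test_over_assertion_can_empty_the_set(self):
        cand = enumerate_topologies([2], [3], complete=True)
        assert apply_protection_assertions(cand, [(1, 10)]) == []


class TestCombineEvidence:
    def test_venezuelin_deduction_is_unique(self, venezuelin_observations):
        """The full wild-type + knockout series pins the four-ring
        topology: MeLan 32-43, MeLan 34-39, Lan 45-49, MeLan 50-31."""
        res = combine_evidence(
            venezuelin_observations, "WT", SPAN, mode="protection_assertion"
        )
        assert res.unique
        assert res.topology == presets.VENEZUELIN_TOPOLOGY
        assert res.evidenced_rings == frozenset({(34, 39), (45, 49)})

    def test_single_wt_with_empty_evidence_keeps_all_matchings(self):
        obs = VariantObservation(
            "WT", frozenset(CYS), DEHYDRO,
            CleavageEvidence("WT", frozenset()), completeness="complete",
        )
        res = combine_evidence([obs], "WT", SPAN, mode="strict")
        assert len(res.topologies) == 24

    def test_contradictory_evidence_returns_conflict_report(self):
        # assert protection over a span no available ring can cover
        obs = VariantObservation(
            "WT", frozenset({50}), {49: "Dha"},
            CleavageEvidence("WT", frozenset({49})),
            asserted_protected_spans=((49, 51),),
            completeness="complete",
        )
        res = combine_evidence([obs], "WT", SPAN, mode="protection_assertion")
        assert res.topologies == []
        assert res.conflict_report

    def test_monotone_in_evidence(self, venezuelin_observations):
        """Adding evidence bonds never enlarges the result set."""
        weaker = [
            VariantObservation(
                o.variant_id, o.cys_positions, o.dehydro_positions,
                CleavageEvidence(o.variant_id, frozenset()),
                o.asserted_protected_spans, o.completeness,
            )
            for o in venezuelin_observations
        ]
        res_weak = combine_evidence(weaker, "WT", SPAN, "protection_assertion")
        res_full = combine_evidence(
            venezuelin_observations, "WT", SPAN, "protection_assertion"
        )
        assert {t.rings for t in res_full.topologies} <= {
            t.rings for t in res_weak.topologies
        }


class TestOracleEquivalence:
    def test_solver_matches_brute_force_on_random_instances(self):
        """Per-variant solving equals direct enumeration + constraint
        re-testing for random position sets with up to 5 Cys."""
        r = random.Random(42)
        for trial in range(40):
            n_cys = r.randint(0, 5)
            n_dehydro = r.randint(n_cys, 6)
            positions = r.sample(range(2, 40), n_cys + n_dehydro)
            cys = frozenset(positions[:n_cys])
            dehydro = {p: "Dhb" for p in positions[n_cys:]}
            span = (1, 45)
            bonds = frozenset(r.sample(range(1, 45), r.randint(0, 6)))
            spans = []
            if r.random() < 0.5 and n_cys:
                a = r.randint(1, 40)
                spans.append((a, a + r.randint(2, 5)))
            complete = r.random() < 0.5
            obs = VariantObservation(
                "v", cys, dehydro, CleavageEvidence("v", bonds),
                tuple(spans), "complete" if complete else "partial",
            )
            got = solve_variant(obs, span, mode="protection_assertion")
            expected = brute_force_solve(cys, dehydro, bonds, spans, complete)
            assert {t.rings for t in got.consistent_topologies} == expected, (
                f"trial {trial}"
            )


class TestModelResultsSurface:
    def test_model_fit_summary_and_ring_table(self, venezuelin_observations):
        model = RingTopologyModel(venezuelin_observations, span=SPAN)
        res = model.fit()
        text = res.summary()
        assert "surviving topologies: 1" in text
        table = res.ring_table()
        assert list(table["cys"]) == [32, 34, 45, 50]
        assert list(table["ring"]) == ["MeLan", "MeLan", "Lan", "MeLan"]

    def test_results_to_dict_roundtrips_topologies(self, venezuelin_observations):
        res = RingTopologyModel(venezuelin_observations, span=SPAN).fit()
        d = res.to_dict()
        assert d["topologies"] == [[[32, 43], [34, 39], [45, 49], [50, 31]]]

    def test_unknown_wild_type_id_rejected(self, venezuelin_observations):
        with pytest.raises(KeyError):
            RingTopologyModel(venezuelin_observations, span=SPAN, wild_type_id="nope")
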