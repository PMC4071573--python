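"""Assembly classification, reaction semantics, and route-search minimality."""

import pytest

from diatomlipid.chem import AcylChain
from diatomlipid.pathway import (
    OPERATORS,
    LipidPool,
    RouteNotFoundError,
    StateSpaceExceeded,
    apply_reaction,
    classify_assembly,
    epa_synthesis_reachability,
    find_routes,
)
from diatomlipid.species import LipidSpecies

P = LipidSpecies.parse
EPA = AcylChain(20, 5)


def pool(*specs, coa=()):
    return LipidPool(
        tuple(P(c, ch) for c, ch in specs),
        frozenset(AcylChain.parse(c) for c in coa),
    )


class TestClassify:
    @pytest.mark.parametrize(
        "cls,chains,label",
        [
            ("PC", "20:5/16:1", "prokaryotic"),
            ("PC", "14:0/16:1", "prokaryotic"),  # C14 sn-2 counts as <=C16
            ("MGDG", "20:5/18:4", "eukaryotic"),
            ("PC", "20:5/20:5", "eukaryotic"),
            ("TAG", "16:0/18:1/20:5", "eukaryotic"),
            ("PC", "16:1/22:6", "eukaryotic"),
        ],
    )
    def test_sn2_rule(self, cls, chains, label):
        call = classify_assembly(P(cls, chains))
        assert call.label == label
        assert call.evidence == P(cls, chains).chains[1]

    def test_unresolved_is_ambiguous(self):
        call = classify_assembly(P("PC", "20:5_16:1"))
        assert call.label == "ambiguous"
        assert call.evidence is None

    def test_lyso_and_free_acid_not_classifiable(self):
        with pytest.raises(ValueError):
            classify_assembly(LipidSpecies("LPC", (EPA,), sn_resolved=True))
        with pytest.raises(ValueError):
            classify_assembly(LipidSpecies("FFA", (EPA,), sn_resolved=True))

    def test_partition_over_packaged_rosters(self, fixtures):
        """Chloroplast-type species all classify prokaryotic; eukaryotic calls occur only in PC."""
        labels = {}
        for fx in fixtures.values():
            for e in fx.roster:
                labels[e.species] = classify_assembly(e.species).label
        assert set(labels.values()) <= {"prokaryotic", "eukaryotic"}
        for sp, label in labels.items():
            if sp.class_id != "PC":
                assert label == "prokaryotic", sp.name
        assert any(
            label == "eukaryotic" for sp, label in labels.items() if sp.class_id == "PC"
        )


class TestReactions:
    def test_pdat_builds_epa_tag_from_di_epa_pc(self):
        start = pool(("PC", "20:5/20:5"), ("DAG", "16:0/16:1"))
        nxt = apply_reaction("PDAT", start, ["PC 20:5/20:5", "DAG 16:0/16:1"])
        names = [sp.name for sp in nxt.species]
        assert "TAG 16:0/16:1/20:5" in names
        assert "LPC 20:5" in names
        assert start.count(P("PC", "20:5/20:5")) == 1  # input pool untouched

    def test_pdct_swaps_head_groups(self):
        start = pool(("PC", "20:5/16:1"), ("DAG", "16:0/16:1"))
        nxt = apply_reaction("PDCT", start, ["PC 20:5/16:1", "DAG 16:0/16:1"])
        names = [sp.name for sp in nxt.species]
        assert "DAG 20:5/16:1" in names and "PC 16:0/16:1" in names

    def test_pla_without_pc_is_an_error(self):
        start = pool(("DAG", "16:0/16:1"))
        with pytest.raises(ValueError):
            apply_reaction("PLA", start, ["PC 20:5/16:1"])

    def test_des_pc_caps(self):
        start = pool(("PC", "20:5/18:4"))
        steps = list(OPERATORS["DES_PC"](start, {}))
        assert steps == []  # both chains at their cap

    def test_elo_acts_on_coa_only(self):
        start = pool(("PC", "16:0/18:3"), coa=["18:3"])
        steps = list(OPERATORS["ELO"](start, {}))
        assert [s.products for s, _ in steps] == [("CoA 20:3",)]

    @pytest.mark.parametrize("op", ["PLA", "PDCT", "PDAT"])
    def test_chain_conservation_outside_reservoir(self, op):
        """Ops not touching CoA conserve the pool's chain multiset exactly."""
        start = pool(("PC", "20:5/18:2"), ("PC", "16:0/16:0"), ("DAG", "16:0/16:1"))
        for _, nxt in OPERATORS[op](start, {}):
            assert nxt.chain_multiset() == start.chain_multiset()

    def test_reservoir_flux_declared(self):
        """ACS/LPCAT move chains between multiset and reservoir, never create them."""
        start = pool(("PC", "20:5/18:2"), ("FFA", "16:1"), coa=["16:0"])
        for op in ("ACS", "LPCAT_rev"):
            for step, nxt in OPERATORS[op](start, {}):
                lost = start.chain_multiset() - nxt.chain_multiset()
                assert sum(lost.values()) == 1
                (chain,) = lost
                assert chain in nxt.coa
        for step, nxt in OPERATORS["LPCAT_fwd"](
            pool(("PC", "20:5/18:2"),).with_changes(
                add=[LipidSpecies("LPC", (EPA,), sn_resolved=True)]
            ).with_changes(add_coa=[AcylChain(16, 1)]),
            {},
        ):
            gained = nxt.chain_multiset() - LipidPool(
                (P("PC", "20:5/18:2"), LipidSpecies("LPC", (EPA,), sn_resolved=True))
            ).chain_multiset()
            assert list(gained) == [AcylChain(16, 1)]  # drawn from the reservoir


def _exhaustive_shortest(start, target, max_depth, ops):
    """Independent oracle: plain recursive enumeration of operator applications."""
    def contains(p):
        return any(sp == target for sp in p.species)

    level = [(start, ())]
    if contains(start):
        return {()}
    for depth in range(1, max_depth + 1):
        nxt = []
        hits = set()
        for p, path in level:
            for op in ops:
                for step, q in OPERATORS[op](p, {}):
                    new = path + (step,)
                    if contains(q):
                        hits.add(new)
                    else:
                        nxt.append((q, new))
        if hits:
            return hits
        level = nxt
    return set()


class TestRouteSearch:
    def test_pdat_route_is_one_step(self):
        start = pool(("PC", "20:5/20:5"), ("DAG", "16:0/16:1"))
        routes = find_routes(start, P("TAG", "16:0/16:1/20:5"), max_depth=4)
        assert [len(r) for r in routes] == [1]
        assert routes[0].steps[0].op == "PDAT"

    def test_acyl_editing_route_to_dag_epa_c16(self):
        """The PLA -> LPCAT -> PDCT editing route is rediscovered as minimal."""
        start = pool(("PC", "20:5/18:2"), ("DAG", "16:0/16:1"), coa=["16:1"])
        routes = find_routes(start, P("DAG", "20:5/16:1"), max_depth=4)
        assert routes and all(len(r) == 3 for r in routes)
        sequences = {tuple(s.op for s in r.steps) for r in routes}
        assert ("PLA", "LPCAT_fwd", "PDCT") in sequences

    @pytest.mark.parametrize(
        "specs,coa,target",
        [
            ([("PC", "20:5/20:5"), ("DAG", "16:0/16:1")], [], ("TAG", "16:0/16:1/20:5")),
            ([("PC", "20:5/18:2"), ("DAG", "16:0/16:1")], ["16:1"], ("DAG", "20:5/16:1")),
            ([("PC", "16:0/16:1"), ("DAG", "16:0/16:0")], [], ("TAG", "16:0/16:0/16:1")),
        ],
    )
    def test_bfs_matches_exhaustive_enumeration(self, specs, coa, target):
        ops = ("PLA", "ACS", "LPCAT_fwd", "LPCAT_rev", "PDCT", "PDAT", "DGAT")
        start = pool(*specs, coa=coa)
        routes = find_routes(start, P(*target), max_depth=4, ops=ops)
        oracle = _exhaustive_shortest(start, P(*target), 4, ops)
        assert {r.steps for r in routes} == oracle

    def test_unreachable_returns_empty(self):
        start = pool(("DAG", "16:0/16:1"))
        assert find_routes(start, P("TAG", "20:5/20:5/20:5"), max_depth=2) == []

    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            find_routes(pool(("DAG", "16:0/16:1")), P("TAG", "16:0/16:1/16:0"), 0)

    def test_state_cap_raises(self):
        start = pool(("PC", "16:0/18:1"), ("PC", "20:5/18:2"), ("DAG", "16:0/16:1"),
                     coa=["16:0", "16:1", "18:1"])
        with pytest.raises(StateSpaceExceeded):
            find_routes(start, P("TAG", "20:5/20:5/20:5"), max_depth=6, state_cap=50)


class TestEpaSynthesis:
    def test_route_from_oleoyl_pc(self):
        start = pool(("PC", "16:0/18:1"))
        route = epa_synthesis_reachability(start)
        assert len(route) >= 1
        assert route.end.contains(lambda sp: sp.class_id == "PC" and EPA in sp.chains)
        # order constraint: elongation on CoA substrates, desaturation on PC
        for step in route.steps:
            if step.op == "ELO":
                assert all(s.startswith("CoA ") for s in step.substrates)
            if step.op == "DES_PC":
                assert all(s.startswith("PC ") for s in step.substrates)
        ops = [s.op for s in route.steps]
        assert "ELO" in ops and "DES_PC" in ops

    def test_route_alternates_pc_and_coa_processing(self):
        """C18 desaturation precedes the single CoA elongation to C20."""
        route = epa_synthesis_reachability(pool(("PC", "16:0/18:1")))
        ops = [s.op for s in route.steps]
        elo = ops.index("ELO")
        assert "DES_PC" in ops[:elo] and "DES_PC" in ops[elo + 1 :]

    def test_no_desaturation_source_unreachable(self):
        start = pool(("PC", "16:0/18:1"))
        with pytest.raises(RouteNotFoundError):
            epa_synthesis_reachability(
                start, ops=("PLA", "ACS", "ELO", "LPCAT_fwd", "LPCAT_rev")
            )

    def test_already_epa_bearing_pc_gives_empty_route(self):
        route = epa_synthesis_reachability(pool(("PC", "20:5/16:1")))
        assert len(route) == 0
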