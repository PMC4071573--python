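"""Assembly-pathway classification and acyl-editing reaction-network search.

Two distinct glycerolipid assembly routes leave a positional signature:
species built in the chloroplast (prokaryotic pathway) carry a C16 (or
shorter) acyl at sn-2, while species built in the ER (eukaryotic pathway)
carry a C18/C20/C22 acyl at sn-2.  ``classify_assembly`` reads that signature
off a positionally resolved species.

The reaction network models the PC-centred acyl-editing machinery:

    PLA         PC(a/b)            -> LPC(a) + FFA(b)
    ACS         FFA(x)             -> acyl-CoA(x)
    LPCAT_fwd   LPC(a) + CoA(x)    -> PC(a/x)
    LPCAT_rev   PC(a/b)            -> LPC(a) + CoA(b)
    PDCT        PC(a/b) + DAG(c/d) -> DAG(a/b) + PC(c/d)   (head-group swap)
    PDAT        PC(a/b) + DAG(c/d) -> TAG(c/d/b) + LPC(a)
    DGAT        DAG(c/d) + CoA(x)  -> TAG(c/d/x)
    ELO         CoA(c:d)           -> CoA(c+2:d)           (on CoA only)
    DES_PC      PC ... (c:d)       -> (c:d+1)              (on PC only)

Acyl chains are conserved across every step except the two modifying
operators (ELO adds two carbons on a CoA-bound chain, DES_PC one double bond
on a PC-bound chain, capped at 18:4 / 20:5).  The acyl-CoA pool is a
non-depleting reservoir; PC/LPC/DAG/TAG/FFA are stoichiometric.  Desaturation
is modeled without regiochemistry, so the omega-3/omega-6 branches collapse
onto one (c:d) ladder.

``find_routes`` is a breadth-first search over canonicalized pool states with
deterministic operator and binding order; it returns every route of minimal
length, so the proposed one-step PDAT route to EPA-containing TAG and the
three-step PLA -> LPCAT -> PDCT route to DAG EPA/C16 are rediscovered as
provably shortest.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .chem import AcylChain
from .species import LipidSpecies

__all__ = [
    "AssemblyCall",
    "LipidPool",
    "ReactionStep",
    "Route",
    "RouteNotFoundError",
    "StateSpaceExceeded",
    "OPERATORS",
    "classify_assembly",
    "apply_reaction",
    "find_routes",
    "epa_synthesis_reachability",
]

#: desaturation caps per carbon number (chains outside this table are not
#: substrates of the modeled PC-bound desaturases)
DES_CAPS = {18: 4, 20: 5}
#: elongation adds C2 units on CoA up to this chain length
ELO_MAX_CARBONS = 22

_CLASSIFIABLE = {"PC", "PE", "PG", "PI", "MGDG", "DGDG", "SQDG", "DAG", "TAG"}
EPA = AcylChain(20, 5)


class RouteNotFoundError(RuntimeError):
    """Target unreachable under the enabled operator set."""


class StateSpaceExceeded(RuntimeError):
    """BFS state cap hit before exhausting the requested depth."""


@dataclass(frozen=True)
class AssemblyCall:
    species: LipidSpecies
    label: str  # "prokaryotic" | "eukaryotic" | "ambiguous"
    evidence: AcylChain | None  # the sn-2 chain, when resolved


def classify_assembly(species: LipidSpecies) -> AssemblyCall:
    """Prokaryotic/eukaryotic call from the sn-2 acyl chain length.

    sn-2 carbons <= 16 (including the minor C14) -> prokaryotic (chloroplast
    assembly); 18/20/22 -> eukaryotic (ER assembly).  Species without a
    positional call are ambiguous; lyso and free-acid species have no
    backbone signature and are not classifiable.
    """
    if species.class_id not in _CLASSIFIABLE:
        raise ValueError(f"{species.class_id} species carry no assembly signature")
    if not species.sn_resolved:
        return AssemblyCall(species, "ambiguous", None)
    sn2 = species.chains[1]
    label = "prokaryotic" if sn2.carbons <= 16 else "eukaryotic"
    return AssemblyCall(species, label, sn2)


def _canon(species: Iterable[LipidSpecies]) -> tuple[LipidSpecies, ...]:
    return tuple(sorted(species, key=lambda s: (s.class_id, s.chain_string)))


@dataclass(frozen=True)
class LipidPool:
    """Stoichiometric species multiset plus a non-depleting acyl-CoA reservoir."""

    species: tuple[LipidSpecies, ...] = ()
    coa: frozenset[AcylChain] = frozenset()

    def __post_init__(self) -> None:
        for sp in self.species:
            if sp.class_id == "ACYL_COA":
                raise ValueError("acyl-CoA lives in the reservoir, not the multiset")
            if sp.class_id in _CLASSIFIABLE and not sp.sn_resolved:
                raise ValueError(f"pool species {sp.name} must be sn-resolved")
        object.__setattr__(self, "species", _canon(self.species))

    def with_changes(
        self,
        remove: Sequence[LipidSpecies] = (),
        add: Sequence[LipidSpecies] = (),
        add_coa: Sequence[AcylChain] = (),
    ) -> "LipidPool":
        stock = list(self.species)
        for sp in remove:
            stock.remove(sp)  # raises ValueError if absent
        stock.extend(add)
        return LipidPool(tuple(stock), self.coa | frozenset(add_coa))

    def count(self, species: LipidSpecies) -> int:
        return self.species.count(species)

    def contains(self, target) -> bool:
        if callable(target):
            return any(target(sp) for sp in self.species)
        return target in self.species

    def chain_multiset(self) -> Counter:
        """Multiset of chains over stoichiometric species (reservoir excluded)."""
        c: Counter = Counter()
        for sp in self.species:
            c.update(sp.chains)
        return c


@dataclass(frozen=True)
class ReactionStep:
    op: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "op": self.op,
            "substrates": list(self.substrates),
            "products": list(self.products),
        }


@dataclass(frozen=True)
class Route:
    steps: tuple[ReactionStep, ...]
    start: LipidPool
    end: LipidPool

    def __len__(self) -> int:
        return len(self.steps)

    def to_dict(self) -> dict:
        return {"length": len(self), "steps": [s.to_dict() for s in self.steps]}


def _pc(a: AcylChain, b: AcylChain) -> LipidSpecies:
    return LipidSpecies("PC", (a, b), sn_resolved=True)


def _name(cls: str, chains: Sequence[AcylChain]) -> str:
    return f"{cls} " + "/".join(str(c) for c in chains)


# ---------------------------------------------------------------------------
# operator registry: name -> bindings(pool) yielding (step, next_pool)
# ---------------------------------------------------------------------------

def _bind_pla(pool: LipidPool, opts: dict):
    for sp in dict.fromkeys(pool.species):
        if sp.class_id != "PC":
            continue
        a, b = sp.chains
        lpc = LipidSpecies("LPC", (a,), sn_resolved=True)
        ffa = LipidSpecies("FFA", (b,), sn_resolved=True)
        step = ReactionStep("PLA", (sp.name,), (lpc.name, ffa.name))
        yield step, pool.with_changes(remove=[sp], add=[lpc, ffa])


def _bind_acs(pool: LipidPool, opts: dict):
    for sp in dict.fromkeys(pool.species):
        if sp.class_id != "FFA":
            continue
        chain = sp.chains[0]
        step = ReactionStep("ACS", (sp.name,), (f"CoA {chain}",))
        yield step, pool.with_changes(remove=[sp], add_coa=[chain])


def _bind_lpcat_fwd(pool: LipidPool, opts: dict):
    for sp in dict.fromkeys(pool.species):
        if sp.class_id != "LPC":
            continue
        for chain in sorted(pool.coa):
            pc = _pc(sp.chains[0], chain)
            step = ReactionStep("LPCAT_fwd", (sp.name, f"CoA {chain}"), (pc.name,))
            yield step, pool.with_changes(remove=[sp], add=[pc])


def _bind_lpcat_rev(pool: LipidPool, opts: dict):
    for sp in dict.fromkeys(pool.species):
        if sp.class_id != "PC":
            continue
        a, b = sp.chains
        lpc = LipidSpecies("LPC", (a,), sn_resolved=True)
        step = ReactionStep("LPCAT_rev", (sp.name,), (lpc.name, f"CoA {b}"))
        yield step, pool.with_changes(remove=[sp], add=[lpc], add_coa=[b])


def _bind_pdct(pool: LipidPool, opts: dict):
    pcs = [s for s in dict.fromkeys(pool.species) if s.class_id == "PC"]
    dags = [s for s in dict.fromkeys(pool.species) if s.class_id == "DAG"]
    for pc in pcs:
        for dag in dags:
            new_dag = LipidSpecies("DAG", pc.chains, sn_resolved=True)
            new_pc = _pc(*dag.chains)
            step = ReactionStep(
                "PDCT", (pc.name, dag.name), (new_dag.name, new_pc.name)
            )
            yield step, pool.with_changes(remove=[pc, dag], add=[new_dag, new_pc])


def _bind_pdat(pool: LipidPool, opts: dict):
    sn1_variant = opts.get("pdat_sn1", False)
    pcs = [s for s in dict.fromkeys(pool.species) if s.class_id == "PC"]
    dags = [s for s in dict.fromkeys(pool.species) if s.class_id == "DAG"]
    for pc in pcs:
        for dag in dags:
            a, b = pc.chains
            c, d = dag.chains
            # default: acylate sn-3; variant: new acyl at sn-1, DAG shifts to sn-2/sn-3
            chains = (b, c, d) if sn1_variant else (c, d, b)
            tag = LipidSpecies("TAG", chains, sn_resolved=True)
            lpc = LipidSpecies("LPC", (a,), sn_resolved=True)
            step = ReactionStep("PDAT", (pc.name, dag.name), (tag.name, lpc.name))
            yield step, pool.with_changes(remove=[pc, dag], add=[tag, lpc])


def _bind_dgat(pool: LipidPool, opts: dict):
    sn1_variant = opts.get("dgat_sn1", False)
    for dag in [s for s in dict.fromkeys(pool.species) if s.class_id == "DAG"]:
        for chain in sorted(pool.coa):
            c, d = dag.chains
            chains = (chain, c, d) if sn1_variant else (c, d, chain)
            tag = LipidSpecies("TAG", chains, sn_resolved=True)
            step = ReactionStep("DGAT", (dag.name, f"CoA {chain}"), (tag.name,))
            yield step, pool.with_changes(remove=[dag], add=[tag])


def _bind_elo(pool: LipidPool, opts: dict):
    for chain in sorted(pool.coa):
        if chain.carbons + 2 > ELO_MAX_CARBONS:
            continue
        longer = AcylChain(chain.carbons + 2, chain.double_bonds)
        if longer in pool.coa:
            continue  # reservoir is a set; no-op additions pruned
        step = ReactionStep("ELO", (f"CoA {chain}",), (f"CoA {longer}",))
        yield step, pool.with_changes(add_coa=[longer])


def _bind_des_pc(pool: LipidPool, opts: dict):
    for sp in dict.fromkeys(pool.species):
        if sp.class_id != "PC":
            continue
        for pos, chain in enumerate(sp.chains):
            cap = DES_CAPS.get(chain.carbons)
            if cap is None or chain.double_bonds >= cap:
                continue
            new_chain = AcylChain(chain.carbons, chain.double_bonds + 1)
            chains = tuple(
                new_chain if i == pos else c for i, c in enumerate(sp.chains)
            )
            new_pc = LipidSpecies("PC", chains, sn_resolved=True)
            step = ReactionStep("DES_PC", (sp.name,), (new_pc.name,))
            yield step, pool.with_changes(remove=[sp], add=[new_pc])


OPERATORS: dict[str, Callable] = {
    "PLA": _bind_pla,
    "ACS": _bind_acs,
    "LPCAT_fwd": _bind_lpcat_fwd,
    "LPCAT_rev": _bind_lpcat_rev,
    "PDCT": _bind_pdct,
    "PDAT": _bind_pdat,
    "DGAT": _bind_dgat,
    "ELO": _bind_elo,
    "DES_PC": _bind_des_pc,
}


def apply_reaction(
    op: str, pool: LipidPool, binding: Sequence[str], **opts
) -> LipidPool:
    """Apply one named reaction to ``pool`` with the given substrate names.

    ``binding`` lists the substrate labels exactly as an enumerated step
    would (e.g. ``["PC 20:5/16:1", "DAG 16:0/16:1"]``).  Returns a new pool;
    the input is never modified.  Raises if the operator has no such binding
    in this pool (missing substrate or type mismatch).
    """
    if op not in OPERATORS:
        raise ValueError(f"unknown reaction operator {op!r}")
    want = tuple(binding)
    for step, nxt in OPERATORS[op](pool, opts):
        if step.substrates == want:
            return nxt
    raise ValueError(f"{op} has no binding {want} in this pool")


def _successors(pool: LipidPool, ops: Sequence[str], opts: dict):
    for op in ops:
        yield from OPERATORS[op](pool, opts)


def _as_predicate(target) -> Callable[[LipidSpecies], bool]:
    if callable(target):
        return target
    return lambda sp: sp == target


def find_routes(
    start: LipidPool,
    target,
    max_depth: int,
    ops: Sequence[str] | None = None,
    state_cap: int = 200_000,
    **opts,
) -> list[Route]:
    """All minimal-length routes from ``start`` to a pool containing ``target``.

    ``target`` is a resolved species or a predicate over species.  BFS over
    canonical pool states with deterministic operator/binding order; every
    distinct step sequence of the minimal length is returned (an already
    satisfied start yields one empty route).  Raises ``StateSpaceExceeded``
    when more than ``state_cap`` states are generated.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if ops is None:
        ops = tuple(OPERATORS)
    pred = _as_predicate(target)
    if start.contains(pred):
        return [Route((), start, start)]

    first_seen: dict[LipidPool, int] = {start: 0}
    frontier: list[tuple[LipidPool, tuple[ReactionStep, ...]]] = [(start, ())]
    for depth in range(1, max_depth + 1):
        nxt_frontier: list[tuple[LipidPool, tuple[ReactionStep, ...]]] = []
        hits: list[Route] = []
        for pool, path in frontier:
            for step, nxt in _successors(pool, ops, opts):
                seen_at = first_seen.get(nxt)
                if seen_at is not None and seen_at < depth:
                    continue
                if seen_at is None:
                    first_seen[nxt] = depth
                    if len(first_seen) > state_cap:
                        raise StateSpaceExceeded(
                            f"more than {state_cap} pool states at depth {depth}"
                        )
                new_path = path + (step,)
                if nxt.contains(pred):
                    hits.append(Route(new_path, start, nxt))
                else:
                    nxt_frontier.append((nxt, new_path))
        if hits:
            uniq: dict[tuple, Route] = {}
            for r in hits:
                uniq.setdefault(r.steps, r)
            return list(uniq.values())
        frontier = nxt_frontier
        if not frontier:
            break
    return []


def epa_synthesis_reachability(
    start: LipidPool,
    max_depth: int = 10,
    ops: Sequence[str] = ("DES_PC", "PLA", "ACS", "ELO", "LPCAT_fwd", "LPCAT_rev"),
    **opts,
) -> Route:
    """Shortest route making a PC that bears EPA (20:5).

    Under the modeled machinery desaturation happens only on PC-bound chains
    and elongation only on CoA-bound chains, so any returned route alternates
    the two through the acyl-editing shuttle (e.g. 18:1 -> 18:3 on PC,
    release to CoA, 18:3 -> 20:3 on CoA, re-esterify, 20:3 -> 20:5 on PC).
    Returns an empty route if the start pool already satisfies the target;
    raises ``RouteNotFoundError`` if unreachable with the enabled operators.
    """

    def bears_epa(sp: LipidSpecies) -> bool:
        return sp.class_id == "PC" and EPA in sp.chains

    routes = find_routes(start, bears_epa, max_depth, ops=ops, **opts)
    if not routes:
        raise RouteNotFoundError(
            f"no PC bearing 20:5 reachable within {max_depth} steps "
            f"with operators {tuple(ops)}"
        )
    return routes[0]
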