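"""Candidate lipid species enumeration and the sorted m/z lookup index.

Composition-level identity ("PC 36:6") is what a Q1 / precursor-ion /
neutral-loss scan can know; positional identity ("PC 20:5/16:1", sn-1/sn-2)
comes only from product-ion scans.  The two are kept distinct: unresolved
chain multisets are written with "_" (descending carbons, then double bonds),
resolved species with "/" in sn order.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

import pandas as pd

from .chem import (
    ADDUCTS,
    CLASSES,
    DEFAULT_MODE_ADDUCTS,
    AcylChain,
    LipidClassSpec,
    assemble_species_formula,
    ion_mz,
)

__all__ = [
    "DEFAULT_POOL",
    "AcylPool",
    "LipidSpecies",
    "IndexEntry",
    "CandidateIndex",
    "enumerate_compositions",
    "build_index",
]

#: acyl chains observed across the profiled diatom lipidome (EPA 20:5, its
#: C16/C18 precursors, myristate, arachidonate-type C20:4, DHA 22:6).
DEFAULT_POOL_CHAINS = (
    "14:0", "16:0", "16:1", "16:2", "16:3",
    "18:1", "18:2", "18:3", "18:4",
    "20:4", "20:5", "22:6",
)


def _chain_sort_key(c: AcylChain) -> tuple[int, int]:
    return (-c.carbons, -c.double_bonds)


@dataclass(frozen=True)
class AcylPool:
    """Ordered, duplicate-free set of acyl chains to enumerate over."""

    chains: tuple[AcylChain, ...]

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("acyl pool must be non-empty")
        if len(set(self.chains)) != len(self.chains):
            raise ValueError("acyl pool contains duplicates")

    @classmethod
    def from_strings(cls, names: Iterable[str]) -> "AcylPool":
        return cls(tuple(AcylChain.parse(n) for n in names))

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self):
        return iter(self.chains)


DEFAULT_POOL = AcylPool.from_strings(DEFAULT_POOL_CHAINS)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid of one class bearing a chain multiset, positionally resolved or not.

    When ``sn_resolved`` the chain tuple is in sn order (sn-1, sn-2[, sn-3]);
    otherwise it is stored canonically (descending carbons then double bonds).
    """

    class_id: str
    chains: tuple[AcylChain, ...]
    sn_resolved: bool = False

    def __post_init__(self) -> None:
        spec = CLASSES.get(self.class_id)
        if spec is None:
            raise ValueError(f"unknown lipid class {self.class_id!r}")
        if len(self.chains) != spec.n_acyl:
            raise ValueError(
                f"{self.class_id} carries {spec.n_acyl} acyls, got {len(self.chains)}"
            )
        if not self.sn_resolved:
            object.__setattr__(
                self, "chains", tuple(sorted(self.chains, key=_chain_sort_key))
            )

    @classmethod
    def parse(cls, class_id: str, chain_text: str) -> "LipidSpecies":
        """Parse "20:5/16:1" (resolved) or "20:5_16:1" (unresolved)."""
        if "/" in chain_text:
            sep, resolved = "/", True
        else:
            sep, resolved = "_", False
        chains = tuple(AcylChain.parse(p) for p in chain_text.split(sep))
        return cls(class_id, chains, sn_resolved=resolved)

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)

    @property
    def composition(self) -> str:
        """Total-level shorthand, e.g. '36:6'."""
        return f"{self.total_carbons}:{self.total_double_bonds}"

    @property
    def chain_string(self) -> str:
        sep = "/" if self.sn_resolved else "_"
        return sep.join(str(c) for c in self.chains)

    @property
    def name(self) -> str:
        return f"{self.class_id} {self.chain_string}"

    @property
    def sn2(self) -> AcylChain:
        if not self.sn_resolved:
            raise ValueError(f"{self.name} has unresolved positions")
        if len(self.chains) < 2:
            raise ValueError(f"{self.name} has no sn-2 chain")
        return self.chains[1]

    def unresolved(self) -> "LipidSpecies":
        return LipidSpecies(self.class_id, self.chains, sn_resolved=False)

    def formula(self):
        return assemble_species_formula(self.class_id, self.chains)

    def mz(self, adduct: str) -> float:
        return ion_mz(self.formula(), adduct)


def enumerate_compositions(
    pool: AcylPool, class_spec: LipidClassSpec | str
) -> list[LipidSpecies]:
    """All unordered chain multisets of the class's acyl count over ``pool``.

    Diacyl classes yield n(n+1)/2 species, triacyl C(n+2,3), in a canonical
    deterministic order: total carbons, then total double bonds, then the
    canonical chain string.
    """
    if isinstance(class_spec, str):
        class_spec = CLASSES[class_spec]
    out = [
        LipidSpecies(class_spec.class_id, combo)
        for combo in combinations_with_replacement(pool.chains, class_spec.n_acyl)
    ]
    out.sort(key=lambda s: (s.total_carbons, s.total_double_bonds, s.chain_string))
    return out


@dataclass(frozen=True)
class IndexEntry:
    species: LipidSpecies
    adduct: str
    mz: float
    mode_token: str


@dataclass
class CandidateIndex:
    """m/z-sorted candidate table with binary-search range queries."""

    entries: list[IndexEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(
            self.entries, key=lambda e: (e.mz, e.species.name, e.adduct)
        )
        self._mzs = [e.mz for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def query(
        self, mz: float, tolerance: float, mode_token: str | None = None
    ) -> list[IndexEntry]:
        """All entries with |entry.mz - mz| <= tolerance, optionally mode-gated."""
        lo = bisect.bisect_left(self._mzs, mz - tolerance)
        hi = bisect.bisect_right(self._mzs, mz + tolerance)
        hits = self.entries[lo:hi]
        if mode_token is not None:
            hits = [e for e in hits if e.mode_token == mode_token]
        return hits

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": [e.species.class_id for e in self.entries],
                "composition": [e.species.composition for e in self.entries],
                "chains": [e.species.chain_string for e in self.entries],
                "sn_resolved": [e.species.sn_resolved for e in self.entries],
                "adduct": [e.adduct for e in self.entries],
                "mode": [e.mode_token for e in self.entries],
                "mz": [round(e.mz, 4) for e in self.entries],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_index(
    compositions: Sequence[LipidSpecies],
    mode_adducts: dict[str, tuple[str, ...]] | None = None,
) -> CandidateIndex:
    """One entry per (species, adduct) admitted by the class's detection modes.

    ``mode_adducts`` maps scan tokens to adduct names (defaults to the
    package-wide defaults).  Rebuilding from the same inputs is bit-identical.
    """
    if not compositions:
        raise ValueError("no compositions to index")
    if mode_adducts is None:
        mode_adducts = DEFAULT_MODE_ADDUCTS
    entries: list[IndexEntry] = []
    for sp in compositions:
        spec = CLASSES[sp.class_id]
        for token in sorted(spec.detection_modes):
            adduct_names = mode_adducts.get(token, ())
            if token in mode_adducts and not adduct_names:
                raise ValueError(f"empty adduct list for mode {token}")
            for ad in adduct_names:
                if ADDUCTS[ad].polarity != token[-1]:
                    raise ValueError(
                        f"adduct {ad} polarity does not match mode {token}"
                    )
                entries.append(IndexEntry(sp, ad, sp.mz(ad), token))
    if not entries:
        raise ValueError("no (species, adduct) entries; check detection modes")
    return CandidateIndex(entries)
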