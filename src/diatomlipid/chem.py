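"""Elemental formulas, monoisotopic masses and diagnostic ions for glycerolipids.

Every downstream stage (candidate enumeration, synthetic spectra, annotation)
rests on the mass arithmetic here.  A glycerolipid is assembled as

    glycerol (C3H8O3) + head group + sum of free fatty acids - n H2O

where ``n`` counts the ester bonds to the backbone plus the bonds internal to
the head block (one per condensation).  Masses are monoisotopic: each element
contributes the mass of its most abundant isotope.  Ion m/z values carry the
electron-mass correction, so the protonated phosphocholine head fragment comes
out at 184.0733 (the classic precursor-ion-scan diagnostic for PC), and the
hexosyl neutral loss at 162.0528 (the galactolipid neutral-loss diagnostic).

Only singly charged adducts are modeled; direct-infusion glycerolipid ions are
predominantly singly charged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "C13_C12_DELTA",
    "AcylChain",
    "ElementalFormula",
    "formula",
    "LipidClassSpec",
    "AdductSpec",
    "CLASSES",
    "ADDUCTS",
    "DEFAULT_MODE_ADDUCTS",
    "acyl_formula",
    "assemble_species_formula",
    "monoisotopic_mass",
    "ion_mz",
    "diagnostic_mz",
]

# Standard monoisotopic atomic masses (12C scale; CODATA/AME values at the
# precision an ESI-QTRAP workflow needs).  C is exactly 12 by definition.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737615,
    "S": 31.9720707,
    "Na": 22.9897693,
}

ELECTRON_MASS = 0.00054858
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS
#: mass difference 13C - 12C, the spacing of the isotope envelope
C13_C12_DELTA = 1.003355

ELEMENTS = tuple(MONOISOTOPIC_MASS)

_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")


@dataclass(frozen=True, order=True)
class AcylChain:
    """One fatty acyl chain in ``carbons:double_bonds`` shorthand.

    Double-bond positions and the omega series are not tracked: "20:5" stands
    for EPA by convention, "22:6" for DHA.
    """

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >=2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds <= self.carbons // 2:
            raise ValueError(
                f"double bonds must lie in [0, {self.carbons // 2}] for a "
                f"C{self.carbons} chain, got {self.double_bonds}"
            )

    @classmethod
    def parse(cls, text: str) -> "AcylChain":
        m = _CHAIN_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse acyl chain {text!r}, expected 'c:d'")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element->count map over C,H,N,O,P,S,Na.

    Counts are non-negative; subtraction raises rather than going negative.
    """

    _counts: tuple[tuple[str, int], ...] = field(default=())

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        clean = {}
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n:
                clean[el] = int(n)
        return cls(tuple((el, clean[el]) for el in ELEMENTS if el in clean))

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def get(self, element: str) -> int:
        return dict(self._counts).get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        c = self.counts
        for el, n in other._counts:
            c[el] = c.get(el, 0) + n
        return ElementalFormula.from_counts(c)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        c = self.counts
        for el, n in other._counts:
            c[el] = c.get(el, 0) - n
            if c[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({c[el]})"
                )
        return ElementalFormula.from_counts(c)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalFormula.from_counts({el: n * k for el, n in self._counts})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self._counts
        ) or "(empty)"


def formula(**counts: int) -> ElementalFormula:
    """Convenience constructor: ``formula(C=6, H=10, O=5)``."""
    return ElementalFormula.from_counts(counts)


WATER = formula(H=2, O=1)
GLYCEROL = formula(C=3, H=8, O=3)


@dataclass(frozen=True)
class LipidClassSpec:
    """Head-group block and detection behaviour of one glycerolipid class.

    ``head_group_formula`` is the free (uncondensed) head block; ``n_head_bonds``
    counts the condensations that attach it (and, for DGDG, link the second
    hexose), each releasing one water.  ``detection_modes`` holds scan tokens
    like ``"PIS+"``, ``"NL+"``, ``"Q1-"``; classes never seen in the modeled
    scans (DAG, TAG, ...) have an empty set.
    """

    class_id: str
    n_acyl: int
    head_group_formula: ElementalFormula
    n_head_bonds: int
    detection_modes: frozenset[str] = frozenset()
    has_glycerol: bool = True
    ionizable: bool = True

    def __post_init__(self) -> None:
        if self.n_acyl not in (1, 2, 3):
            raise ValueError("n_acyl must be 1, 2 or 3")


_PHOSPHOCHOLINE = formula(C=5, H=14, N=1, O=4, P=1)
_PHOSPHOETHANOLAMINE = formula(C=2, H=8, N=1, O=4, P=1)
_GLYCEROPHOSPHATE = formula(C=3, H=9, O=6, P=1)
_INOSITOLPHOSPHATE = formula(C=6, H=13, O=9, P=1)
_HEXOSE = formula(C=6, H=12, O=6)
_SULFOQUINOVOSE = formula(C=6, H=12, O=8, S=1)

CLASSES: dict[str, LipidClassSpec] = {
    "PC": LipidClassSpec("PC", 2, _PHOSPHOCHOLINE, 1, frozenset({"PIS+"})),
    "PE": LipidClassSpec("PE", 2, _PHOSPHOETHANOLAMINE, 1, frozenset({"Q1-"})),
    "PG": LipidClassSpec("PG", 2, _GLYCEROPHOSPHATE, 1, frozenset({"Q1-"})),
    "PI": LipidClassSpec("PI", 2, _INOSITOLPHOSPHATE, 1, frozenset({"Q1-"})),
    "LPC": LipidClassSpec("LPC", 1, _PHOSPHOCHOLINE, 1),
    "MGDG": LipidClassSpec("MGDG", 2, _HEXOSE, 1, frozenset({"NL+"})),
    "DGDG": LipidClassSpec("DGDG", 2, _HEXOSE * 2, 2, frozenset({"NL+"})),
    "SQDG": LipidClassSpec("SQDG", 2, _SULFOQUINOVOSE, 1, frozenset({"Q1-"})),
    "DAG": LipidClassSpec("DAG", 2, formula(), 0),
    "TAG": LipidClassSpec("TAG", 3, formula(), 0),
    "FFA": LipidClassSpec("FFA", 1, formula(), 0, has_glycerol=False),
    "ACYL_COA": LipidClassSpec(
        "ACYL_COA", 1, formula(), 0, has_glycerol=False, ionizable=False
    ),
}


@dataclass(frozen=True)
class AdductSpec:
    """Singly charged ionization adduct; ``delta`` is a signed element map."""

    name: str
    polarity: str
    delta: tuple[tuple[str, int], ...]
    charge: int

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")
        if (self.charge > 0) != (self.polarity == "+"):
            raise ValueError("adduct polarity must match charge sign")

    @property
    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.delta)


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", "+", (("H", 1),), +1),
    "[M+Na]+": AdductSpec("[M+Na]+", "+", (("Na", 1),), +1),
    "[M-H]-": AdductSpec("[M-H]-", "-", (("H", -1),), -1),
    "[M+HCOO]-": AdductSpec("[M+HCOO]-", "-", (("C", 1), ("H", 1), ("O", 2)), -1),
}

#: default adduct list generated/matched per scan token.  The neutral-loss
#: channel carries both protonated and sodiated candidates because the adduct
#: under acidified infusion is not fixed a priori; configurable everywhere.
DEFAULT_MODE_ADDUCTS: dict[str, tuple[str, ...]] = {
    "PIS+": ("[M+H]+",),
    "NL+": ("[M+H]+", "[M+Na]+"),
    "Q1-": ("[M-H]-",),
}


def acyl_formula(chain: AcylChain) -> ElementalFormula:
    """Free fatty acid stoichiometry C_c H_(2c-2d) O2."""
    return formula(C=chain.carbons, H=2 * chain.carbons - 2 * chain.double_bonds, O=2)


def assemble_species_formula(
    class_spec: LipidClassSpec | str, chains: Iterable[AcylChain]
) -> ElementalFormula:
    """Neutral molecular formula of a species of ``class_spec`` bearing ``chains``.

    Raises on chain-count mismatch or a class with no defined neutral formula
    (acyl-CoA, which only participates in the reaction network).
    """
    if isinstance(class_spec, str):
        try:
            class_spec = CLASSES[class_spec]
        except KeyError:
            raise ValueError(f"unknown lipid class {class_spec!r}") from None
    chains = tuple(chains)
    if len(chains) != class_spec.n_acyl:
        raise ValueError(
            f"{class_spec.class_id} carries {class_spec.n_acyl} acyls, "
            f"got {len(chains)}"
        )
    if not class_spec.ionizable:
        raise ValueError(f"{class_spec.class_id} has no defined neutral formula")
    total = ElementalFormula()
    for ch in chains:
        total = total + acyl_formula(ch)
    if not class_spec.has_glycerol:
        return total  # free fatty acid
    total = total + GLYCEROL + class_spec.head_group_formula
    n_condensations = len(chains) + class_spec.n_head_bonds
    return total - WATER * n_condensations


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da; additive over formula addition."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f._counts)


def ion_mz(f: ElementalFormula, adduct: AdductSpec | str) -> float:
    """m/z of the singly charged ``adduct`` ion of neutral formula ``f``.

    The electron mass is subtracted for cations and added for anions.  Raises
    if the adduct would remove atoms the formula does not have.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unknown adduct {adduct!r}") from None
    counts = f.counts
    for el, n in adduct.delta:
        counts[el] = counts.get(el, 0) + n
        if counts[el] < 0:
            raise ValueError(
                f"adduct {adduct.name} removes {el} the formula lacks"
            )
    m = monoisotopic_mass(f) + adduct.delta_mass - adduct.charge * ELECTRON_MASS
    return m / abs(adduct.charge)


def diagnostic_mz(name: str, chain: AcylChain | None = None) -> float:
    """Diagnostic fragment m/z or neutral-loss mass.

    ``phosphocholine_fragment``
        the C5H15NO4P+ cation monitored by the positive precursor-ion scan
        for PC (184.0733, printed as 184.07).
    ``hexose_neutral_loss``
        the C6H10O5 neutral lost by galactolipids in the positive
        neutral-loss scan (162.0528, nominal 162).
    ``acyl_carboxylate``
        the [RCOO]- anion of ``chain``, the product-ion-scan reporter used
        for sn-positional reading.
    """
    if name == "phosphocholine_fragment":
        return monoisotopic_mass(formula(C=5, H=15, N=1, O=4, P=1)) - ELECTRON_MASS
    if name == "hexose_neutral_loss":
        return monoisotopic_mass(formula(C=6, H=10, O=5))
    if name == "acyl_carboxylate":
        if chain is None:
            raise ValueError("acyl_carboxylate needs a chain")
        return (
            monoisotopic_mass(acyl_formula(chain))
            - MONOISOTOPIC_MASS["H"]
            + ELECTRON_MASS
        )
    raise ValueError(f"unknown diagnostic {name!r}")
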