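"""Instrument-free synthetic spectra with known ground truth.

The packaged fixtures emulate the profiled diatom polar lipidome: a
phospholipid (PL) fraction of 11 PC + 2 PG + 1 PI species (no PE) and a
glycolipid (GL) fraction of 8 MGDG + 5 DGDG + 3 SQDG species.  Roster
construction honors the biological constraints the profile obeys: every
chloroplast-type lipid (MGDG, DGDG, SQDG, PG, PI) carries a C16 acyl at sn-2,
C18 acyls occur only at the sn-2 position of PCs, and EPA-containing
eukaryotic PCs carry EPA at sn-1.

Precursor scans place one peak per roster species visible in the requested
mode at its exact adduct m/z; optional decoy peaks and a binomial 13C isotope
envelope (M, M+1, M+2) can be layered on top.  Product-ion scans emit the
acyl carboxylate anions with a fixed sn-2 : sn-1 intensity ratio ``r`` — the
positional convention shared with the assigner, since published diagnostic
rules give no number.  All randomness is seeded; identical inputs give
byte-identical spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .chem import (
    C13_C12_DELTA,
    CLASSES,
    DEFAULT_MODE_ADDUCTS,
    AcylChain,
    diagnostic_mz,
    ion_mz,
    monoisotopic_mass,
)
from .species import LipidSpecies
from .spectra_io import ScanMode, Spectrum

__all__ = [
    "SN2_SN1_RATIO",
    "RosterEntry",
    "IsotopeModel",
    "FixtureSpec",
    "load_roster",
    "packaged_fixtures",
    "generate_scan",
    "generate_product_scan",
]

#: sn-2 : sn-1 carboxylate intensity ratio used by the generator and, as the
#: matching threshold context, by the positional assigner.
SN2_SN1_RATIO = 2.0

#: decoy peaks are never placed closer than this to a true peak (Da)
DECOY_EXCLUSION = 0.05

_BASE_INTENSITY = 1000.0


@dataclass(frozen=True)
class RosterEntry:
    species: LipidSpecies  # positionally resolved
    abundance: float

    def __post_init__(self) -> None:
        if not self.species.sn_resolved:
            raise ValueError(f"roster species {self.species.name} must be resolved")
        if not 0 < self.abundance <= 1:
            raise ValueError("abundance must lie in (0, 1]")


@dataclass(frozen=True)
class IsotopeModel:
    """Binomial 13C envelope: M+k scaled by the mass-k binomial term."""

    p13c: float = 0.0107
    depth: int = 2

    def ratios(self, n_carbons: int) -> list[float]:
        """Intensity of M+k relative to M, k = 1..depth."""
        p, n = self.p13c, n_carbons
        base = (1 - p) ** n
        out = []
        for k in range(1, self.depth + 1):
            term = math.comb(n, k) * p**k * (1 - p) ** (n - k)
            out.append(term / base)
        return out


@dataclass(frozen=True)
class FixtureSpec:
    """Complete recipe for one fraction's synthetic scans."""

    name: str
    fraction: str  # "PL" or "GL"
    roster: tuple[RosterEntry, ...]
    n_decoys: int = 0
    decoy_scale: float = 50.0
    isotopes: IsotopeModel | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.roster:
            raise ValueError("fixture roster is empty")
        if self.fraction not in ("PL", "GL"):
            raise ValueError("fraction must be 'PL' or 'GL'")

    @property
    def scan_modes(self) -> tuple[ScanMode, ...]:
        """The acquisition modes under which this fraction is profiled."""
        if self.fraction == "PL":
            return (
                ScanMode("PIS", "+", round(diagnostic_mz("phosphocholine_fragment"), 4)),
                ScanMode("Q1", "-"),
            )
        return (
            ScanMode("NL", "+", round(diagnostic_mz("hexose_neutral_loss"), 4)),
            ScanMode("Q1", "-"),
        )


def load_roster(source) -> tuple[RosterEntry, ...]:
    """Read a roster TSV (class, sn1, sn2, sn3, abundance)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for _, row in df.iterrows():
        chains = [AcylChain.parse(row[c]) for c in ("sn1", "sn2", "sn3") if row[c]]
        sp = LipidSpecies(row["class"], tuple(chains), sn_resolved=True)
        entries.append(RosterEntry(sp, float(row["abundance"])))
    return tuple(entries)


def packaged_fixtures(seed: int = 1, n_decoys: int = 0) -> dict[str, FixtureSpec]:
    """The shipped PL and GL fraction fixtures (isotopes off, zero decoys)."""
    out = {}
    for name, fraction in (("fsolaris_pl", "PL"), ("fsolaris_gl", "GL")):
        ref = resources.files("diatomlipid.data").joinpath(f"{name}.tsv")
        with resources.as_file(ref) as path:
            roster = load_roster(path)
        out[name] = FixtureSpec(
            name=name, fraction=fraction, roster=roster, seed=seed, n_decoys=n_decoys
        )
    return out


def _mode_seed(seed: int, token: str) -> np.random.Generator:
    # stable per-mode stream so each scan is independently reproducible
    return np.random.default_rng([seed, sum(ord(c) for c in token)])


def generate_scan(
    fixture: FixtureSpec,
    mode: ScanMode,
    mode_adducts: dict[str, tuple[str, ...]] | None = None,
) -> Spectrum:
    """Precursor-level scan of the fixture in ``mode``.

    One peak per roster species whose class is detectable in the mode, at the
    exact m/z of the mode's primary adduct, intensity proportional to roster
    abundance.  Decoys are uniform over [400, 1000] m/z, rejected within
    0.05 Da of any true peak.
    """
    if mode_adducts is None:
        mode_adducts = DEFAULT_MODE_ADDUCTS
    token = mode.token
    if token not in mode_adducts:
        raise ValueError(f"no adduct configured for scan mode {token}")
    primary_adduct = mode_adducts[token][0]

    mzs: list[float] = []
    intens: list[float] = []
    for entry in fixture.roster:
        spec = CLASSES[entry.species.class_id]
        if token not in spec.detection_modes:
            continue
        f = entry.species.formula()
        mz0 = ion_mz(f, primary_adduct)
        i0 = entry.abundance * _BASE_INTENSITY
        mzs.append(mz0)
        intens.append(i0)
        if fixture.isotopes is not None:
            for k, ratio in enumerate(fixture.isotopes.ratios(f.get("C")), start=1):
                mzs.append(mz0 + k * C13_C12_DELTA)
                intens.append(i0 * ratio)

    rng = _mode_seed(fixture.seed, token)
    true_mzs = np.array(sorted(mzs)) if mzs else np.empty(0)
    added = 0
    while added < fixture.n_decoys:
        cand = float(rng.uniform(400.0, 1000.0))
        if true_mzs.size and np.min(np.abs(true_mzs - cand)) < DECOY_EXCLUSION:
            continue
        mzs.append(cand)
        intens.append(float(rng.uniform(0.1, 1.0)) * fixture.decoy_scale)
        added += 1

    order = np.argsort(mzs, kind="stable")
    return Spectrum(
        mode,
        np.round(np.asarray(mzs, dtype=float)[order], 4),
        np.round(np.asarray(intens, dtype=float)[order], 1),
        fraction=fixture.fraction,
    )


def generate_product_scan(
    species: LipidSpecies,
    polarity: str = "-",
    r: float = SN2_SN1_RATIO,
    precursor_adduct: str | None = None,
) -> Spectrum:
    """Product-ion scan of one positionally resolved species.

    Emits one [RCOO]- carboxylate per acyl chain; the sn-2 chain's fragment
    is ``r`` times as intense as each sn-1 (and sn-3) contribution, and
    coincident fragments of identical chains sum.  A low-intensity head-group
    marker (deprotonated head block) is appended for head-bearing classes.
    Only negative-mode product scans are modeled.
    """
    if polarity != "-":
        raise ValueError("product scans are modeled in negative mode only")
    if not species.sn_resolved:
        raise ValueError(f"{species.name} has unresolved sn positions")
    spec = CLASSES[species.class_id]
    if spec.n_acyl < 2:
        raise ValueError("product scans model diacyl/triacyl species")

    if precursor_adduct is None:
        precursor_adduct = "[M-H]-"
    precursor = ion_mz(species.formula(), precursor_adduct)

    base = 100.0
    frag: dict[float, float] = {}
    for pos, chain in enumerate(species.chains):
        mz = round(diagnostic_mz("acyl_carboxylate", chain), 4)
        weight = r if pos == 1 else 1.0  # sn-2 is the middle position
        frag[mz] = frag.get(mz, 0.0) + base * weight
    if spec.head_group_formula:
        head_mz = round(
            monoisotopic_mass(spec.head_group_formula) - 1.0078250319 + 0.00054858, 4
        )
        frag[head_mz] = frag.get(head_mz, 0.0) + base * 0.2

    mzs = sorted(frag)
    return Spectrum(
        ScanMode("PRODUCT", "-", round(precursor, 4)),
        np.array(mzs),
        np.array([round(frag[m], 1) for m in mzs]),
        fraction=None,
    )
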