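"""Peak matching against the candidate index, overlap flagging, and profiling.

Matching is class-gated by scan mode, mirroring what each acquisition can
see: the positive precursor-ion scan for the 184.07 phosphocholine fragment
admits PC only; the positive neutral-loss scan for 162 admits the
galactolipids MGDG and DGDG; the negative Q1 scan admits SQDG, PG, PI (and
PE, whose absence from the profile is then a measured negative rather than an
assumption).  Classes within a scan are resolved by head-group mass.

Every candidate within tolerance is reported, ranked by absolute mass error;
multi-candidate peaks are flagged ambiguous and contribute only their
best-ranked candidate to the species counts, so profile totals stay
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import CLASSES, diagnostic_mz
from .species import CandidateIndex, IndexEntry, LipidSpecies
from .spectra_io import Spectrum

__all__ = [
    "DEFAULT_TOLERANCE",
    "Annotation",
    "ProfileReport",
    "match_peaks",
    "flag_isotopic_overlap",
    "resolve_profile",
]

#: default matching tolerance in Da (unit-resolution QTRAP regime)
DEFAULT_TOLERANCE = 0.01

AMBIGUOUS = "ambiguous_multi_candidate"
ISOTOPE_RISK = "isotopic_overlap_risk"

#: expected diagnostic parameter per gated scan token (loose sanity window)
_EXPECTED_PARAM = {
    "PIS+": ("phosphocholine_fragment", 0.1),
    "NL+": ("hexose_neutral_loss", 0.6),
}


@dataclass(frozen=True)
class Annotation:
    """One (peak, candidate) match at composition-level identity."""

    observed_mz: float
    species: LipidSpecies
    adduct: str
    theoretical_mz: float
    scan_token: str
    fraction: str | None = None
    rank: int = 1
    flags: frozenset[str] = frozenset()
    positional: str | None = None
    assembly: str | None = None

    @property
    def class_id(self) -> str:
        return self.species.class_id

    @property
    def composition(self) -> str:
        return self.species.composition

    @property
    def error_da(self) -> float:
        return self.observed_mz - self.theoretical_mz

    @property
    def error_mda(self) -> float:
        return self.error_da * 1000.0

    @property
    def error_ppm(self) -> float:
        return self.error_da / self.theoretical_mz * 1e6


def _admitted_classes(spectrum: Spectrum) -> frozenset[str]:
    token = spectrum.mode.token
    admitted = frozenset(
        cid for cid, spec in CLASSES.items() if token in spec.detection_modes
    )
    expectation = _EXPECTED_PARAM.get(token)
    if expectation is not None:
        diag, window = expectation
        expected = diagnostic_mz(diag)
        if spectrum.mode.param is None or abs(spectrum.mode.param - expected) > window:
            raise ValueError(
                f"scan parameter {spectrum.mode.param} does not match the "
                f"{diag} diagnostic ({expected:.4f})"
            )
    return admitted


def match_peaks(
    spectrum: Spectrum,
    index: CandidateIndex,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[Annotation]:
    """Annotate every peak with all in-tolerance, mode-admitted candidates.

    Candidates for one peak are ranked by |mass error| (ties broken by
    candidate name for determinism); if a peak has more than one candidate,
    all of them carry the ambiguous flag.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    token = spectrum.mode.token
    if spectrum.mode.kind == "PRODUCT":
        raise ValueError("product-ion scans are handled by the positional module")
    admitted = _admitted_classes(spectrum)
    out: list[Annotation] = []
    for mz in spectrum.mz.tolist():
        hits = [
            e
            for e in index.query(mz, tolerance, mode_token=token)
            if e.species.class_id in admitted
        ]
        hits.sort(key=lambda e: (abs(mz - e.mz), e.species.name, e.adduct))
        flags = frozenset({AMBIGUOUS}) if len(hits) > 1 else frozenset()
        for rank, e in enumerate(hits, start=1):
            out.append(
                Annotation(
                    observed_mz=mz,
                    species=e.species,
                    adduct=e.adduct,
                    theoretical_mz=e.mz,
                    scan_token=token,
                    fraction=spectrum.fraction,
                    rank=rank,
                    flags=flags,
                )
            )
    return out


def flag_isotopic_overlap(
    index: CandidateIndex, resolution_window: float
) -> list[tuple[IndexEntry, IndexEntry]]:
    """Candidate pairs whose M+2 envelope lands on a neighbour's monoisotope.

    Within one detection mode, a pair (A, B) with mz(B) - mz(A) within
    ``resolution_window`` of two 13C-12C spacings (2.00671 Da) is flagged:
    A's M+2 isotopologue overlaps B.  The report is advisory — candidates are
    warned about, never removed.
    """
    if resolution_window <= 0:
        raise ValueError("resolution window must be positive")
    from .chem import C13_C12_DELTA

    target = 2 * C13_C12_DELTA
    pairs: list[tuple[IndexEntry, IndexEntry]] = []
    entries = index.entries
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            gap = b.mz - a.mz
            if gap > target + resolution_window:
                break
            if a.mode_token == b.mode_token and abs(gap - target) <= resolution_window:
                pairs.append((a, b))
    return pairs


@dataclass
class ProfileReport:
    """Per-class species inventory plus the profile's structural checks."""

    species_by_class: dict[str, list[str]] = field(default_factory=dict)
    checks: dict[str, bool] = field(default_factory=dict)
    check_support: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {cls: len(v) for cls, v in self.species_by_class.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, class_id: str) -> int:
        return len(self.species_by_class.get(class_id, []))

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "total": self.total,
            "species": self.species_by_class,
            "checks": self.checks,
            "check_support": self.check_support,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_text(self) -> str:
        lines = [f"total species: {self.total}"]
        for cls in sorted(self.species_by_class):
            names = ", ".join(self.species_by_class[cls])
            lines.append(f"  {cls}: {self.count(cls)}  ({names})")
        for name, ok in sorted(self.checks.items()):
            lines.append(f"check {name}: {'pass' if ok else 'FAIL'}")
        return "\n".join(lines)


def resolve_profile(
    annotations: Iterable[Annotation],
    positional_species: Sequence[LipidSpecies] = (),
) -> ProfileReport:
    """Collapse annotations into distinct species and evaluate profile checks.

    Deduplication is keyed on (class, composition): a species seen both in Q1
    and in a class-specific scan is one species, and ambiguous peaks count
    only through their best-ranked candidate.  ``positional_species`` are
    resolved assignments used for the chain-level checks (C18 acyls only at
    PC sn-2; sn-2 C16 on all chloroplast-type classes); without them those
    checks are vacuously true, as is PE absence on an empty profile.
    """
    seen: dict[tuple[str, str], str] = {}
    for a in annotations:
        if a.rank != 1:
            continue
        key = (a.class_id, a.composition)
        seen.setdefault(key, f"{a.class_id} {a.composition}")

    by_class: dict[str, list[str]] = {}
    for (cls, comp), label in sorted(seen.items()):
        by_class.setdefault(cls, []).append(label)

    checks: dict[str, bool] = {}
    support: dict[str, list[str]] = {}

    pe_species = by_class.get("PE", [])
    checks["pe_absent"] = not pe_species
    support["pe_absent"] = list(pe_species)

    c18_violations = []
    for sp in positional_species:
        for pos, chain in enumerate(sp.chains):
            if chain.carbons == 18 and not (sp.class_id == "PC" and pos == 1):
                c18_violations.append(sp.name)
    checks["c18_only_at_pc_sn2"] = not c18_violations
    support["c18_only_at_pc_sn2"] = c18_violations

    chloroplast = {"MGDG", "DGDG", "SQDG", "PG", "PI"}
    sn2_violations = [
        sp.name
        for sp in positional_species
        if sp.class_id in chloroplast and sp.sn2.carbons != 16
    ]
    checks["sn2_c16_on_chloroplast_classes"] = not sn2_violations
    support["sn2_c16_on_chloroplast_classes"] = sn2_violations

    return ProfileReport(by_class, checks, support)
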