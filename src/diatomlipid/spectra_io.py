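"""Peak-list and annotation-table I/O with scan-mode metadata.

The native format is a small TSV dialect: ``#``-prefixed header lines carry
the acquisition metadata, then two tab-separated columns of m/z and
intensity.  m/z is serialized at 4 decimals and intensity at 1, which keeps
files diff-stable and matches unit-resolution QTRAP practice.  MGF is
supported through pyteomics for interoperability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ScanMode",
    "Spectrum",
    "read_peaklist",
    "write_peaklist",
    "write_annotation_table",
    "ANNOTATION_COLUMNS",
]


class FormatError(ValueError):
    """Raised for malformed peak-list files."""


_KINDS = ("Q1", "PIS", "NL", "PRODUCT")


@dataclass(frozen=True)
class ScanMode:
    """Acquisition mode of one direct-infusion scan.

    ``param`` is the diagnostic fragment m/z for a precursor-ion scan, the
    neutral-loss mass for a neutral-loss scan, and the precursor m/z for a
    product-ion scan; Q1 scans have none.
    """

    kind: str
    polarity: str
    param: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise FormatError(f"unknown scan kind {self.kind!r}")
        if self.polarity not in ("+", "-"):
            raise FormatError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if self.kind == "Q1":
            if self.param is not None:
                raise FormatError("Q1 scans carry no parameter")
        elif self.param is None:
            raise FormatError(f"{self.kind} scans require a parameter")

    @property
    def token(self) -> str:
        """Short gating token, e.g. 'PIS+', 'Q1-'."""
        return f"{self.kind}{self.polarity}"


@dataclass(frozen=True)
class Spectrum:
    """One scan: mode, optional fraction label, and a sorted peak list."""

    mode: ScanMode
    mz: np.ndarray
    intensity: np.ndarray
    fraction: str | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        if mz.size and np.any(mz <= 0):
            raise ValueError("non-positive m/z")
        if mz.size and np.any(np.diff(mz) < 0):
            warnings.warn("peak list not sorted by m/z; sorting", stacklevel=2)
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return int(self.mz.size)


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for ln in lines:
        body = ln[1:].strip()
        if "=" not in body:
            raise FormatError(f"bad header line {ln!r}")
        key, _, val = body.partition("=")
        meta[key.strip()] = val.strip()
    return meta


def _mode_from_meta(meta: dict[str, str]) -> tuple[ScanMode, str | None]:
    for req in ("mode", "polarity"):
        if req not in meta:
            raise FormatError(f"missing #{req}= header")
    param_text = meta.get("param", "")
    param = float(param_text) if param_text else None
    mode = ScanMode(meta["mode"], meta["polarity"], param)
    return mode, meta.get("fraction") or None


def read_peaklist(path, fmt: str | None = None) -> Spectrum:
    """Read one spectrum from TSV (native dialect) or MGF."""
    path = Path(path)
    if fmt is None:
        fmt = "mgf" if path.suffix.lower() == ".mgf" else "tsv"
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt != "tsv":
        raise ValueError(f"unknown peak-list format {fmt!r}")

    header: list[str] = []
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"expected 2 tab-separated columns, got {line!r}")
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"non-numeric peak row {line!r}") from exc
    mode, fraction = _mode_from_meta(_parse_header(header))
    return Spectrum(mode, np.array(mzs), np.array(intens), fraction=fraction)


def write_peaklist(spectrum: Spectrum, path) -> None:
    """Serialize in the native TSV dialect (m/z %.4f, intensity %.1f)."""
    path = Path(path)
    lines = [
        f"#mode={spectrum.mode.kind}",
        f"#polarity={spectrum.mode.polarity}",
        f"#param={'' if spectrum.mode.param is None else format(spectrum.mode.param, '.4f')}",
        f"#fraction={spectrum.fraction or ''}",
    ]
    for mz, inten in spectrum.peaks:
        lines.append(f"{mz:.4f}\t{inten:.1f}")
    path.write_text("\n".join(lines) + "\n")


def _read_mgf(path: Path) -> Spectrum:
    from pyteomics import mgf

    with mgf.read(str(path)) as reader:
        try:
            entry = next(iter(reader))
        except StopIteration:
            raise FormatError(f"no spectra in {path}") from None
    params = entry.get("params", {})
    title = params.get("title", "")
    meta: dict[str, str] = {}
    for piece in title.split(";"):
        if "=" in piece:
            k, _, v = piece.partition("=")
            meta[k.strip()] = v.strip()
    mode, fraction = _mode_from_meta(meta)
    return Spectrum(
        mode,
        np.asarray(entry["m/z array"], dtype=float),
        np.asarray(entry["intensity array"], dtype=float),
        fraction=fraction,
    )


def write_mgf(spectrum: Spectrum, path) -> None:
    from pyteomics import mgf

    title = (
        f"mode={spectrum.mode.kind};polarity={spectrum.mode.polarity};"
        f"param={'' if spectrum.mode.param is None else format(spectrum.mode.param, '.4f')};"
        f"fraction={spectrum.fraction or ''}"
    )
    mgf.write(
        [
            {
                "m/z array": spectrum.mz,
                "intensity array": spectrum.intensity,
                "params": {"title": title},
            }
        ],
        str(path),
        file_mode="w",
    )


ANNOTATION_COLUMNS = (
    "fraction",
    "scan_mode",
    "observed_mz",
    "class",
    "composition",
    "positional",
    "adduct",
    "theoretical_mz",
    "error_mDa",
    "error_ppm",
    "flags",
)


def write_annotation_table(annotations: Iterable, path) -> None:
    """Write annotations as a TSV with a stable column and row order.

    Rows are ordered by class then theoretical m/z; numeric columns are
    formatted explicitly so re-runs are byte-identical.
    """
    rows = []
    for a in annotations:
        rows.append(
            {
                "fraction": a.fraction or "NA",
                "scan_mode": a.scan_token,
                "observed_mz": f"{a.observed_mz:.4f}",
                "class": a.class_id,
                "composition": a.composition,
                "positional": a.positional or "NA",
                "adduct": a.adduct,
                "theoretical_mz": f"{a.theoretical_mz:.4f}",
                "error_mDa": f"{a.error_mda:.3f}",
                "error_ppm": f"{a.error_ppm:.2f}",
                "flags": ";".join(sorted(a.flags)) if a.flags else "",
            }
        )
    frame = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    if len(frame):
        frame = frame.sort_values(
            ["class", "theoretical_mz", "observed_mz", "adduct"],
            kind="stable",
        ).reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False)
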