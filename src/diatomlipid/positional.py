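"""sn-positional assignment from negative-mode product-ion spectra.

The backbone's center position is sn-2.  The assigner reads the acyl
carboxylate fragments ([RCOO]-) of a composition's chains and applies the
package's positional convention, shared with the synthetic generator: the
sn-2 chain yields the most intense carboxylate.  A call is made only when
the top fragment exceeds the runner-up by the ratio threshold tau (default
1.5); otherwise the species stays ambiguous.  Compositions whose chains are
all identical are resolved by symmetry without ratios.

Triacyl calls identify the sn-2 chain only; sn-1 versus sn-3 is left
unresolved, matching the (sn-1/sn-2) granularity of the reported profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chem import CLASSES, diagnostic_mz
from .species import LipidSpecies
from .spectra_io import Spectrum

__all__ = ["RATIO_THRESHOLD", "PositionalCall", "assign_positions"]

#: default intensity-ratio threshold tau for accepting an sn-2 call
RATIO_THRESHOLD = 1.5


@dataclass(frozen=True)
class PositionalCall:
    """Outcome of reading one product-ion spectrum."""

    composition: LipidSpecies  # unresolved input identity
    assignment: LipidSpecies | None  # resolved species, or None
    ratio: float  # observed top/runner-up carboxylate ratio (inf if trivial)
    confidence: str  # "resolved", "trivial", or "ambiguous"
    note: str = ""

    @property
    def is_ambiguous(self) -> bool:
        return self.assignment is None

    @property
    def label(self) -> str:
        return self.assignment.chain_string if self.assignment else "ambiguous"


def _chain_intensity(spectrum: Spectrum, chain, tolerance: float) -> float:
    """Summed intensity of the chain's carboxylate within tolerance; NaN if absent."""
    target = diagnostic_mz("acyl_carboxylate", chain)
    mask = abs(spectrum.mz - target) <= tolerance
    if not mask.any():
        return math.nan
    return float(spectrum.intensity[mask].sum())


def assign_positions(
    product_spectrum: Spectrum,
    composition: LipidSpecies,
    ratio_threshold: float = RATIO_THRESHOLD,
    tolerance: float = 0.01,
    check_precursor: bool = True,
) -> PositionalCall:
    """Assign sn positions of ``composition`` from its product-ion spectrum.

    The chain whose carboxylate is most intense is placed at sn-2 when its
    intensity exceeds the runner-up chain's by at least ``ratio_threshold``.
    Chain order in the input never affects the call.  A missing carboxylate
    for any chain yields an ambiguous call with a note.
    """
    composition = composition.unresolved()
    spec = CLASSES[composition.class_id]
    if product_spectrum.mode.kind != "PRODUCT":
        raise ValueError("positional assignment needs a product-ion scan")
    if check_precursor and product_spectrum.mode.param is not None:
        prec = composition.mz("[M-H]-" if product_spectrum.mode.polarity == "-" else "[M+H]+")
        if abs(prec - product_spectrum.mode.param) > 0.5:
            raise ValueError(
                f"product scan precursor {product_spectrum.mode.param} does not "
                f"match {composition.name} ({prec:.4f})"
            )

    distinct = sorted(set(composition.chains), key=lambda c: (-c.carbons, -c.double_bonds))
    if len(distinct) == 1:
        # symmetric composition: every position carries the same chain
        resolved = LipidSpecies(
            composition.class_id, composition.chains, sn_resolved=True
        )
        return PositionalCall(composition, resolved, math.inf, "trivial")

    intensities = {c: _chain_intensity(product_spectrum, c, tolerance) for c in distinct}
    missing = [str(c) for c, i in intensities.items() if math.isnan(i)]
    if missing:
        return PositionalCall(
            composition,
            None,
            math.nan,
            "ambiguous",
            note=f"missing carboxylate fragment for {', '.join(missing)}",
        )

    ranked = sorted(
        distinct, key=lambda c: (-intensities[c], -c.carbons, -c.double_bonds)
    )
    top, runner = ranked[0], ranked[1]
    ratio = intensities[top] / intensities[runner] if intensities[runner] else math.inf
    if ratio < ratio_threshold:
        return PositionalCall(
            composition, None, ratio, "ambiguous",
            note=f"top/runner-up ratio {ratio:.2f} below threshold {ratio_threshold}",
        )

    others = list(composition.chains)
    others.remove(top)  # removes one instance; duplicates of sn-2 chain may remain
    others.sort(key=lambda c: (-c.carbons, -c.double_bonds))
    if spec.n_acyl == 2:
        chains = (others[0], top)
    else:  # triacyl: sn-2 identified, sn-1/sn-3 in canonical order
        chains = (others[0], top, others[1])
    resolved = LipidSpecies(composition.class_id, chains, sn_resolved=True)
    return PositionalCall(composition, resolved, ratio, "resolved")
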