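"""Label-preserving time-series augmentation by amplitude rescaling.

Each pre-processed ROI trace is multiplied by every factor of the grid
0.5–4.5 in steps of 0.5 (nine factors), and the rescaled copies are pooled
with the originals for a ten-fold increase in data strength.  The grid is
kept exactly as printed even though it contains 1.0, whose copies duplicate
their original up to provenance.  Augmented traces are not re-normalized —
doing so would cancel the rescaling entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import AUGMENTED, Spectrum

DEFAULT_FACTORS = tuple(np.arange(0.5, 4.51, 0.5))


@dataclass(frozen=True)
class AugmentPlan:
    """Ordered rescaling factors applied to every spectrum."""

    factors: tuple[float, ...] = DEFAULT_FACTORS

    def __post_init__(self) -> None:
        if len(self.factors) == 0:
            raise ValueError("augmentation plan needs at least one factor")
        if any(f <= 0 for f in self.factors):
            raise ValueError("rescaling factors must be positive")


def rescale(spectrum: Spectrum, factor: float) -> Spectrum:
    """Multiply every sample by ``factor``; label and origin are preserved."""
    if factor <= 0:
        raise ValueError("rescaling factor must be positive")
    return spectrum.with_samples(
        spectrum.samples * factor,
        id=f"{spectrum.id}-x{factor:g}",
        origin_id=spectrum.origin_id,
        provenance=AUGMENTED,
        scale_factor=factor,
    )


def augment_set(spectra: list[Spectrum], plan: AugmentPlan | None = None) -> list[Spectrum]:
    """Pool the originals with every rescaled copy.

    Output size is ``len(spectra) * (1 + len(plan.factors))`` — 5000 for the
    default 500-spectrum study (9 augmented copies per original).
    """
    if len(spectra) == 0:
        raise ValueError("empty spectrum collection")
    plan = plan or AugmentPlan()
    out = list(spectra)
    for s in spectra:
        out.extend(rescale(s, f) for f in plan.factors)
    return out
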