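"""Core container for time-domain photoacoustic traces.

A :class:`Spectrum` is a single 1-D amplitude-vs-time recording together with
its class label (day of tumor progression), acquisition metadata (tissue,
position, replicate) and augmentation provenance.  All pipeline stages accept
and return lists of ``Spectrum`` objects so that metadata travels with the
samples untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

#: provenance tags
ORIGINAL = "original"
AUGMENTED = "augmented"


@dataclass
class Spectrum:
    """One time-domain photoacoustic trace with label and provenance.

    Parameters
    ----------
    samples
        Amplitudes (arbitrary units), one per sampling interval.
    sampling_rate
        Acquisition rate in Hz.
    label
        Class tag (e.g. ``"day10"``).
    id
        Unique identifier of this trace.
    origin_id
        Identifier of the original trace this one derives from.  For
        originals it equals ``id`` (filled in automatically when omitted).
    provenance
        ``"original"`` or ``"augmented"``.
    scale_factor
        Rescaling factor applied relative to the origin trace (1.0 for
        originals).
    start_time
        Time of the first sample, in seconds, relative to the trigger.
    """

    samples: np.ndarray
    sampling_rate: float
    label: str
    id: str
    origin_id: str | None = None
    tissue_id: int = 0
    position_id: int = 0
    replicate_id: int = 0
    provenance: str = ORIGINAL
    scale_factor: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size == 0:
            raise ValueError("spectrum must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.provenance not in (ORIGINAL, AUGMENTED):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.origin_id is None:
            self.origin_id = self.id
        if self.provenance == ORIGINAL:
            if self.scale_factor != 1.0:
                raise ValueError("original spectra must have scale_factor 1.0")
            if self.origin_id != self.id:
                raise ValueError("original spectra must be their own origin")

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record span in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (uniform grid from ``start_time``)."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    @property
    def energy(self) -> float:
        """Sum of squared amplitudes."""
        return float(np.sum(self.samples**2))

    # -- functional update --------------------------------------------------

    def replace(self, **changes) -> "Spectrum":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def with_samples(self, samples: np.ndarray, **changes) -> "Spectrum":
        """Return a copy carrying new sample values (metadata preserved)."""
        return dataclasses.replace(self, samples=np.asarray(samples, dtype=float), **changes)
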