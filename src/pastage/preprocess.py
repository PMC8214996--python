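"""Pre-processing chain and region-of-interest extraction.

The chain applies, in fixed order: linear detrending, polynomial baseline
correction, optional background subtraction, max-absolute normalization,
then extraction of the region of interest (ROI) — by default the 0.27–0.6 ms
window where spectral variation across progression groups is largest.

Index convention for the ROI: sample ``i`` is kept when
``round(start * rate) <= i < round(end * rate)`` (0-based, half-open,
round-half-away-from-zero), which at 2.6 MHz maps 0.27–0.6 ms to indices
702..1559 — 858 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum


@dataclass(frozen=True)
class ROIWindow:
    """Analysis window along the time axis, in seconds."""

    start: float = 0.27e-3
    end: float = 0.6e-3

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")


@dataclass(frozen=True)
class PreprocessOptions:
    """Which stages of the fixed chain to run.

    ``baseline_order`` is the polynomial order of the baseline fit (order 0
    removes the mean); ``background`` is an optional blank trace subtracted
    elementwise (off by default — the synthetic design has no blank).
    """

    detrend: bool = True
    baseline_order: int | None = 2
    background: Spectrum | None = None
    normalize: bool = True


def _fit_poly(y: np.ndarray, order: int) -> np.ndarray:
    x = np.arange(y.size, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(x, y, order)
    return np.polynomial.polynomial.polyval(x, coeffs)


def detrend(spectrum: Spectrum) -> Spectrum:
    """Subtract the least-squares straight line over sample index."""
    if spectrum.n_samples < 2:
        raise ValueError("detrending requires at least 2 samples")
    return spectrum.with_samples(spectrum.samples - _fit_poly(spectrum.samples, 1))


def correct_baseline(spectrum: Spectrum, poly_order: int = 2) -> Spectrum:
    """Subtract a least-squares polynomial baseline of the given order."""
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    if poly_order >= spectrum.n_samples:
        raise ValueError("poly_order must be smaller than the sample count")
    return spectrum.with_samples(spectrum.samples - _fit_poly(spectrum.samples, poly_order))


def subtract_background(spectrum: Spectrum, background: Spectrum) -> Spectrum:
    """Elementwise subtraction of a blank (background) trace."""
    if spectrum.n_samples != background.n_samples:
        raise ValueError("background length mismatch")
    if spectrum.sampling_rate != background.sampling_rate:
        raise ValueError("background sampling-rate mismatch")
    return spectrum.with_samples(spectrum.samples - background.samples)


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit maximum absolute amplitude (shape- and sign-preserving)."""
    peak = float(np.max(np.abs(spectrum.samples)))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return spectrum.with_samples(spectrum.samples / peak)


def roi_indices(roi: ROIWindow, sampling_rate: float) -> tuple[int, int]:
    """Half-open sample-index window of the ROI (round half away from zero)."""
    i0 = int(np.floor(roi.start * sampling_rate + 0.5))
    i1 = int(np.floor(roi.end * sampling_rate + 0.5))
    return i0, i1


def extract_roi(spectrum: Spectrum, roi: ROIWindow | None = None) -> Spectrum:
    """Slice out the ROI window; sample values are copied bit-identically."""
    roi = roi or ROIWindow()
    i0, i1 = roi_indices(roi, spectrum.sampling_rate)
    if i0 < 0 or i1 > spectrum.n_samples:
        raise ValueError("ROI lies outside the recorded span")
    if i1 <= i0:
        raise ValueError("ROI selects no samples")
    return spectrum.with_samples(spectrum.samples[i0:i1], start_time=roi.start)


def preprocess_spectrum(
    spectrum: Spectrum,
    roi: ROIWindow | None = None,
    options: PreprocessOptions | None = None,
) -> Spectrum:
    """Run the fixed chain detrend → baseline → background → normalize → ROI."""
    options = options or PreprocessOptions()
    s = spectrum
    if options.detrend:
        s = detrend(s)
    if options.baseline_order is not None:
        s = correct_baseline(s, options.baseline_order)
    if options.background is not None:
        s = subtract_background(s, options.background)
    if options.normalize:
        s = normalize(s)
    return extract_roi(s, roi)


def preprocess_set(
    spectra: list[Spectrum],
    roi: ROIWindow | None = None,
    options: PreprocessOptions | None = None,
) -> list[Spectrum]:
    """Apply :func:`preprocess_spectrum` to every trace, metadata preserved."""
    if len(spectra) == 0:
        raise ValueError("empty spectrum collection")
    return [preprocess_spectrum(s, roi, options) for s in spectra]
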