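"""Synthetic photoacoustic dataset generator.

The recorded spectra behind the original ex vivo staging study are not
publicly deposited, so this module generates labeled surrogate data with the
same design: five progression groups (day 0 control through day 20), five
tissues per group, four probe positions per tissue and five replicate traces
per position — 500 original spectra of 5200 samples at a 2.6 MHz sampling
rate.

Each trace is a sum of two exponentially damped sinusoids gated to onset
times inside the analysis window (0.27–0.6 ms), on top of a slow polynomial
baseline drift and additive white Gaussian noise.  Groups differ in both
overall amplitude (strictly increasing with day, mimicking growing
absorbers) and waveform shape (component frequencies and onsets), so class
information survives amplitude-rescaling augmentation.  Tissue- and
position-level log-normal random effects are shared by all traces nested
under them, reproducing the replicate structure of the acquisition.

All component frequencies sit below a quarter of the sampling rate, so
nearly all signal energy falls in the level-2 low-low wavelet-packet subband
("AA2") — the property the downstream feature extraction relies on.

The module also carries the study's caliper tumor-volume formula,
``V = width^2 * length / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum

DEFAULT_GROUP_LABELS = ("day0", "day5", "day10", "day15", "day20")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout and acquisition settings of the recording study."""

    n_groups: int = 5
    group_labels: tuple[str, ...] = DEFAULT_GROUP_LABELS
    n_tissues_per_group: int = 5
    n_positions_per_tissue: int = 4
    n_replicates_per_position: int = 5
    sampling_rate: float = 2.6e6
    record_duration: float = 2e-3

    def __post_init__(self) -> None:
        counts = (
            self.n_groups,
            self.n_tissues_per_group,
            self.n_positions_per_tissue,
            self.n_replicates_per_position,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        if len(self.group_labels) != self.n_groups:
            raise ValueError("group_labels length must equal n_groups")
        if len(set(self.group_labels)) != self.n_groups:
            raise ValueError("group labels must be unique")
        n = self.sampling_rate * self.record_duration
        if abs(n - round(n)) > 1e-6 or round(n) < 1:
            raise ValueError(
                "sampling_rate * record_duration must be a whole sample count"
            )

    @property
    def n_samples(self) -> int:
        """Samples per trace (5200 at defaults)."""
        return int(round(self.sampling_rate * self.record_duration))

    @property
    def n_spectra(self) -> int:
        """Total original spectra (500 at defaults)."""
        return (
            self.n_groups
            * self.n_tissues_per_group
            * self.n_positions_per_tissue
            * self.n_replicates_per_position
        )


@dataclass(frozen=True)
class ClassTemplate:
    """Waveform parameters of one progression group.

    ``frequencies`` (Hz), ``dampings`` (1/s), ``component_amplitudes``
    (relative, a.u.) and ``onsets`` (s) describe the damped-oscillation
    components; ``amplitude_scale`` multiplies the whole waveform and must
    increase strictly with day index across the default templates.
    ``drift`` are polynomial baseline coefficients over normalized time
    (constant first).  ``tissue_effect_sd`` / ``position_effect_sd`` are the
    standard deviations of log-normal amplitude random effects shared within
    a tissue / a position.
    """

    frequencies: tuple[float, ...]
    dampings: tuple[float, ...]
    component_amplitudes: tuple[float, ...]
    onsets: tuple[float, ...]
    amplitude_scale: float = 1.0
    noise_sd: float = 0.004
    drift: tuple[float, ...] = (0.03, -0.05, 0.025)
    tissue_effect_sd: float = 0.08
    position_effect_sd: float = 0.05

    def __post_init__(self) -> None:
        k = len(self.frequencies)
        if k < 1:
            raise ValueError("at least one oscillation component is required")
        if not (len(self.dampings) == len(self.component_amplitudes) == len(self.onsets) == k):
            raise ValueError("component parameter tuples must have equal length")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be positive")
        if any(d <= 0 for d in self.dampings):
            raise ValueError("dampings must be positive")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def default_templates(
    design: StudyDesign | None = None,
) -> dict[str, ClassTemplate]:
    """Per-group waveform templates emulating progressive tumor stages.

    Amplitude grows strictly with day (larger, more absorbing tumors give
    stronger pressure transients) while component frequencies and onsets
    shift upward, so groups differ in shape as well as scale.  All
    frequencies stay below ``sampling_rate / 4``.
    """
    design = design or StudyDesign()
    nyq4 = design.sampling_rate / 4.0
    specs = [
        # (freqs Hz, onsets s, amplitude scale); frequencies stay well inside
        # the level-2 low-low passband [0, fs/8] so db6's gradual roll-off
        # leaks almost nothing into the detail subbands
        ((45e3, 75e3), (0.29e-3, 0.40e-3), 0.60),
        ((58e3, 92e3), (0.30e-3, 0.42e-3), 0.85),
        ((72e3, 110e3), (0.31e-3, 0.44e-3), 1.15),
        ((87e3, 129e3), (0.32e-3, 0.46e-3), 1.50),
        ((103e3, 149e3), (0.33e-3, 0.48e-3), 1.90),
    ]
    templates: dict[str, ClassTemplate] = {}
    for label, (freqs, onsets, scale) in zip(design.group_labels, specs):
        assert all(f < nyq4 for f in freqs)
        templates[label] = ClassTemplate(
            frequencies=freqs,
            dampings=(4.5e4, 6.0e4),
            component_amplitudes=(1.0, 0.6),
            onsets=onsets,
            amplitude_scale=scale,
        )
    if len(templates) != design.n_groups:
        raise ValueError("no default templates beyond five groups")
    return templates


# -- seeding ---------------------------------------------------------------
#
# One master seed fans out to independent substreams through SeedSequence
# spawn keys: (0, g, t) for the tissue random effect, (1, g, t, p) for the
# position random effect and (2, g, t, p, r) for the per-trace stream (drift
# jitter, then noise).  Any subset of the design can therefore be regenerated
# bit-identically without generating the rest.

_TISSUE, _POSITION, _TRACE = 0, 1, 2


def _rng(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _waveform(template: ClassTemplate, t: np.ndarray) -> np.ndarray:
    """Noise-free gated damped-sinusoid mixture (unit amplitude scale)."""
    out = np.zeros_like(t)
    for f, d, a, t0 in zip(
        template.frequencies,
        template.dampings,
        template.component_amplitudes,
        template.onsets,
    ):
        u = t - t0
        live = u > 0
        x = d * u[live]
        # envelope peaks at 1 one time-constant after onset; starts C^1 at 0
        out[live] += a * x * np.exp(1.0 - x) * np.sin(2.0 * np.pi * f * u[live])
    return out


def generate_dataset(
    design: StudyDesign,
    templates: dict[str, ClassTemplate],
    seed: int,
) -> list[Spectrum]:
    """Generate all original spectra of the study design.

    Returns ``design.n_spectra`` traces, each ``design.n_samples`` long,
    ordered by (group, tissue, position, replicate).  A fixed seed gives
    bit-identical output.
    """
    missing = [g for g in design.group_labels if g not in templates]
    if missing:
        raise ValueError(f"missing template for group(s): {missing}")
    nyq4 = design.sampling_rate / 4.0
    for label in design.group_labels:
        if any(f >= nyq4 for f in templates[label].frequencies):
            raise ValueError(
                f"template {label!r} has components at or above sampling_rate/4"
            )

    t = np.arange(design.n_samples) / design.sampling_rate
    t_norm = t / design.record_duration
    spectra: list[Spectrum] = []
    for g, label in enumerate(design.group_labels):
        tpl = templates[label]
        clean = tpl.amplitude_scale * _waveform(tpl, t)
        drift_basis = np.polynomial.polynomial.polyval(t_norm, tpl.drift)
        for ti in range(design.n_tissues_per_group):
            z_tissue = _rng(seed, (_TISSUE, g, ti)).standard_normal()
            tissue_mult = float(np.exp(tpl.tissue_effect_sd * z_tissue))
            for pi in range(design.n_positions_per_tissue):
                z_pos = _rng(seed, (_POSITION, g, ti, pi)).standard_normal()
                pos_mult = float(np.exp(tpl.position_effect_sd * z_pos))
                for ri in range(design.n_replicates_per_position):
                    rng = _rng(seed, (_TRACE, g, ti, pi, ri))
                    drift_mult = rng.normal(1.0, 0.3)
                    samples = (
                        tissue_mult * pos_mult * clean
                        + drift_mult * drift_basis
                        + rng.normal(0.0, tpl.noise_sd, design.n_samples)
                    )
                    sid = f"{label}-t{ti}-p{pi}-r{ri}"
                    spectra.append(
                        Spectrum(
                            samples=samples,
                            sampling_rate=design.sampling_rate,
                            label=label,
                            id=sid,
                            tissue_id=ti,
                            position_id=pi,
                            replicate_id=ri,
                        )
                    )
    return spectra


def tumor_volume(width: float, length: float) -> float:
    """Caliper tumor volume ``width^2 * length / 2`` (mm^3 for mm inputs)."""
    if width < 0 or length < 0:
        raise ValueError("width and length must be nonnegative")
    return width**2 * length / 2.0
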