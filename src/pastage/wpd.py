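"""Wavelet packet decomposition (db6, level 2) and AA2 feature extraction.

A wavelet packet decomposition recursively splits both the approximation and
the detail branch with a two-channel filter bank, giving a full binary tree
of subbands.  With the orthogonal Daubechies-6 filters and periodized
boundaries the transform is orthonormal: total energy is preserved at every
level and the original trace is reconstructed exactly.

Periodization is only orthonormal when every level sees an even length, so
inputs are zero-padded up to the next multiple of ``2**level`` before
decomposing (the padding is recorded and trimmed again on reconstruction).
An 858-sample ROI trace therefore yields 215 coefficients per level-2 node.

Node labels use natural (filter-bank) order: ``(2, 0)`` is the low-low
"AA2" subband that carries essentially all energy of the band-limited
photoacoustic traces and supplies the classification features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .spectra import Spectrum

DEFAULT_WAVELET = "db6"
DEFAULT_LEVEL = 2
_MODE = "periodization"

#: metadata columns carried through every feature table
FEATURE_META_COLUMNS = [
    "id",
    "label",
    "origin_id",
    "provenance",
    "scale_factor",
    "tissue_id",
    "position_id",
    "replicate_id",
]


def _node_path(depth: int, index: int) -> str:
    """pywt path of node (depth, index) in natural order, e.g. (2,1) -> 'ad'."""
    bits = format(index, f"0{depth}b")
    return bits.replace("0", "a").replace("1", "d")


@dataclass
class WPDTree:
    """Full wavelet-packet tree of one signal down to ``level``."""

    wavelet: str
    level: int
    input_length: int
    nodes: dict[tuple[int, int], np.ndarray]
    boundary_mode: str = _MODE

    @property
    def padded_length(self) -> int:
        block = 2**self.level
        return -(-self.input_length // block) * block

    def leaf_nodes(self) -> list[tuple[int, int]]:
        return [(self.level, i) for i in range(2**self.level)]

    def node_energy(self, key: tuple[int, int]) -> float:
        return float(np.sum(self.nodes[key] ** 2))


def wpd_decompose(
    signal: np.ndarray | Spectrum,
    wavelet: str = DEFAULT_WAVELET,
    level: int = DEFAULT_LEVEL,
) -> WPDTree:
    """Decompose a 1-D signal into its full wavelet-packet tree.

    Coefficient counts halve at each level of the (zero-padded) chain; for a
    length-858 input at level 2 every leaf holds 215 coefficients.
    """
    if isinstance(signal, Spectrum):
        signal = signal.samples
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if level < 1:
        raise ValueError("level must be >= 1")
    filt_len = pywt.Wavelet(wavelet).dec_len
    if x.size < filt_len:
        raise ValueError(
            f"signal length {x.size} shorter than the {wavelet} filter ({filt_len})"
        )
    block = 2**level
    padded = -(-x.size // block) * block
    if padded != x.size:
        x = np.concatenate([x, np.zeros(padded - x.size)])
    wp = pywt.WaveletPacket(x, wavelet, mode=_MODE, maxlevel=level)
    nodes = {
        (d, i): np.asarray(wp[_node_path(d, i)].data, dtype=float)
        for d in range(1, level + 1)
        for i in range(2**d)
    }
    return WPDTree(wavelet=wavelet, level=level, input_length=int(signal.size), nodes=nodes)


def wpd_reconstruct(tree: WPDTree) -> np.ndarray:
    """Invert the decomposition from the deepest-level nodes.

    Exact to floating-point precision (the transform is orthonormal on the
    padded grid).
    """
    for key in tree.leaf_nodes():
        if key not in tree.nodes:
            raise ValueError(f"missing node {key}")
    wp = pywt.WaveletPacket(None, tree.wavelet, mode=_MODE, maxlevel=tree.level)
    for d, i in tree.leaf_nodes():
        wp[_node_path(d, i)] = tree.nodes[(d, i)]
    rec = wp.reconstruct(update=False)
    return np.asarray(rec[: tree.input_length], dtype=float)


@dataclass(frozen=True)
class EnergyDistribution:
    """Per-leaf-node fractions of total squared-coefficient energy."""

    fractions: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError("energy fractions must sum to 1")

    @property
    def aa2(self) -> float:
        """Fraction in the level-2 approximation-of-approximation node."""
        return self.fractions[(2, 0)]


def energy_distribution(tree: WPDTree) -> EnergyDistribution:
    """Energy fraction of each deepest-level node (sums to 1)."""
    energies = {key: tree.node_energy(key) for key in tree.leaf_nodes()}
    total = sum(energies.values())
    if total == 0.0:
        raise ValueError("energy fractions undefined for an all-zero signal")
    return EnergyDistribution({k: e / total for k, e in energies.items()})


def aa2_fraction(signal: np.ndarray | Spectrum, wavelet: str = DEFAULT_WAVELET) -> float:
    """Convenience: level-2 AA2 energy fraction of one signal."""
    return energy_distribution(wpd_decompose(signal, wavelet, DEFAULT_LEVEL)).fractions[(2, 0)]


def extract_aa2_features(
    spectra: list[Spectrum],
    wavelet: str = DEFAULT_WAVELET,
    level: int = DEFAULT_LEVEL,
) -> pd.DataFrame:
    """AA2 coefficients of every spectrum as a raw feature table.

    One row per spectrum; feature columns ``aa2_001 .. aa2_NNN`` hold the
    level-``level`` node-(``level``, 0) coefficients in filter-output order
    (215 columns for the default 858-sample ROI); metadata columns carry the
    label and provenance through to selection and classification.
    """
    if len(spectra) == 0:
        raise ValueError("empty spectrum collection")
    lengths = {s.n_samples for s in spectra}
    if len(lengths) != 1:
        raise ValueError(f"spectra have ragged lengths: {sorted(lengths)}")
    rows = [wpd_decompose(s, wavelet, level).nodes[(level, 0)] for s in spectra]
    coef = np.vstack(rows)
    width = len(str(coef.shape[1]))
    cols = [f"aa2_{i + 1:0{max(width, 3)}d}" for i in range(coef.shape[1])]
    meta = pd.DataFrame(
        {
            "id": [s.id for s in spectra],
            "label": [s.label for s in spectra],
            "origin_id": [s.origin_id for s in spectra],
            "provenance": [s.provenance for s in spectra],
            "scale_factor": [s.scale_factor for s in spectra],
            "tissue_id": [s.tissue_id for s in spectra],
            "position_id": [s.position_id for s in spectra],
            "replicate_id": [s.replicate_id for s in spectra],
        }
    )
    return pd.concat([meta, pd.DataFrame(coef, columns=cols)], axis=1)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the coefficient columns of a feature table."""
    return [c for c in table.columns if c.startswith("aa2_")]
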