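"""Minimal-Redundancy-Maximal-Relevance (mRMR) feature ranking.

mRMR greedily ranks features by mutual information (MI): the first pick
maximizes relevance MI(x; y) to the class labels, and every later pick
maximizes the difference between its relevance and its mean MI with the
features already selected (the MID "difference" scheme; the MIQ quotient
scheme is available as an option).  The criterion value at selection time is
recorded as the feature's importance score.

MI between a continuous feature and the labels (or another feature) is
estimated from the empirical joint frequency table after equal-frequency
(quantile) binning into ``ceil(sqrt(n))`` bins, capped at 256.  Quantile
binning is invariant under monotone amplitude scaling, which matters here
because rescaling augmentation spreads each feature over a 9-fold amplitude
range.

Ties in the greedy criterion are broken toward the lower coefficient index
so rankings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wpd import FEATURE_META_COLUMNS, feature_columns

MAX_BINS = 256


def _codes(values: np.ndarray) -> np.ndarray:
    """Integer codes of discrete values (labels or bin ids)."""
    _, codes = np.unique(np.asarray(values), return_inverse=True)
    return codes


def bin_feature(x: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Equal-frequency binning of a continuous feature into integer codes.

    Defaults to ``ceil(sqrt(n))`` bins capped at 256; duplicate quantile
    edges collapse, so constant features map to a single bin.
    """
    x = np.asarray(x, dtype=float)
    if n_bins is None:
        n_bins = min(int(np.ceil(np.sqrt(x.size))), MAX_BINS)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def discrete_mutual_information(cx: np.ndarray, cy: np.ndarray) -> float:
    """MI in nats of two discrete code vectors, from the joint count table."""
    cx = np.asarray(cx)
    cy = np.asarray(cy)
    if cx.shape != cy.shape:
        raise ValueError("length mismatch")
    cx = _codes(cx)
    cy = _codes(cy)
    nx, ny = cx.max() + 1, cy.max() + 1
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny).astype(float)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int | None = None,
    *,
    bin_y: bool = False,
) -> float:
    """MI in nats between a continuous feature and class labels.

    ``x`` is quantile-binned; ``y`` is treated as discrete labels unless
    ``bin_y`` is set (used for feature-feature redundancy terms).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("length mismatch between feature and labels")
    cy = bin_feature(np.asarray(y, dtype=float), n_bins) if bin_y else _codes(y)
    if not bin_y and len(np.unique(cy)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    return discrete_mutual_information(bin_feature(x, n_bins), cy)


@dataclass(frozen=True)
class MRMRRanking:
    """Greedy mRMR selection order with criterion scores.

    ``indices`` are 1-based positions within the AA2 coefficient vector
    (matching the ``aa2_NNN`` column numbering); ``scores`` are the greedy
    criterion values at selection time — the first is a plain relevance MI,
    later ones are relevance minus mean redundancy and may be negative.
    """

    columns: tuple[str, ...]
    indices: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len({*self.columns}) != len(self.columns):
            raise ValueError("ranking entries must be unique")
        if not all(np.isfinite(self.scores)):
            raise ValueError("ranking scores must be finite")

    def __len__(self) -> int:
        return len(self.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.columns) + 1),
                "column": self.columns,
                "coefficient_index": self.indices,
                "importance_score": self.scores,
            }
        )


def mrmr_rank(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series | None = None,
    k: int = 10,
    scheme: str = "difference",
    n_bins: int | None = None,
) -> MRMRRanking:
    """Rank the top ``k`` feature columns by the greedy mRMR criterion.

    ``table`` may be a full feature table (metadata plus ``aa2_*`` columns,
    labels taken from its ``label`` column) or a plain feature frame with
    ``labels`` given separately.
    """
    if scheme not in ("difference", "quotient"):
        raise ValueError("scheme must be 'difference' or 'quotient'")
    cols = feature_columns(table)
    if not cols:
        cols = [c for c in table.columns if c not in FEATURE_META_COLUMNS]
    if labels is None:
        if "label" not in table.columns:
            raise ValueError("labels not given and table has no 'label' column")
        labels = table["label"].to_numpy()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    if not 1 <= k <= len(cols):
        raise ValueError(f"k must be in 1..{len(cols)}")

    codes = {c: bin_feature(table[c].to_numpy(dtype=float), n_bins) for c in cols}
    cy = _codes(labels)
    relevance = {c: discrete_mutual_information(codes[c], cy) for c in cols}

    selected: list[str] = []
    scores: list[float] = []
    redundancy: dict[str, float] = {c: 0.0 for c in cols}  # running sums
    remaining = list(cols)
    while len(selected) < k:
        if selected:
            last = selected[-1]
            for c in remaining:
                redundancy[c] += discrete_mutual_information(codes[c], codes[last])
        best_c, best_v = None, -np.inf
        for c in remaining:  # original column order => lowest index wins ties
            if selected:
                mean_red = redundancy[c] / len(selected)
                v = (
                    relevance[c] - mean_red
                    if scheme == "difference"
                    else relevance[c] / max(mean_red, np.finfo(float).tiny)
                )
            else:
                v = relevance[c]
            if v > best_v:
                best_c, best_v = c, v
        selected.append(best_c)
        scores.append(best_v)
        remaining.remove(best_c)

    indices = tuple(cols.index(c) + 1 for c in selected)
    return MRMRRanking(columns=tuple(selected), indices=indices, scores=tuple(scores))


def build_feature_matrix(table: pd.DataFrame, ranking: MRMRRanking, k: int = 10) -> pd.DataFrame:
    """Subset a feature table to the top-``k`` ranked columns, in rank order.

    Metadata columns (label, origin id, provenance, ...) are retained, so
    the result is the input matrix for SVM training — 5000 rows by 10
    features at study defaults.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking):
        raise ValueError("ranking holds fewer entries than k")
    keep = list(ranking.columns[:k])
    missing = [c for c in keep if c not in table.columns]
    if missing:
        raise ValueError(f"ranking refers to absent columns: {missing}")
    meta = [c for c in FEATURE_META_COLUMNS if c in table.columns]
    return table[meta + keep].copy()
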