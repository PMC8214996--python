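"""CSV/JSON readers and writers for pipeline artifacts.

Spectra travel as one CSV row per trace: the metadata columns
``id, label, tissue_id, position_id, replicate_id, provenance,
scale_factor, origin_id, sampling_rate, start_time`` followed by the sample
columns ``s000000, s000001, ...``.  Write followed by read is the identity
on values and metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mrmr import MRMRRanking
from .spectra import Spectrum
from .svm_eval import EvaluationReport, RepeatedHoldoutResult

SPECTRA_META_COLUMNS = [
    "id",
    "label",
    "tissue_id",
    "position_id",
    "replicate_id",
    "provenance",
    "scale_factor",
    "origin_id",
    "sampling_rate",
    "start_time",
]


def write_spectra_csv(spectra: list[Spectrum], path: str | Path) -> None:
    """Write a spectrum collection as a rectangular CSV."""
    if len(spectra) == 0:
        raise ValueError("empty spectrum collection")
    lengths = {s.n_samples for s in spectra}
    if len(lengths) != 1:
        raise ValueError(f"spectra have ragged lengths: {sorted(lengths)}")
    n = lengths.pop()
    sample_cols = [f"s{i:06d}" for i in range(n)]
    meta = {
        "id": [s.id for s in spectra],
        "label": [s.label for s in spectra],
        "tissue_id": [s.tissue_id for s in spectra],
        "position_id": [s.position_id for s in spectra],
        "replicate_id": [s.replicate_id for s in spectra],
        "provenance": [s.provenance for s in spectra],
        "scale_factor": [s.scale_factor for s in spectra],
        "origin_id": [s.origin_id for s in spectra],
        "sampling_rate": [s.sampling_rate for s in spectra],
        "start_time": [s.start_time for s in spectra],
    }
    df = pd.concat(
        [pd.DataFrame(meta), pd.DataFrame(np.vstack([s.samples for s in spectra]), columns=sample_cols)],
        axis=1,
    )
    # %.17g + round_trip parsing make write/read the identity on doubles
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Read a spectrum collection written by :func:`write_spectra_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SPECTRA_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra CSV missing required columns: {missing}")
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    if not sample_cols:
        raise ValueError("spectra CSV has no sample columns")
    samples = df[sample_cols].to_numpy()
    if not np.all(np.isfinite(samples.astype(float, copy=False))):
        raise ValueError("spectra CSV has non-numeric or ragged sample rows")
    return [
        Spectrum(
            samples=samples[i],
            sampling_rate=float(row.sampling_rate),
            label=str(row.label),
            id=str(row.id),
            origin_id=str(row.origin_id),
            tissue_id=int(row.tissue_id),
            position_id=int(row.position_id),
            replicate_id=int(row.replicate_id),
            provenance=str(row.provenance),
            scale_factor=float(row.scale_factor),
            start_time=float(row.start_time),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ranking_csv(ranking: MRMRRanking, path: str | Path) -> None:
    ranking.to_frame().to_csv(path, index=False)


def read_ranking_csv(path: str | Path) -> MRMRRanking:
    df = pd.read_csv(path)
    return MRMRRanking(
        columns=tuple(df["column"]),
        indices=tuple(int(i) for i in df["coefficient_index"]),
        scores=tuple(float(s) for s in df["importance_score"]),
    )


def write_reports_json(result: RepeatedHoldoutResult, path: str | Path) -> None:
    payload = {
        "reports": {k: [r.to_dict() for r in v] for k, v in result.reports.items()},
        "best": {k: r.to_dict() for k, r in result.best_reports.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_reports_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def report_from_dict(d: dict) -> EvaluationReport:
    return EvaluationReport(
        kernel=d["kernel"],
        split_seed=d["split_seed"],
        classes=tuple(d["classes"]),
        confusion=np.asarray(d["confusion"], dtype=int),
        sensitivity=d["sensitivity"],
        specificity=d["specificity"],
        accuracy=d["accuracy"],
        undefined_sensitivity=tuple(d.get("undefined_sensitivity", ())),
    )
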