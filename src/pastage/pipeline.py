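"""End-to-end pipeline orchestration from a single configuration.

``run_pipeline`` chains generate → preprocess/ROI → augment → wavelet-packet
features → mRMR selection → repeated SVM hold-out, writes every tabular
artifact under an output directory and records a manifest (configuration,
derived seeds, library versions, stage counts) so a rerun with the same
configuration and seed reproduces the artifacts byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .augment import AugmentPlan, augment_set
from .io import (
    write_feature_table,
    write_ranking_csv,
    write_reports_json,
    write_spectra_csv,
)
from .mrmr import build_feature_matrix, mrmr_rank
from .preprocess import PreprocessOptions, ROIWindow, preprocess_set
from .svm_eval import (
    KERNELS,
    RepeatedHoldoutResult,
    SVMHyperparameters,
    repeated_holdout,
    split_seed_for_repeat,
)
from .synth import ClassTemplate, StudyDesign, default_templates, generate_dataset
from .wpd import DEFAULT_LEVEL, DEFAULT_WAVELET, extract_aa2_features, feature_columns

log = logging.getLogger("pastage")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, with study-protocol defaults.

    Defaults reproduce the study conditions: 2.6 MHz sampling, 0.27–0.6 ms
    ROI, rescaling factors 0.5–4.5 step 0.5, db6 level-2 decomposition,
    top-10 mRMR features, 80/20 stratified splits repeated 10 times.
    """

    design: StudyDesign = field(default_factory=StudyDesign)
    templates: dict[str, ClassTemplate] | None = None
    roi: ROIWindow = field(default_factory=ROIWindow)
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    augment: AugmentPlan = field(default_factory=AugmentPlan)
    wavelet: str = DEFAULT_WAVELET
    level: int = DEFAULT_LEVEL
    mrmr_k: int = 10
    mrmr_scheme: str = "difference"
    kernels: tuple[str, ...] = KERNELS
    hyperparameters: SVMHyperparameters = field(default_factory=SVMHyperparameters)
    train_fraction: float = 0.8
    n_repeats: int = 10
    split_policy: str = "rowwise"
    seed: int = 0
    save_spectra: bool = True

    def resolved_templates(self) -> dict[str, ClassTemplate]:
        return self.templates if self.templates is not None else default_templates(self.design)

    def to_dict(self) -> dict:
        d = {
            "design": dataclasses.asdict(self.design),
            "templates": {
                k: dataclasses.asdict(v) for k, v in self.resolved_templates().items()
            },
            "roi": dataclasses.asdict(self.roi),
            "preprocess": {
                "detrend": self.preprocess.detrend,
                "baseline_order": self.preprocess.baseline_order,
                "background": self.preprocess.background is not None,
                "normalize": self.preprocess.normalize,
            },
            "augment": {"factors": list(self.augment.factors)},
            "wavelet": self.wavelet,
            "level": self.level,
            "mrmr_k": self.mrmr_k,
            "mrmr_scheme": self.mrmr_scheme,
            "kernels": list(self.kernels),
            "hyperparameters": dataclasses.asdict(self.hyperparameters),
            "train_fraction": self.train_fraction,
            "n_repeats": self.n_repeats,
            "split_policy": self.split_policy,
            "seed": self.seed,
            "save_spectra": self.save_spectra,
        }
        return d


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a configuration from a (YAML-loaded) plain dictionary.

    Recognized sections mirror :class:`PipelineConfig`; ``roi`` accepts
    ``start_ms``/``end_ms`` in milliseconds.  Waveform templates are code-
    level objects and are not settable from YAML.
    """
    cfg = PipelineConfig()
    if "design" in d:
        cfg.design = StudyDesign(**{**dataclasses.asdict(cfg.design), **d["design"]})
    if "roi" in d:
        roi = d["roi"]
        start = roi.get("start_ms", cfg.roi.start * 1e3) * 1e-3
        end = roi.get("end_ms", cfg.roi.end * 1e3) * 1e-3
        cfg.roi = ROIWindow(start=start, end=end)
    if "preprocess" in d:
        p = d["preprocess"]
        cfg.preprocess = PreprocessOptions(
            detrend=p.get("detrend", True),
            baseline_order=p.get("baseline_order", 2),
            normalize=p.get("normalize", True),
        )
    if "augment" in d:
        cfg.augment = AugmentPlan(factors=tuple(d["augment"]["factors"]))
    if "hyperparameters" in d:
        cfg.hyperparameters = SVMHyperparameters(**d["hyperparameters"])
    for key in (
        "wavelet",
        "level",
        "mrmr_k",
        "mrmr_scheme",
        "train_fraction",
        "n_repeats",
        "split_policy",
        "seed",
        "save_spectra",
    ):
        if key in d:
            setattr(cfg, key, d[key])
    if "kernels" in d:
        cfg.kernels = tuple(d["kernels"])
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write artifacts plus a manifest to ``outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = _stage("synthesize")
    originals = generate_dataset(config.design, config.resolved_templates(), config.seed)
    timings["synthesize"] = time.perf_counter() - t0

    t0 = _stage("preprocess")
    roi_spectra = preprocess_set(originals, config.roi, config.preprocess)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = _stage("augment")
    augmented = augment_set(roi_spectra, config.augment)
    timings["augment"] = time.perf_counter() - t0
    if config.save_spectra:
        write_spectra_csv(augmented, outdir / "spectra_roi.csv")

    t0 = _stage("wavelet features")
    features = extract_aa2_features(augmented, config.wavelet, config.level)
    timings["features"] = time.perf_counter() - t0
    if config.save_spectra:
        write_feature_table(features, outdir / "features_aa2.csv")

    t0 = _stage("mRMR selection")
    ranking = mrmr_rank(features, k=config.mrmr_k, scheme=config.mrmr_scheme)
    matrix = build_feature_matrix(features, ranking, config.mrmr_k)
    timings["mrmr"] = time.perf_counter() - t0
    write_ranking_csv(ranking, outdir / "mrmr_ranking.csv")
    write_feature_table(matrix, outdir / "feature_matrix.csv")

    t0 = _stage("SVM evaluation")
    result = repeated_holdout(
        matrix,
        kernels=config.kernels,
        n_repeats=config.n_repeats,
        master_seed=config.seed,
        train_fraction=config.train_fraction,
        policy=config.split_policy,
        hyperparameters=config.hyperparameters,
    )
    timings["svm"] = time.perf_counter() - t0
    write_reports_json(result, outdir / "reports.json")
    result.summary_frame().to_csv(outdir / "summary.csv", index=False)

    manifest = {
        "pastage_version": __version__,
        "library_versions": _library_versions(),
        "config": config.to_dict(),
        "derived_split_seeds": [
            split_seed_for_repeat(config.seed, r) for r in range(config.n_repeats)
        ],
        "counts": {
            "n_original": len(originals),
            "n_total": len(augmented),
            "roi_length": roi_spectra[0].n_samples,
            "n_raw_features": len(feature_columns(features)),
            "n_selected_features": config.mrmr_k,
            "n_reports": result.n_reports,
        },
        "selected_features": list(ranking.columns[: config.mrmr_k]),
        "best_accuracy_pct": {k: r.accuracy for k, r in result.best_reports.items()},
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _library_versions() -> dict[str, str]:
    import pywt
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "pywavelets": pywt.__version__,
        "scikit-learn": sklearn.__version__,
    }
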