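# pastage

Staging breast-tumor progression from ex vivo photoacoustic spectroscopy
with machine learning: a tested, reusable implementation of the full
classification pipeline, driven by a synthetic-spectrum generator that
emulates the original study design (the recorded spectra are available only
on request, so no public accession exists).

Photoacoustic spectroscopy records the ultrasonic pressure transient a
tissue emits after pulsed-laser excitation as a 1-D time-domain trace. In
the emulated study, traces from tumor xenografts at five progression time
points (day 0 control, days 5/10/15/20 post-induction; 100 traces per
group, 2.6 MHz sampling, 2 ms records) are classified back to their time
point. The pipeline is:

1. **Pre-processing** — detrend, polynomial baseline correction, optional
   background subtraction, max-absolute normalization; then extraction of
   the 0.27–0.6 ms region of interest (858 samples) where spectral
   variation across groups is largest.
2. **Augmentation** — label-preserving amplitude rescaling by factors
   0.5–4.5 in steps of 0.5, pooling the 9 rescaled copies with each
   original for a 10-fold increase in data strength (500 → 5000 spectra).
3. **Feature extraction** — level-2 wavelet packet decomposition (WPD) with
   the Daubechies-6 mother wavelet. The transform is orthonormal: energy is
   conserved at every level and reconstruction is exact. Nearly all signal
   energy (> 99.2% per group) falls in the level-2 approximation node
   AA2 = (2, 0), whose 215 coefficients per trace form the raw features.
4. **Feature selection** — minimal-Redundancy-Maximal-Relevance (mRMR):
   greedy ranking by mutual information I(x; y) with the class, penalized
   by mean mutual information with already-selected features (difference
   scheme). The top 10 coefficients form the 5000 × 10 feature matrix.
5. **Classification** — one-vs-one multi-class SVM with RBF, polynomial and
   linear kernels on standardized features; each binary subproblem scores a
   sample by f(x) = Σⱼ αⱼ yⱼ G(x, xⱼ) + b. Stratified 80/20 hold-out
   repeated 10 times; per-class sensitivity, one-vs-rest specificity and
   overall accuracy are reported from the confusion matrix, and the
   best-accuracy model per kernel is kept.

Two split policies are provided: `rowwise` splits rows independently (so
rescaled copies of one trace can land on both sides — the protocol implied
by augmenting before splitting) and `grouped` keeps each origin family
together (leakage-free). Both are reported.

## Worked example

The numbered scripts under `analysis/` run the stages in order
(`python analysis/01_simulate.py`, then 02…06), chaining bulky
intermediates through `scratch/` and writing summary tables to `results/`.
The same stages are available as a CLI (`pastage run-all --out rundir
--seed 1`) or as library calls:

```python
from pastage import (StudyDesign, default_templates, generate_dataset,
                     preprocess_set, augment_set, extract_aa2_features,
                     mrmr_rank, build_feature_matrix, repeated_holdout)

design = StudyDesign()                    # 5 groups x 5 tissues x 4 positions x 5 replicates
spectra = generate_dataset(design, default_templates(design), seed=1)
table = extract_aa2_features(augment_set(preprocess_set(spectra)))
matrix = build_feature_matrix(table, mrmr_rank(table, k=10), 10)
result = repeated_holdout(matrix, n_repeats=10, master_seed=1)
print({k: r.accuracy for k, r in result.best_reports.items()})
```

Output of the analysis run at seed 1:

```
AA2 energy fraction per group (% of level-2 energy):
         mean     min
day0   99.959  99.946
day5   99.979  99.964
day10  99.987  99.983
day15  99.986  99.982
day20  99.968  99.965

best test accuracy over 10 repeats (%):
  rowwise  rbf 100.0, polynomial 100.0, linear 100.0
  grouped  rbf 100.0, polynomial 100.0, linear 100.0
```

The AA2 table confirms the band-concentration property the feature
extraction relies on: the synthetic templates are band-limited, so the
level-2 approximation node captures > 99.9% of each group's ROI energy.
The accuracies show that with the default well-separated class templates
(groups differ in amplitude and waveform shape) all three kernels stage the
synthetic spectra essentially perfectly, while label-permuted controls stay
at the 20% chance level (see `tests/test_acceptance.py`).

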