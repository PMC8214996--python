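# Methods

## The synthetic study and what it emulates

The package analyses time-domain photoacoustic traces labeled by tumor
progression day. Because the recorded dataset behind the original study is
not publicly deposited, `pastage.synth` generates a surrogate with the same
factorial design: 5 groups (day0 … day20) × 5 tissues × 4 positions × 5
replicates = 500 traces, each 5200 samples at 2.6 MHz (2 ms records).

Each trace is

    x(t) = m_tissue · m_position · A_g · Σ_k a_k · e_k(t − t0_k) · sin(2π f_k (t − t0_k))
           + c(t) + ε(t)

with envelope `e_k(u) = d_k u · exp(1 − d_k u)` for `u > 0` (continuous
onset, peak one damping time-constant after `t0_k`), a slow quadratic
baseline `c(t)` with a per-trace N(1, 0.3) amplitude jitter, and white
Gaussian noise ε. The group templates differ in:

| parameter | day0 → day20 | rationale |
|---|---|---|
| amplitude scale `A_g` | 0.60, 0.85, 1.15, 1.50, 1.90 | strictly increasing: larger absorbing tumors give stronger transients |
| component frequencies | (45, 75) → (103, 149) kHz | shape drift that survives rescaling augmentation |
| onsets | 0.29/0.40 → 0.33/0.48 ms | all inside the 0.27–0.6 ms analysis window |
| dampings | 4.5·10⁴, 6.0·10⁴ s⁻¹ (all groups) | ring-down of ~100 µs, contained in the window |
| noise sd | 0.004 (all groups) | keeps > 99% of raw energy below fs/4 even for the weakest (day0) traces |

Tissue- and position-level random effects are log-normal amplitude
multipliers (sd 0.08 and 0.05) shared by everything nested under them,
mirroring the replicate structure of the acquisition.

All component frequencies sit well inside the level-2 low-low subband
[0, fs/8] = [0, 325 kHz]. The nominal constraint is only that they stay
below fs/4, but the db6 filters roll off gradually, so placing them below
~0.5 · fs/8 is what actually keeps the AA2 energy fraction above 99.2% for
every group.

Seeding: one master seed fans out through `numpy` `SeedSequence` spawn keys
— `(0, g, t)` tissue effects, `(1, g, t, p)` position effects,
`(2, g, t, p, r)` per-trace streams, `(3, r)` per-repeat split seeds — so
any subset of the design is reproducible without generating the rest.

What the generator does **not** emulate: physical acoustics (optical
absorption, Grüneisen parameter, transducer response), instrument drift
across sessions, inter-animal biological variability beyond a scalar
amplitude effect, or any spectral signature of real tumor biochemistry.
Passing tests therefore demonstrate that the pipeline machinery is correct
and recovers planted class structure — not that real tumor stages are
separable at these accuracies.

## Pre-processing

The named stages run in a fixed order: linear detrend → polynomial baseline
correction (default order 2; order 0 is mean removal) → optional background
subtraction (off by default; the synthetic design has no blank trace) →
max-absolute normalization → ROI slice. Normalization precedes ROI
extraction so the window inherits the full-record scale; max-absolute
scaling preserves waveform shape and sign. ROI indices use a 0-based
half-open window with round-half-away-from-zero boundaries:
0.27–0.6 ms at 2.6 MHz → samples 702..1559, length 858.

## Augmentation

Amplitude rescaling by the grid 0.5–4.5 step 0.5 (nine factors, including
1.0, which duplicates its original up to provenance — the grid is kept as
specified). Augmented traces are not re-normalized, which would cancel the
rescaling. Augmentation happens after pre-processing/ROI and before any
split; the evaluation stage therefore offers both the row-wise (`rowwise`)
and the family-wise (`grouped`) split policy, and the tests document that
row-wise splitting lets the model exploit rescaled siblings (leakage).

## Wavelet packet decomposition

Full binary tree to level 2 with db6, periodized boundaries, natural
(filter-bank) node order; AA2 ≡ node (2, 0). Periodization is orthonormal
only for even lengths, so inputs are zero-padded to the next multiple of
2^level before decomposing; the padding is recorded and trimmed on
reconstruction. Consequences: level-2 nodes of an 858-sample ROI trace hold
215 coefficients; the sum of squared level-2 coefficients equals the input
energy to < 1e-9 relative error; reconstruction from the leaves is exact to
float precision. The per-node convention was cross-checked against an
explicit circular-convolution filter bank (`c[k] = Σ_m f[m] x[(2k + L/2 −
m) mod N]`).

"Coefficient index" in rankings means the 1-based position within the AA2
vector (columns `aa2_001 … aa2_215`).

## mRMR

Mutual information is estimated from empirical joint frequencies after
equal-frequency (quantile) binning of continuous features into ⌈√n⌉ bins,
capped at 256; labels are used as-is. Quantile binning is invariant under
monotone transformations, which makes the estimator robust to the 9-fold
amplitude spread injected by augmentation. Selection is greedy: the first
feature maximizes relevance I(x; y); each later feature maximizes
relevance − mean MI with the already-selected set (MID difference scheme;
the quotient scheme is config-switchable). The recorded importance score is
the criterion value at selection time — scores after the first can be
negative when redundancy dominates, and are comparable in ordering
semantics only. Ties break toward the lower coefficient index.

## SVM and evaluation

Features are standardized with train-split statistics, then fit with
scikit-learn `SVC` in one-vs-one mode. Defaults (the study names only the
kernels): C = 1; RBF γ = 1/(d · Var); polynomial degree 3, offset 1.
`decision_score` re-evaluates f(x) = Σ αⱼ yⱼ G(x, xⱼ) + b per class pair
directly from the fitted dual coefficients and matches
`SVC.decision_function` to float precision; the same primitive scores
hand-set models in the tests.

Evaluation: stratified 80/20 hold-out (per-class proportions within ±1
row), repeated 10 times with per-repeat seeds shared across kernels so
kernel comparisons are paired; "best" is the highest test accuracy.
Sensitivity(c) = TP/(TP+FN), specificity(c) = TN/(TN+FP) one-vs-rest,
accuracy = trace/total, all in percent. A class absent from a test
partition yields NaN sensitivity and is flagged, not dropped.

## Problem sizes in tests and analysis

The analysis scripts and the acceptance checks run the full default study
(500 → 5000 spectra, 215 → 10 features); the staging-recovery check
averages over 5 master seeds with 10 repeats each. Unit and property tests
use reduced factorial designs (e.g. 2×2×2 tissues/positions/replicates) and
short signals (lengths 16–858) chosen so each property is still exercised
end to end. The white-noise equipartition check averages 10⁴ draws of
length 64.

## Known limitations

- The generator's waveform family is a stated assumption, not a fit to
  recorded spectra; published accuracies and importance scores from
  recorded data are data-dependent and are not reproduction targets.
- The MI estimator's binning bias (~(bins−1)(classes−1)/2n nats) makes tiny
  scores at small n noisy; rankings, not score magnitudes, are the output.
- With the default well-separated templates all kernels saturate near 100%
  accuracy; kernel differences reported in the original study are not
  expected to reappear on synthetic data.
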