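# Methods

`avmvpa` re-implements, as a tested pipeline on synthetic data, a
multivariate analysis of how feature-selective attention modulates
audiovisual semantic integration: subjects view/hear dynamic facial
stimuli carrying two binary semantic features (gender: male/female;
emotion: crying/laughing) under three stimulus conditions (visual-only V,
auditory-only A, audiovisual AV) while performing one of four attention
tasks (number = no face feature attended, gender, emotion, or bi-feature =
both attended). This note documents the generative model, the analysis
statistics, the numerical choices, and what the synthetic experiments do
and do not establish.

## Experimental design

One run is 1,350 s at TR = 2 s (675 volumes): a 10 s pre-stimulation
baseline, then 10 blocks, each a 4 s instruction followed by eight 14 s
trials (stimulation during the first 8 s, then a blank), with 20 s blanks
between blocks — 80 trials per run. Stimulus assignment is a seeded
permutation with exactly two stimuli of each (gender, emotion) joint
category per block, which implies the 4/4 marginal balance of both
features within every block and fixes the 80-stimulus label multiset
across seeds (a 20/20/20/20 clip pool). The incongruent-AV control
(gender and emotion tasks only) reuses the congruent timeline;
incongruence acts purely through the generative gains below.

## Generative model

The phantom is a 24×24×12 voxel ellipsoid "brain" (≈2,800 masked voxels)
containing disjoint compact ROIs: two 30-voxel clusters per semantic
feature and four 62-voxel heteromodal clusters (left/right pSTS-MTG and
perirhinal analogues). Per phantom (shared by all subjects and runs) each
masked voxel draws a log-normal evoked-amplitude multiplier
(`evoked_sigma` = 0.3), and each feature-ROI voxel draws a ±1 contrast
sign — the spatial pattern that distinguishes the two categories.

A run's noiseless signal at voxel v is

    s_v(t) = a·e_v·h_v · B(t) + ½·c·g_f·σ_v · S_f(t)        (feature ROIs)

where `B` is the stimulation boxcar convolved with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6, sampled at TR;
taken from nilearn), `S_f` the same with per-trial ±1 category signs,
`a` = `base_amplitude` (default 1.5), `e_v` the evoked multiplier,
`c` = `class_contrast` (default 0.2), and σ_v the contrast sign.
`h_v` = `heteromodal_sensory_gain` (1.5) for heteromodal voxels in AV
runs with ≥1 attended feature, else 1 — so the heteromodal AV response
exceeds max(A, V) exactly when some face feature is attended (the
max-criterion direction). The contrast gain is

    g_f = 1                                  (feature f unattended)
        = attention_gain (1.5)               (attended, V / A / incongruent AV)
        = attention_gain · av_congruent_gain (attended, congruent AV; 1.5·1.4)

Noise is voxel-local AR(1) Gaussian (marginal sd `noise_sigma` = 1,
lag-1 correlation `ar1_rho` = 0.3) plus a spatially common AR(1)
fluctuation shared by all voxels (`global_noise_sigma` = 0.5), standing
in for physiological and scanner-wide signals. Directed connectivity is
planted by injecting the standardized heteromodal *local* ongoing
fluctuation (the realized heteromodal noise mean, which is neither
stimulus-locked nor global) at a lag of one TR into the voxels of each
attended feature's ROIs with coefficient `coupling_strength` (0.8,
relative to the voxel noise scale). A scanner baseline of 100 a.u. is
added, and subjects scale all signal amplitudes by a log-normal jitter
(sd `subject_sigma` = 0.1).

Effect-size calibration: the attentional and heteromodal gains (1.5, 1.4,
1.5) and the coupling coefficient (0.8) are the model's fixed defaults;
`base_amplitude` and `class_contrast` were calibrated once so the
synthetic data operates in the regime the method presupposes — evoked
responses of a few percent signal change (the pipeline measures ≈3–7 %
in heteromodal ROIs), between-class pattern cosines solidly positive,
reproducibility ratios of order 1–2.5, and above-chance but non-trivial
single-trial decodability. With much larger contrasts the between-class
cosine turns negative on informative voxel sets and the ratio statistic
leaves its meaningful (positive-denominator) domain.

## Preprocessing

The five pre-equilibrium volumes (the 10 s baseline) are discarded and
onsets re-referenced; each voxel is linearly detrended over the run and
z-scored (mean 0, variance 1) within each block's time span; constant
voxels are zeroed and flagged (variance guard ε = 1e-12). Trial patterns
are the mean of the last four volumes of each 14 s trial (the 6th–14th
second window, volumes 3–6 of the trial 0-based, accounting for the
hemodynamic delay). Cross-validation folds are the 10 design blocks,
which automatically gives 10 non-overlapping 8-trial folds balanced 4/4
in both label dimensions, with 72 training trials per fold.

## MVPA statistics

**Searchlight Fisher selection.** The searchlight radius is √2 voxel
units: the center, its 6 face and 12 edge neighbours — 19 voxels,
truncated at the mask edge. Per center, the Fisher discriminant ratio of
the two categories is computed from the training trials as the quadratic
form J = Δᵀ(S_W + λI)⁻¹Δ with Δ the class-mean difference and S_W the
pooled within-class covariance of the neighbourhood; this equals the
textbook (wᵀS_B w)/(wᵀS_W w) along the Fisher direction up to the ridge.
Numerically, S_W = S_T − γΔΔᵀ (S_T the label-free total scatter,
γ = n₁n₂/n), so with A = S_T/(n−2) + λI a Sherman–Morrison identity gives
J = u/(1 − αu), u = ΔᵀA⁻¹Δ. A is inverted once per fold and reused
across the label permutations of the localization step, which is what
makes 200–1,000 permutations feasible on one CPU. The ridge is
λ = 1e-6·tr(S_T/(n−2))/p (+1e-12): defining it on the total rather than
the within-class trace keeps it label-free (the difference is O(1e-6));
all-constant neighbourhoods get J = 0 and a degeneracy flag. The K
highest-J voxels are selected (K = 1500 at full scale; ties broken by
lexicographic voxel coordinate for determinism).

**Reproducibility ratio.** On a held-out fold (8 trials, 4 per class),
the reproducibility index of a trial pair is the cosine of the angle
between the two pattern vectors; r_within averages the 12 same-class
pairs (6 per class), r_between the 16 cross-class pairs, and the ratio
is R = r_within / r_between (a difference form r_within − r_between is
available via `form="difference"`). A fold with |r_between| < 0.05 is
flagged undefined and excluded from the fold average with a warning:
0.05 is the sampling-noise scale of a 16-pair mean cosine, below which
the ratio is arbitrarily large and meaningless.

**Decoding.** A linear SVM (C = 1, no class weighting — classes are
balanced by design) is trained on the 72 training trials at the selected
voxels and scored on the 8 held-out trials; per-fold weight maps keep
zeros at unselected voxels.

Voxel selection and SVM training always happen inside the fold loop; a
deliberate `selection_scope="all"` leak mode exists only so tests can
demonstrate the accuracy inflation it causes.

## Localization and cross-reproducibility

Per-fold SVM weight maps are averaged across all folds and subjects into
a group map. Each fold map is first scaled to unit L2 norm: the SVM
weight norm is inversely tied to the margin, so poorly separable
(label-permuted) fits would otherwise dominate the average purely
through scale. Magnitudes (|w|) are averaged by default for a
sign-invariant importance measure; a signed mode exists. The
family-wise-error threshold is the nearest-rank 95th percentile
(index ⌈0.95·n⌉ of the sorted list) of the max-voxel weights of 1,000
(200 at desk scale) group maps built from balanced within-fold label
permutations, drawn independently per subject. Suprathreshold voxels are
reported as 26-connected clusters with size and center of mass.
Cross-reproducibility evaluates the fold-wise ratio on an externally
fixed voxel set (no per-fold selection), testing whether a set localized
from the bi-feature AV runs generalizes to the number/gender/emotion AV
runs.

## Connectivity

ROI time series are voxel means of the preprocessed runs. Because every
voxel responds to the stimulation and shares the global fluctuation, each
ROI series is residualized — separately within every block and
inter-block segment, since block z-scoring rescales segments differently
— against the HRF-convolved stimulation regressor, the global mean
series (global-signal regression), and an intercept. Without this step
the shared deterministic response masquerades as bidirectional Granger
causality in every task. Granger tests fit a bivariate VAR with order
selected by BIC up to 3 (lags beyond 6 s at TR 2 s are hemodynamically
implausible), comparing full vs own-lags-only models with an F-test per
direction; an augmented Dickey–Fuller unit-root flag marks unreliable
pairs. Group-level p-values combine subjects by Fisher's method, and
Benjamini–Hochberg FDR at 0.05 is applied across all directed
(heteromodal × informative-cluster × 2) pairs; significant edges are
counted per direction.

## GLM and percent signal change

First-level GLMs fit each condition run with the HRF-convolved
stimulation regressor, a linear drift, and an intercept by least squares.
The second-level max criterion — AV > max(A, V) at p < 0.05
FWE-corrected, intersected with V > 0 or A > 0 at p < 0.05 uncorrected —
is operationalized as the minimum-statistic conjunction of one-sided
one-sample t-tests on the subject contrasts AV−A and AV−V, with the FWE
threshold from the max over voxels of the min-t statistic under subject
sign-flipping (all 2^S flips enumerated for S ≤ 14; conjunction-null,
the stricter reading). The disjunctive mask uses uncorrected one-sided
t-tests. Percent signal change fits the GLM to the ROI-mean series and
reports 100 × the peak of the fitted event response over the intercept;
a non-positive baseline yields NaN with the undefined flag.

## Desk-scale problem sizes

Analyses in the test suite and acceptance script use: the 24×24×12 grid
with K = 300 selected voxels (orderings are stable in K over 25–1500);
50 replicates for the reproducibility/connectivity orderings and 25 for
the GLM pattern; 3 subjects and 200 permutations for localization; a
10×10×6 phantom, one subject, 200 permutations × 200 datasets for the
FWE calibration; 5 subjects for the exact sign-flip second level (the
floor p of 2^S flips requires S ≥ 5); 500 white-noise pairs for the
Granger type-I calibration. Full-fidelity defaults (K = 1500,
n_perm = 1000, 9 subjects) remain the configuration defaults.

## What the synthetic experiments show — and what they do not

Passing tests establish that the implemented statistics detect exactly
the structure the generative model plants (attention-gated contrast,
congruence-gated AV enhancement, attention-gated superadditive
heteromodal responses, lag-1 directed coupling), that the permutation
and sign-flip procedures control their error rates on matched null data,
and that each computational step agrees with an independent oracle. The
phantom omits much of real fMRI: no motion, no slice-timing or
registration errors, no spatially structured (non-global) noise
correlations, no HRF variability across regions or subjects, hemodynamics
exactly matching the analysis HRF, and single-trial decodability that is
optimistic relative to typical reports. Results on real data would
additionally depend on the out-of-scope spatial preprocessing chain.

## Known limitations

* The reproducibility *ratio* is unstable wherever r_between approaches
  zero; the ε-exclusion handles isolated folds, but regimes with strong
  contrast and weak shared response are better served by the difference
  form.
* Pairwise (not conditional) Granger causality is the default; with more
  than two jointly interacting ROIs, indirect paths can appear as edges
  (a conditional variant is available behind a flag).
* Fisher's combination assumes independent subjects; it is
  anti-conservative if runs share structured artifacts.
* The empirical nearest-rank 95th-percentile threshold at n_perm = 200
  has an inherent ≈5.5 % attained level (11/201 under exchangeability);
  n_perm = 1000 brings it to ≈5.1 %.
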