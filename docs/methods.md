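# Methods

`twinpcg` classifies 5-second phonocardiogram (PCG) segments as *normal* or
*abnormal* from an 18-dimensional descriptor fed to a twin support vector
machine. This note records the model, the numerical conventions, the
defaults and why they are what they are, and what the synthetic data do and
do not establish.

## Signal model and windowing

Records are mono waveforms sampled at 2000 Hz. Every record is reduced to a
fixed analysis window of the first 10,000 samples (5 s), zero-padded when
shorter. A fixed window is mandatory because the subband two-norms below
are extensive quantities (they grow with record length); how to handle
longer records is a genuine protocol choice and we chose plain truncation —
simple, deterministic and sufficient for quasi-stationary heart sounds.
Integer PCM amplitudes are mapped to [−1, 1] on read so that the
scale-dependent features are computed on one fixed convention.

## Features

**Wavelet-packet two-norms (16).** The window is decomposed with a full
4-level wavelet-packet transform using the orthogonal Daubechies db6 filter
pair and periodization boundaries. The 16 terminal subbands (4,0)…(4,15)
are kept in natural (Paley) order; feature k is ‖S_k‖₂, the Euclidean norm
of subband k's coefficients. Periodization is used because it keeps the
transform exactly orthogonal, so Parseval holds to rounding error
(Σ_k ‖S_k‖₂² equals the window energy; asserted at 1e−8 relative in the
tests). Norms are computed on the raw decomposition coefficients rather
than reconstructed node signals: under orthogonality the energies agree,
and raw coefficients avoid a second filtering pass. No best-basis pruning
takes place — the basis is the fixed full level-4 tree, so an entropy-based
selection criterion would have nothing to choose.

**Wavelet-packet energy entropy (1).** With E_k = ‖S_k‖₂² and
ε_k = E_k / Σ_j E_j, the feature is H = −Σ_k ε_k ln ε_k, the Shannon
entropy of the subband energy distribution (0·ln 0 := 0). H is 0 when all
energy sits in one subband and ln 16 ≈ 2.773 when spread uniformly, and is
invariant to rescaling the input — a useful property when recording gain is
arbitrary. The natural logarithm is a pure convention; any base rescales H
by a constant that downstream standardization absorbs. A per-sample
variant of this sum is not well defined (the ε_k are per-record constants),
so the package computes one scalar per record, which is also what the
classifier consumes. An all-zero window has no defined entropy and is
rejected with an explicit error.

**Box-counting fractal dimension (1).** Time is mapped to [0, 1] and
amplitude affinely to [0, 1] (a flat signal maps to the constant 1/2), so
the estimate is invariant to affine amplitude transforms and bounded by the
planar limit 2. For a grid scale δ the unit square is tiled by an exact
NB × NB grid, NB = round(1/δ); the covered set is the polyline through
consecutive samples, and each time column contributes
`row(colmax) − row(colmin) + 1` boxes, since a polyline's extremes within a
column occur at samples or column edges. The exact integer tiling (rather
than a ragged partial last row/column) is what makes the count symmetric
under amplitude flips and time reversal, properties the tests assert at
1e−12. Scales follow the dyadic ladder δ_i = 2^{i−1}·δ_t (δ_t = one sample
interval), i = 1…i_max, with default i_max = ⌊log₂ n⌋ − 4 (nine scales at
n = 10,000) so the coarsest column still spans ≳16 samples; the grid scale
cannot meaningfully shrink below the sampling interval. The dimension
estimate is the ordinary least-squares slope of log N(δ) against
log(1/δ), over all computed scales, with r² reported as a fit diagnostic.

A known, documented bias: on *sampled* random-walk data the estimator
converges to the continuum Brownian-graph value 3/2 only logarithmically —
the expected range of a k-step walk approaches its √k asymptote from
below, so local slopes rise from ≈1.22 at the sampling scale toward the
asymptote at coarse scales. At n = 10,000 the 20-replicate mean is ≈1.36
(recomputed by the test suite and the acceptance script), and smooth
signals (ramp, constant) estimate ≈1.0. Heart-sound values produced by the
pipeline typically fall in 1.35–1.6, murmurs pushing the value up.

## Classifier: twin support vector machine

Instead of one separating hyperplane, the TWSVM fits two nonparallel
planes in the kernel space spanned by the m training samples C:
f_k(x) = K(x, Cᵀ)u_k + b_k, k = 1, 2. Plane 1 minimizes
½‖K(A,Cᵀ)u₁ + e b₁‖² + c₁ eᵀζ subject to −(K(B,Cᵀ)u₁ + e b₁) + ζ ≥ e,
ζ ≥ 0, where A holds the positive-class (abnormal) rows and B the
negative-class rows; plane 2 is the mirror problem. Each QP's constraints
involve only the opposite class, so the two problems are about a quarter
the size of the single SVM QP, and class imbalance is handled naturally —
each class gets its own plane. A test point is assigned to the class of
the nearer plane, distance |f_k(x)| / √(u_kᵀ K(C,Cᵀ) u_k); the absolute
value in the numerator is required for a distance, and an exact tie goes
to the negative (normal) class.

The QPs are solved via their duals: with H = [K(A,Cᵀ) e] and
G = [K(B,Cᵀ) e], the dual of plane 1 is
max_α eᵀα − ½ αᵀ G (HᵀH + εI)⁻¹ Gᵀ α with box constraints 0 ≤ α ≤ c₁, and
[u₁; b₁] = −(HᵀH + εI)⁻¹ Gᵀ α. The Tikhonov ridge ε = 1e−6 is required —
HᵀH is rank-deficient whenever m₁ + 1 < m — and is included in the primal
objective the tests compare against, so the comparison is exact. The box
QP is solved with projected L-BFGS-B (an accelerated projected-gradient
fallback guards against line-search failures on ill-conditioned kernels),
then polished by solving the KKT system exactly on the strictly interior
coordinates; on all small fixtures the result matches a generic primal
solve to ≤1e−5 in objective.

The kernel is Gaussian, K(x, y) = exp(−‖x−y‖²/2σ²), with the width
entering each plane separately (σ₁, σ₂). Defaults c₁ = c₂ = σ₁ = σ₂ = 3.5,
the operating point the method was tuned to; a stratified k-fold
cross-validation grid search (mean validation accuracy, ties to the first
grid point) is available for re-tuning. Features are z-scored inside
`fit`/`predict` with training-set statistics (off by a switch): the raw
descriptor mixes scales — norms of order tens, entropy ≈1, dimension ≈1.5 —
and an unstandardized Gaussian kernel would be dominated by the norm block.
Stratification is used in CV because heart-sound datasets are typically
imbalanced toward abnormal recordings.

## Evaluation

Abnormal is the positive class throughout. From TP/FN/TN/FP the package
reports accuracy, sensitivity (recall), specificity, precision and F1 (the
harmonic mean of recall and precision), all in percent. A measure whose
denominator is zero raises an error naming the measure rather than
returning 0: silent zeros corrupt grid searches. The experiment protocol
draws a seeded stratified train/test split (200/150 when the dataset is
large enough, otherwise the same proportion), selects hyperparameters by
CV on the training rows only, fits once, and evaluates once on the held-out
rows; the split seed is mandatory, and every artifact embeds the config
hash and seeds. Train/test membership is record-wise; with real multi-
recording subjects a patient-wise split would be stricter.

## Synthetic data: what it emulates, and what it does not

Each synthetic record is built from per-beat S1 and S2 Gaussian-enveloped
tone bursts (defaults: S1 ≈ 50 Hz with 20 ms envelope sd, S2 ≈ 80 Hz,
0.45× S1's amplitude, a fixed 0.32 s systolic interval) at a configurable
heart rate, plus white sensor noise. Abnormal records add a murmur:
band-limited noise confined to a smooth systolic window between S1 and S2.
The noise and murmur random streams are spawned independently from the
seed, so the normal and abnormal variants of one seed differ *only* inside
systole — a property the tests exploit.

The dataset generator draws per-record heterogeneity emulating a
multi-site archive: heart rate U(55, 100) bpm, ±10% S1/S2 frequency
jitter, sensor noise sd U(0.01, 0.04), murmur amplitude U(0.2, 0.5), a
per-record murmur band (center U(150, 600) Hz, ±40% width) because
different pathologies murmur at different pitches, and an overall record
gain LogNormal(0, 1.6) because uncalibrated recording chains make absolute
level meaningless. The last two are exactly the degradations the entropy
and fractal features are invariant to and the raw norms are not, which is
why the 18-feature classifier measurably outperforms the 16-norm variant
on this data — the same qualitative ordering the feature hierarchy is
designed for.

Limitations to keep in mind: the generator produces stationary beat
timing (no respiratory sinus arrhythmia or ectopy), murmurs only in
systole, Gaussian noise only (no friction rubs, clipping, speech or
ambient transients), and class structure that is by construction aligned
with the features' invariances. Passing the end-to-end test therefore
demonstrates that the pipeline's machinery — features, solver, protocol —
extracts the available class structure; it does not certify accuracy on
real clinical recordings, which must be evaluated on a real archive.

## Problem sizes and numerical defaults

The shipped experiments use 350 records (200 abnormal, 150 normal) with a
200/150 train/test split — the package's standard study scale. Tolerances:
Parseval 1e−8 relative; QP feasibility/objective comparisons 1e−5–1e−6;
ridge ε = 1e−6; entropy closed forms exact to 1e−12. Degenerate inputs
(zero-energy windows, one-class training sets, flat signals, undefined
metrics) raise typed errors rather than producing silent values; the one
deliberate silent convention is the flat signal's amplitude mapping to 1/2
in the box counter, which makes the constant signal a well-defined
dimension-1 fixture.
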