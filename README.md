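# twinpcg

Classification of heart sounds (phonocardiograms) as **normal** or
**abnormal** from compact wavelet/entropy/fractal descriptors and a
**twin support vector machine**, for biomedical-signal researchers and
engineers prototyping automated cardiac auscultation.

Auscultation records — 2000 Hz mono waveforms such as those in the
PhysioNet/CinC Challenge 2016 database — carry diagnostic information in
the two heart sounds S1/S2 and, for many pathologies, in systolic murmurs.
`twinpcg` reduces each 5 s segment (10,000 samples) to at most 18 numbers:

1. **16 subband two-norms** ‖S_k‖₂ of the terminal nodes (4,0)…(4,15) of a
   full 4-level db6 wavelet-packet decomposition (periodization
   boundaries, so Parseval holds exactly);
2. **wavelet-packet energy entropy** H = −Σ_k ε_k ln ε_k, where
   ε_k = ‖S_k‖₂² / Σ_j ‖S_j‖₂² — low when energy concentrates in one band,
   ln 16 when uniform, invariant to recording gain;
3. **box-counting fractal dimension** D_B: the least-squares slope of
   log N(δ) vs log(1/δ) over dyadic grid scales δ_i = 2^{i−1}δ_t on the
   normalized unit square — a gain-invariant measure of waveform
   irregularity (smooth signals ≈ 1, murmurs push it toward 1.6).

The classifier fits two nonparallel kernel hyperplanes
K(x, Cᵀ)u_k + b_k = 0 — one pulled close to each class and pushed unit
margin from the other — by solving, per plane,

    min ½‖K(A,Cᵀ)u₁ + e b₁‖² + c₁ eᵀζ
    s.t. −(K(B,Cᵀ)u₁ + e b₁) + ζ ≥ e,  ζ ≥ 0

through its box-constrained dual (Gaussian kernel
K(x,y) = exp(−‖x−y‖²/2σ²); defaults c₁ = c₂ = σ₁ = σ₂ = 3.5). A point is
assigned to the class of the nearer plane. The two QPs are a quarter the
size of the single-SVM problem and tolerate class imbalance naturally. A
built-in generator synthesizes labeled PCG records (S1/S2 bursts, systolic
murmurs, sensor noise, archive-style gain and band heterogeneity), so the
entire pipeline runs and is tested without external data.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
from twinpcg import (ExperimentConfig, extract_features, features_to_frame,
                     run_experiment, synthesize_dataset)

records = synthesize_dataset(n_normal=150, n_abnormal=200, seed=7)
frame = features_to_frame(
    [extract_features(r, "wavelet+entropy+fractal") for r in records])
result = run_experiment(frame, ExperimentConfig(split_seed=7))
print(result.summary())
```

```
classifier     : twsvm
feature set    : wavelet+entropy+fractal (18 features)
train / test   : 200 / 150  (split seed 7)
hyperparams    : {'c1': 3.5, 'c2': 3.5, 'sigma1': 3.5, 'sigma2': 3.5}
config hash    : 042f35d7f68c

measure       percent
accuracy       100.00
sensitivity    100.00
specificity    100.00
precision      100.00
F1             100.00

confusion      : TP=86 FN=0 TN=64 FP=0
```

All 150 held-out records are classified correctly here (synthetic data at
this seed is cleanly separable in 18 dimensions; the 16-norm variant of
the same run misclassifies several records — gain jitter hurts the norms
but not the entropy/fractal features). For one record the descriptor looks
like: first norms `[16.5694, 10.9545, 0.6637, 1.1586, …]`, entropy
`0.7064`, fractal dimension `1.4119` — entropies across a dataset
typically fall in 0.5–2 and dimensions in 1.35–1.6.

The same flow is available from the shell:

```sh
twinpcg simulate --n-normal 150 --n-abnormal 200 --seed 7 --out-dir data/
twinpcg extract --wav-dir data/ --labels data/labels.csv --feature-set 18 --out features.csv
twinpcg train --features features.csv --model model.joblib
twinpcg predict --model model.joblib --features features.csv --out predictions.csv
twinpcg evaluate --predictions predictions.csv --labels data/labels.csv
```

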