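# Methods

This note documents the model implemented by `fbcsp-select`, the
choices made where the method description leaves room, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Pipeline definition and conventions

**Epoching.** Trials are cut from continuous recordings over a window
relative to each cue (default 0.5–2.5 s). Indexing is 0-based and
half-open: a trial holds samples `[round((cue+t0)·fs), round((cue+t0)·fs)
+ round((t1−t0)·fs))`, so every trial has an identical length and there
is no off-by-one ambiguity. Epochs are cut first, filtered second.

**Filtering.** All filters are Butterworth band-passes applied
zero-phase (forward–backward), so the 2-s analysis window is not
shifted by group delay; the magnitude response is squared in exchange.
"Order" means the overall band-pass order (an order-4 band-pass is
`scipy.signal.butter(2, ..., btype="bandpass")`). The broadband filter
(0.5–40 Hz, order 4) feeds only the TDP/correlation path; the filter
bank (eight 4-Hz bands, 4–36 Hz, order 4 each) is applied to the raw
epochs for the CSP path. The method description does not say whether
the broadband filter also precedes the bank; applying both would
attenuate only the 4–8 Hz band edge, and keeping the bank on raw epochs
makes each band's content depend on exactly one filter. Epochs shorter
than the zero-phase filter's padding requirement are rejected, never
padded — a padding policy would silently change variance features.

**TDPs.** `T(i,p)(k) = log var(Δᵖ x)` with Δ the first-order forward
difference applied `p` times (the simplest discrete derivative; the
signal shortens by `p` samples), population-normalised variance, and a
floor of 1e-12 before the natural log so constant or linear-ramp
channels yield finite values instead of poisoning the Fisher argmax.
Natural logs are used throughout (the conventional choice for
log-variance CSP features; no ordering depends on the base).

**Fisher ratio.** Numerator: Σₚ (between-class mean difference)²;
denominator: Σₚ Σ_c within-class population variance. With balanced
classes any alternative normalisation of the within-class term rescales
all channels equally and leaves the argmax unchanged. Argmax ties break
to the lowest channel index for reproducibility. A channel whose TDPs
have zero within-class variability in both classes is "degenerate"
(ratio undefined); degenerate channels are excluded from the argmax and
an error is raised only if every channel is degenerate.

**Supporting set.** Per-trial Pearson correlations between each channel
and the principle channel are computed on the broadband epochs (the
TDP/correlation stage is defined on the wide band, not per sub-band)
and averaged within each class. A channel joins S when both class means
reach ρ_thr; the test uses *signed* correlations exactly as the
selection rule is written — a strongly anti-correlated channel does not
qualify. The principle channel always belongs to S (its self-correlation
is identically 1), so the most discriminative channel is always
available to CSP. S is reported in ascending channel order. |S| < 2 is
an error that advises lowering the threshold.

**CSP.** Per-trial covariances are `XXᵀ/trace(XXᵀ)` (no demeaning, the
standard CSP convention; band-passed signals are zero-mean to numerical
precision). The variance-ratio extremisation is solved exactly as the
symmetric-definite generalised eigenproblem of the class-mean pair —
the largest/smallest eigenvalues *are* the attained ratios. When E̅₂'s
condition number exceeds 1e10 a ridge of 1e-10·trace is added to its
diagonal (small supporting sets with few trials can be rank-deficient).
One filter pair per band, no additional eigenvector pairs, so the final
feature vector is exactly 4-dimensional after band selection. Filter
signs are fixed (first non-negligible component positive); log-variance
features are sign-invariant anyway. Feature variances are population
variances of the projected signal (with demeaning), floored at 1e-12
before the log.

**Band selection.** Mutual information between each feature and the
label is estimated by Parzen-window class-conditional densities
(Gaussian kernel, Silverman bandwidth 1.06·σ·n^(−1/5), floored at
1e-3 of the feature scale) and the sample mean of the log posterior
ratio, in bits, clipped below at 0. A band's score is the sum of its
two features' MI — selection operates at band level (choose the best
two bands), not at individual-feature level; that matches selecting two
frequency bands and keeps the feature vector's structure fixed. Ties
break to the lower band index. MI is always computed on training trials
only.

**Classifier.** Linear maximum-margin classifier (SVM, C = 1) on
features standardised by training-fold mean/SD. Four-dimensional
features rarely justify a nonlinear kernel, and a fixed C keeps the
pipeline deterministic. The decision function is stored as explicit
weights, so saved models are plain JSON and predictions need no
training data ("self-contained model" contract).

**Cross-validation.** 5 seeded repetitions of stratified 5-fold CV.
When ρ_thr is not fixed, it is chosen *within each training fold* by an
inner stratified 5-fold CV over the grid (default 0.6–0.9 in steps of
0.05) — nested selection, so held-out trials never influence the
choice. Reported per-threshold tables evaluated on outer folds are for
inspection; the headline accuracy always comes from the nested
procedure. Grid values whose supporting set collapses below 2 channels
are skipped during selection. Both a constant-threshold mode and the
per-session (nested) mode are exposed.

## Synthetic session generator

The generator emulates exactly the structure the method assumes:

* **Sources.** Every source channel carries 1/f background noise
  (spectrally shaped white noise, flat below 1 Hz). A subset
  (default sources 7–9 of 18) additionally carries a mu rhythm:
  white noise band-passed to 8–12 Hz (order 4, zero-phase).
* **ERD.** In class-1 trials the mu rhythm's variance on those sources
  is multiplied by (1 − depth), depth = 0.6 by default — a power
  modulation of a stochastic oscillation, not a deterministic sinusoid,
  so band power varies trial to trial as real rhythms do.
* **Volume conduction.** Observed channels are a row-normalised
  `exp(−|a−b|/2)` mixture of the sources — a monotone spatial
  correlation falloff without any electrode geometry — plus white
  sensor noise (SD 0.05 against a background SD of 1.0 and oscillation
  SD of 2.0).
* **Determinism.** One `numpy` Generator seeded from the config drives
  everything; identical seeds give bit-identical sessions.

Default scale choices: the oscillation dominates the 8–12 Hz band at
the ERD channels (background contributes ≈ 5 % of in-band power there),
neighbouring channels correlate above 0.6 through shared sources (so
the default ρ_thr grid produces supporting sets of ~5–13 channels,
shrinking as the threshold rises), and sensor noise is small enough not
to wash out inter-channel correlation.

**Calibration ceiling.** For a power-modulated band-limited Gaussian
process observed for T = 2 s in a B ≤ 4 Hz band, the per-trial log
band-power SD is bounded below by roughly √(2/(2·B_eff·T)) ≈ 0.37–0.39
(B_eff ≈ 3.3 Hz for the order-4 zero-phase band filter), and summing
independent co-band sources does not lower it (the sum is again a
Gaussian process of the same bandwidth). With the 60 % depth the class
mean shift is log(1/0.4) ≈ 0.92, so the attainable class separation of
log mu power at the strongest mixed channel is capped near 2.4–2.5
pooled SDs; the preset realises ≈ 2.2. Consequences: classifier
training accuracy on the preset sits around 0.89–0.97 rather than
arbitrarily close to 1, while cross-validated accuracy comfortably
clears 85 % and selection recovery is near-perfect.

**What the generator does not emulate.** No electrode geometry or
biophysical leadfield, no artifacts (EMG/EOG), no beta-band ERS, no
within-session nonstationarity, no class-dependent correlation
structure beyond the power modulation. Passing tests on this generator
show the pipeline recovers planted spatial/spectral structure under
volume-conduction-like mixing and realistic trial-power variability;
they do not certify performance on real EEG, where artifacts and
nonstationarity dominate.

## Numerical and interface choices

* Variance floors (1e-12) appear before every log; MI densities carry a
  1e-300 guard inside the log ratio.
* The cross-validation engine precomputes per-trial filtered data,
  TDPs, correlation matrices and band covariances once per session and
  lets folds index into them; all of these are per-trial quantities, so
  fold subsetting is exact (identical results to refitting from raw
  data) and no information crosses trial boundaries.
* Epoch container: a plain `.npz` with `data`, `labels`, `fs`,
  `channel_names`. Models are JSON. Configs are YAML.
* EDF: reading goes through MNE (annotation onsets become cue times);
  writing uses a minimal built-in single-segment 16-bit encoder
  (1-second records, no EDF+ annotation channel — cue times belong in a
  JSON sidecar). Round-trip fidelity is limited by 16-bit quantisation
  over the symmetric physical range.
* Problem sizes in the test-suite and acceptance script: recovery rates
  use 100 sessions of the default preset; cross-validation examples use
  the 200-trial preset; the permutation null uses 20 shuffles of a 5×5
  CV at a fixed threshold.

## Limitations

* Binary classification only; no multi-class CSP extension.
* One spatial filter pair per band (by construction of the 4-D feature
  contract); no regularised or sparse CSP variants.
* The selection rule uses signed correlations; physiologically one
  might argue |ρ| should qualify anti-correlated channels, but that
  would change the printed selection rule and is not implemented.
* Input sampling rates are taken as-is (no resampling), and no artifact
  rejection or re-referencing is performed.
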