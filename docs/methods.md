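# Methods

This note records the models, parameter choices and conventions behind
`eegssl`, and what the synthetic experiments do and do not show.

## Synthetic EEG generator

Each trial of class k is a sum over the five canonical bands of
Gaussian noise confined to that band, scaled so the band's standard
deviation equals the class profile entry, plus a 1/f (pink) background
and an optional linear source-to-channel mixing:

    s_c(t) = Σ_b  a_b(t) · n_b(t) · P[k, b]  +  σ_noise · pink(t)

* **Band-limited noise** is synthesized by masking the DFT of white
  noise. The in-band spectrum is flat and the out-of-band power is
  exactly zero, so an independent spectral measurement recovers the
  configured band SD essentially exactly. (Butterworth-filtered
  synthesis was tried first; the compounding passband edges of the
  synthesis and measurement filters lose ~6% of the SD, which blurs
  the generator's contract.) Per-band content is Gaussian by
  construction, so the closed-form differential entropy is exact in
  expectation.
* **Slow amplitude drift.** Each band of each source is modulated by a
  log-normal envelope a_b(t) = exp(m(t)) whose log is a stationary
  Gaussian process with Gaussian autocorrelation
  corr(Δ) = exp(−Δ²/2τ²), τ = 20 s, log-SD 0.35. This realizes the
  temporal-continuity assumption the pretext tasks rely on: windows
  ≤ 12 s apart share amplitude state (corr ≈ 0.84) while windows
  > 60 s apart are effectively independent (corr ≈ 0.01). Ultraslow
  (< 0.1 Hz) amplitude fluctuation of band power is a documented
  feature of real EEG; the Gaussian-autocorrelation form is a modeling
  convenience.
* **Gamma cap.** The nominal γ band ends at 100 Hz, which equals
  Nyquist at 200 Hz sampling; synthesis caps γ content at 0.95·Nyquist
  (95 Hz) and the analysis filter clips its edge to 0.99·Nyquist with
  a warning.
* **Defaults** (the study conditions used by the tests and the
  acceptance script): 2 subjects × 6 trials × 240 s × 8 channels at
  200 Hz, 3 classes with distinct θ/α/β/γ SD profiles, pink noise
  SD 0.3. Labels are constant within a trial and balanced round-robin
  per subject. One RNG stream is spawned per (subject, trial), so
  generation is bit-reproducible and order-independent.
  `noise_color="white"` with zero profiles and no envelope gives the
  structure-free null used by the controls: i.i.d. noise in which
  nothing is predictable across windows.

Not emulated: eye/muscle artifacts, electrode geometry, volume
conduction, nonstationary class content within a trial, inter-subject
variability beyond independent noise. Passing tests on this generator
show the pipeline's machinery and its statistical behavior are
correct; they do not certify accuracy levels on real recordings.

## Windows and differential-entropy features

Windows are 0-based, half-open [t, t+T), T = 1 s by default,
non-overlapping (hop = T, configurable). A trailing partial window is
discarded.

DE per window/channel/band is ½ln(2πe·σ̂²) in **nats** (natural log
throughout; a log base changes features only by a constant factor and
is irrelevant to any downstream classifier, but it is pinned here for
exact tests). σ̂² is the unbiased (n−1) sample variance. Two routes:

* `method="filter"` (default): order-4 zero-phase Butterworth
  (`sosfiltfilt`) applied to the whole recording before windowing, so
  no group delay shifts window alignment;
* `method="stft"`: mean Welch band power as the variance estimate.

The two agree within 0.2 nats on band-limited Gaussian signals. A
zero-variance window raises an error rather than emitting −∞, which
would silently poison downstream training.

## Pretext tasks

* **Sampling.** τ_pos = 12 and τ_neg = 60 window units by default
  (12 s / 60 s at 1-s windows); values are unspecified in the
  emotion-EEG literature, and these follow common practice for
  temporal pretext tasks on biosignals. Pairs/triples are drawn within
  one trial only — temporal adjacency across trial boundaries is
  meaningless. Classes are balanced N/2 : N/2 (the constraint alone
  does not fix the ratio, and imbalance degenerates the linear head).
  TS anchors come from the positive context; ordered triples place the
  third window strictly between the anchors, shuffled triples draw it
  from beyond τ_neg of both anchors.
* **Heads and loss.** RP uses the elementwise absolute difference of
  embeddings; TS concatenates the two absolute differences. Both use
  the logistic loss on y ∈ {−1, +1}. The printed loss is per-sample
  (sum/N) during training; the `logistic_loss` API returns the sum.
* **RP loss form.** Only the TS loss is written out in the source
  literature, with RP described as the same construction on pairs;
  this package uses the identical logistic form over g_RP.

## Encoder and context model

The default raw-window encoder is a temporal convolution bank with
log-energy pooling:

    conv   = W1 · im2col(x; kernel 33, stride 8)     (24 filters)
    pooled = log(mean_t conv² + 1e-8)                 (per-filter)
    z      = tanh(W2 · pooled + b2)                   (D = 32)

Each filter is a learned FIR band-pass, and its pooled log energy is a
differential-entropy-like statistic — the natural representation for
signals whose classes differ in band variance. An MLP variant accepts
precomputed DE features. The context model is a single-layer GRU
(hidden = D), causal by construction. The exact architecture is not
prescribed by the problem; this one is small enough to train in
seconds on a CPU and is exposed via `EncoderConfig`.

All training runs on the package's own reverse-mode autodiff core
(`eegssl.nn`): a deliberately small tape-based engine (a dozen
primitives) whose gradients are tested against central finite
differences, optimized with a hand-written Adam.

## CPC training protocol

* Negatives are drawn uniformly from all windows of the dataset
  (any trial), excluding the entry's positive; contrast size N = 8
  (7 negatives). Each valid context position is used at most once per
  epoch; epochs are capped at 60 batches of 16 for CPU budgets.
* One independent W_k per prediction step k = 1..4; the total loss is
  the mean over k (scale-invariant in K).
* All scoring is done in log space (log-sum-exp); exp(zᵀW c) is never
  materialized.
* W_k is initialized at scale 1/√(D·ctx), so the untrained model's
  candidate scores are near-equal and its loss sits at the chance
  level ln N. This matters for the null control: "no structure" should
  read as ln N, not as an offset inflated by random score variance.
* `fit(val_window_sets=...)` tracks the InfoNCE loss on held-out
  trials after every epoch and returns the best-validation checkpoint.
  Without this, a model trained on structure-free noise still drives
  its *training* loss below ln N by memorizing individual windows
  (observed: 1.2 vs chance 2.08, with held-out loss rising to 2.5);
  early stopping on unseen trials is the standard remedy and keeps the
  null honest. Decoupled (AdamW-style) weight decay is available but
  mild by default.

## Downstream evaluation

* **Folds group by trial** and are stratified by trial label
  (`StratifiedGroupKFold`). Window-level splitting would leak
  within-trial autocorrelation and inflate every method; this choice
  is stricter than an unspecified protocol and affects comparability
  with published absolute numbers.
* **Per-fold macro-F1** averages per-class F1 over the classes present
  in that fold (truth or predictions). With 12 trials and 10 grouped
  folds a test fold cannot contain all classes, and averaging over
  globally-defined classes would score a perfect classifier 66%. The
  standalone `f1_macro(pred, true, n_classes)` keeps the strict
  convention (absent class ⇒ F1 := 0) for exact metric tests.
* **Scarce labels.** `label_fraction` keeps a stratified fraction of
  each fold's training windows labeled (minimum one per class) before
  fitting the probe — an L2-regularized multinomial logistic
  regression (C = 1). `mode="fine_tune"` instead clones the pretrained
  encoder per fold and trains it jointly with a softmax head (Adam,
  10 epochs by default); the frozen linear probe remains the headline
  protocol because it measures representation quality rather than
  architecture capacity.
* **Valence/arousal quadrants** use score ≥ 5 as "high" (ties count
  high; the tie direction must be fixed somewhere and is documented
  here), class = 2·[V≥5] + [A≥5].
* **Method comparison** uses the two-sided Wilcoxon signed-rank test
  on paired per-fold scores, Bonferroni-corrected across the pairs
  tested. Identical score vectors are a degenerate comparison and
  raise; the batch comparison table records such pairs as NaN.
* **Null controls.** The permutation null shuffles labels i.i.d.
  across windows (labels independent of features) and should land at
  chance. Trial-level permutation (`permute_trial_labels`) is also
  provided, but with few trials per class it exhibits the well-known
  below-chance anti-correlation bias of permutation CV (observed
  ~25% on 12 trials against a 33.3% chance level), so it is tested
  with an appropriately loose tolerance rather than presented as a
  tight control.

## Problem sizes

The default experiment (12 trials × 240 windows × 8 channels) keeps
every stage CPU-friendly: dataset generation ~2 s, DE extraction
~1 s, RP/TS pretraining a few seconds, CPC pretraining ~20 s for
8 epochs, the full acceptance recomputation ~1 minute. These sizes
were chosen as the smallest at which the statistical claims (pretext
learnability, probe transfer, null behavior) are stable across seeds.

## Known limitations

* The generator's class effect sizes are chosen for testability; real
  emotion effects in EEG are far subtler, and absolute accuracies here
  say nothing about real-data performance.
* The encoder is intentionally small; no claim is made that it is the
  best architecture for real EEG.
* Cross-subject transfer, artifact handling and real-data adapters
  (SEED/DEAP directory layouts) are out of scope.
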