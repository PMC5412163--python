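# Methods

`eegcad` implements a subband-entropy pipeline for two-class classification
of resting-state EEG (autistic vs. normal): zero-phase elliptic band-pass
filtering, fixed-length segmentation, 4-level discrete wavelet transform
(Daubechies-4), entropy or moment features per coefficient band, a small
feed-forward neural network, and stratified 10-fold cross-validation.  This
note records the model assumptions, the parameter choices that matter, and
the design decisions taken where the procedure was genuinely open.

## Signal model and preprocessing

Recordings are multichannel scalp voltages at a nominal 256 Hz, 16 channels
in 10–20 placement.  Amplitudes are treated as arbitrary-but-consistent
units: the entropy features are invariant under affine rescaling (the
histogram bins scale with each array's range), so amplifier gain does not
matter; the threshold count is the one deliberate exception (see below).

*Band-pass.* Elliptic IIR, order 4, passband 0.1–60 Hz, stopband
attenuation 40 dB, applied forward–backward (`sosfiltfilt`) for zero phase.
The passband ripple is 0.2 dB: forward–backward application squares the
magnitude response, so a 0.2 dB single-pass design keeps the net passband
deviation within 5 % of unity, which the looser conventional 0.5 dB design
would not (its squared response dips to 0.89).

*Notch.* Optional second-order IIR notch, Q = 30, default 60 Hz, off by
default — the recordings this pipeline emulates were already
notch-filtered at acquisition.

*Ocular-artifact removal.* FastICA with as many components as channels,
fixed seed.  Components whose absolute Pearson correlation with any frontal
reference channel (FP1, FP2, F7, F8) exceeds 0.7 are zeroed before
back-projection.  The stage is **off by default**: enabling it degrades the
reference results it reproduces, and segment entropies are robust to
occasional transients.  ICA requires non-Gaussian sources to be
identifiable; on synthetic data this is guaranteed by the generator's
amplitude-modulated bands (below).  Non-convergence is flagged as an error,
with an explicit pass-through option.

*Segmentation.* Windows of `length_s` seconds starting at 0, step,
2·step, … with step = length × (1 − overlap); trailing partial windows are
discarded and windows never span recording boundaries.  A recording of
`d` seconds yields `floor((d − L)/step) + 1` windows.  Defaults: 60 s with
half-segment overlap (the best-performing configuration of the method this
package reimplements).

## Wavelet decomposition

4-level DWT with db4 and symmetric (half-sample) boundary extension per
channel; `periodization` is available where exact energy conservation is
wanted.  Coefficients are named D1 (finest, 64–128 Hz at fs = 256) through
D4 (8–16 Hz) plus A4 (0–8 Hz), the standard dyadic mapping
D_k ↔ (fs/2^(k+1), fs/2^k).  Published tables sometimes label these bands
at twice these frequencies (D1 as "128–256 Hz"), which is inconsistent with
a 128 Hz Nyquist; the package implements and documents the standard
mapping.

## Features

Entropies are defined on a discrete distribution, but wavelet coefficients
are continuous — a "unique values" reading would make every value unique
and collapse Shannon entropy to log2(n).  Probabilities are therefore
estimated by an equal-width histogram (default 256 bins) over each array's
own range, empty bins dropped.  This preserves the entropy *ordering*
between more- and less-structured signals while staying well defined.

- Shannon: H = −Σ p_i log2 p_i (bits; 0 ≤ H ≤ log2 k).
- Rényi: H = log(Σ p_i^α)/(1 − α), natural log; the order α is not fixed
  by the source method, default 2 (collision entropy), configurable.
- Log-energy: H = Σ log(p_i²), natural log, over occupied bins.
- Threshold: count of coefficients with |x| > 0.2 (strict).  The absolute
  value is a deliberate choice — wavelet coefficients are signed and a
  one-sided count would ignore half the excursions (`features.threshold_abs`
  restores the literal one-sided reading).  This feature is intentionally
  *not* scale-invariant.
- Moments: population mean, std, variance, skewness, kurtosis
  (non-excess).  Zero-variance input yields 0 for skewness/kurtosis with a
  warning so feature matrices stay finite.

One feature function is used per experiment.  A segment's vector holds one
value per (channel, selected coefficient), channels-major; the default
selection is the detail bands D1–D4 (the best-performing combination).
Whether the source method pooled channels or kept them separate is not
stated; per-channel concatenation is the information-preserving reading.

## Classifier

One hidden layer of 5 log-sigmoid units, 2-unit softmax output; the
autistic class is output index 0.  Features are z-scored with statistics
fitted on the training fold only (unnormalised entropy magnitudes would
saturate the sigmoids).  Training: full-batch gradient descent with
classical momentum on mean cross-entropy — learning rate 0.01, momentum
0.9, ≤500 epochs, early stop when the epoch loss change is below 1e-6.
Weights initialise uniform(−0.5, 0.5)/√fan-in from a seeded generator.  The
source method specifies the architecture but no learning rule, epochs or
initialisation; these are this package's choices, exposed in config.
Full-batch training makes the fit independent of sample order (verified to
1e-9) and bit-reproducible for a fixed seed.

## Evaluation

10-fold cross-validation at segment level.  Folds are **stratified by class
label** by default: with plain random folds a degenerate majority-class
model systematically scores *below* chance, because each test fold's class
imbalance is opposite its training fold's (measured: null-data accuracy
41–48 % unstratified vs. centred near 50 % stratified).  Plain random
folds remain available (`stratified=False`, `kfold_split`).

The rate metrics are reported in two conventions.  `sensitivity_paper` =
TN/(FP+TN) and `specificity_paper` = TP/(TP+FN) follow the printed formulas
of the source method exactly (they swap the conventional definitions);
`sensitivity_std`/`specificity_std` are conventional.  Accuracy is
(TP+TN)/total.  Zero-denominator metrics are NaN, never exceptions.

ROC is computed on the pooled out-of-fold scores by threshold sweep, AUC by
trapezoid; it equals the Mann–Whitney pairwise probability (ties ½), which
the tests verify against a brute-force oracle.  The report carries per-fold
confusion counts, mean-of-fold accuracy (the headline number) and
pooled-count metrics.

**Caveat — segment-level splitting.**  Random segment-level folds let
segments of one subject appear in both training and test sets, a known
source of optimism for clinical claims; with overlapping windows adjacent
segments even share samples (measured: ~60 % "null" accuracy with
half-overlap).  The validity checks below therefore use non-overlapping
windows; subject-level grouping is the right protocol for any real clinical
evaluation.

## Synthetic data generator

The generator emulates the *statistical structure the method exploits*, not
physiological ASD EEG.  Each channel is a sum of band-limited Gaussian
noise for delta/theta/alpha/beta/gamma with a 1/f-like weight profile
(1.0/0.8/0.7/0.5/0.35) and a slow (~0.3 Hz) random amplitude envelope per
band — real rhythms wax and wane, and the resulting super-Gaussian
marginals keep ICA identifiable.  For the autistic class the alpha, beta
and gamma envelopes are raised to the power (1 + effect_size), sharpening
sustained activity into sparse bursts.  Burstiness concentrates the
histogram of the D2–D4 coefficients and lowers their Shannon entropy
monotonically with effect size (~2 bits mean drop at effect 2; 6–8 pooled
standard errors of class separation) while every band's variance stays at
unity — so the class signal lives in distribution *shape*, invisible to
variance-type features.  At effect 0 both classes come from the identical
distribution.  Optional blink transients (300 ms positive bumps, 16× 
stronger on FP1/FP2/F7/F8) exercise the ocular stage.

Default cohort shape mirrors a small clinical dataset: 10 normal + 9
autistic subjects, 16 channels, 256 Hz, per-subject durations from fixed
profiles (normal 5–27 min, 148 min total; autistic 12–40 min, 173 min
total — hence 321 one-minute non-overlapping segments).  All randomness
derives from one master seed via a named substream per (class, subject).

What passing tests on this generator do **not** show: robustness to real
artifacts, electrode noise, inter-subject physiological variability, or any
clinical validity of the entropy biomarker.  They show the pipeline's
machinery is correct and that it recovers a known subband-complexity
difference at realistic SNR while staying at chance when none exists.

## Study sizes used by the validity checks

The end-to-end checks (tests and `scripts/acceptance.py`) run at desk
scale: strong effect 8+8 subjects × 300 s (80 one-minute segments), null
11+11 subjects × 600 s (220 segments, more because the chance-level
estimate is noisier than the strong-effect one).  Under the null, cross-validated
accuracy has model-level variance well beyond binomial (measured std
≈ 3.5 % even with i.i.d. features), so the acceptance script averages a
few replicate datasets; the pass bands themselves (≥ 90 % strong, 50 ± 10 %
null) are fixed.

## Numerical choices and degenerate inputs

- Histogram of a constant array → single bin, p = [1]; all entropies 0.
- `threshold_entropy` uses strict inequality (0.2 itself does not count).
- Segment-count arithmetic guards exact multiples with a 1e-9 tolerance.
- Softmax and sigmoid are computed in overflow-safe form.
- Non-finite samples at load time are rejected by default;
  `repair="linear"` interpolates isolated NaNs instead.
- Zero-scale features (constant across training data) get scale 1 in the
  z-score, leaving them inert rather than dividing by zero.

## Known limitations

- Segment-level CV (see caveat above) matches the reference protocol but
  flatters any subject-specific signal; subject-grouped splitting is
  provided for honest clinical estimates.
- The printed sensitivity/specificity formulas are implemented verbatim
  under `*_paper` names; downstream consumers wanting conventional
  definitions must read the `*_std` fields.
- EDF files are read, not written; the simulator emits CSV matrices plus a
  manifest.
- The ANN has no regularisation beyond early stopping and small capacity;
  it is the reference architecture, not a competitive modern classifier.
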