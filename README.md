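# eegcad

Computer-aided two-class classification of resting-state EEG (autistic vs.
normal) from subband entropy: discrete wavelet decomposition, entropy and
moment features, and a small feed-forward neural network, evaluated by
10-fold cross-validation.  The package is aimed at researchers studying
EEG complexity biomarkers who need a tested, reproducible reference
implementation of this classical pipeline — including a synthetic
two-class EEG generator, so every stage and the end-to-end experiment run
without access to clinical data.

## Method

For each recording (16 channels in 10–20 placement, 256 Hz):

1. **Preprocess** — zero-phase elliptic band-pass 0.1–60 Hz (order 4,
   0.2 dB ripple, 40 dB stopband), optional 60 Hz notch, optional ICA
   ocular-artifact removal referenced to FP1/FP2/F7/F8.
2. **Segment** — fixed windows of length *L* (default 60 s), step
   *L*·(1 − overlap), trailing partial windows discarded.
3. **Decompose** — 4-level DWT with db4 per channel: details D1…D4 and
   approximation A4; at 256 Hz, D_k spans (256/2^(k+1), 256/2^k) Hz and A4
   spans 0–8 Hz.
4. **Extract features** — one function per experiment on each selected
   coefficient array (default Shannon entropy on D1–D4).  With occupied
   histogram-bin probabilities *p_i* (256 equal-width bins over the
   array's range):
   - Shannon  H = −Σ p_i log₂ p_i
   - Rényi   H = (1 − α)⁻¹ ln Σ p_iᵅ  (default α = 2)
   - log-energy H = Σ ln p_i²
   - threshold  #{ i : |x_i| > 0.2 }
   - moments: mean, std, variance, skewness, kurtosis
5. **Classify** — network with 5 log-sigmoid hidden units and 2-unit
   softmax output on z-scored features, full-batch gradient descent with
   momentum.
6. **Evaluate** — stratified 10-fold cross-validation at segment level;
   sensitivity/specificity/accuracy from pooled confusion counts (in both
   the source method's printed convention and the conventional one), ROC
   and AUC on pooled out-of-fold scores.

See `docs/methods.md` for assumptions, parameter rationale and what the
synthetic generator does and does not emulate.

## Worked example

```python
import numpy as np
from eegcad import (SyntheticSpec, generate_dataset, extract_features,
                    run_cross_validation)
from eegcad.config import load_config

spec = SyntheticSpec(n_subjects_per_class=4, duration_s=300.0,
                     effect_size=2.0, seed=7)
recordings = generate_dataset(spec)          # 4 normal + 4 autistic subjects
cfg = load_config(None, {"segment": {"overlap": 0.0}})
features = extract_features(recordings, cfg)
report = run_cross_validation(features, k=10, seed=7)
print(f"{len(recordings)} recordings -> {len(features)} segments of 60 s")
print(f"mean 10-fold CV accuracy: {report.mean_accuracy:.1f}%")
print(f"pooled AUC: {report.auc:.3f}")
m = report.pooled_metrics
print(f"sensitivity/specificity (conventional): "
      f"{m['sensitivity_std']:.1f}% / {m['specificity_std']:.1f}%")
```

Output:

```
8 recordings -> 40 segments of 60 s
mean 10-fold CV accuracy: 95.0%
pooled AUC: 0.995
sensitivity/specificity (conventional): 100.0% / 90.0%
```

The generator plants a class difference in subband complexity: the
autistic class's alpha/beta/gamma activity arrives in sparse bursts, which
lowers the Shannon entropy of the D2–D4 wavelet coefficients while leaving
band power unchanged.  An accuracy near 100 % therefore means the pipeline
recovered the planted complexity difference; at `effect_size=0` the same
pipeline stays at chance (~50 %).

## Command line

```sh
eegcad simulate --out data/                     # synthetic dataset + manifest
eegcad extract  --manifest data/manifest.csv --out features.csv
eegcad train    --features features.csv --out model.json
eegcad evaluate --features features.csv --out-dir results/ --roc-plot
eegcad sweep    --manifest data/manifest.csv --out sweep.csv \
                --lengths 30,60 --overlaps 0,0.5 --selections "D1,D2,D3,D4"
```

Each command archives its resolved configuration beside its outputs.
Recordings may be EDF files or CSV matrices (header row of channel names,
one column per channel; sampling rate given in the manifest or via
`--fs`).

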