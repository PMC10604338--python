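# mcheart

Multi-channel phonocardiogram (PCG) processing and heart-murmur detection.

Auscultation recordings contain two fundamental heart sounds per beat — S1
and S2 — while murmurs are broadband noise confined to the systolic and
diastolic intervals between them. `mcheart` separates these components and
classifies recordings with a light residual CNN:

1. **Boundary detection.** Each recording is amplitude-normalized
   (s / max|s|), low-pass filtered (zero-phase Butterworth, 150 Hz, order 2),
   and reduced to its Hilbert envelope En. A threshold
   `Thsh = mean(En) + std(En)` splits the envelope into a binary
   fundamental-heart-sound mask: samples at or above the threshold are S1/S2
   lobes, the remainder is the systolic/diastolic murmur channel, with
   `fhs + murmur = envelope` exactly. A causal moving average (window 70
   samples) can be applied to the envelope first, which stabilizes the
   murmur channel.
2. **Multi-channel features.** Log-mel spectrograms
   (`Mel(f) = 2595 log10(1 + f/700)`, Hamming-window STFT, dB relative to
   the recording's global maximum) of the raw signal and of the separated
   envelope channels are stacked, together with the mean interval between
   prominent envelope peaks — murmurs add peaks, so murmur-free recordings
   have longer intervals.
3. **ReLCNN classifier.** A light CNN with max-feature-map activations
   (channel-pair max, halving 2f maps to f; filters 32, 32, 48, 48, 64, 64,
   32, 32, 32), three residual connections, trainable-slope Swish, and
   8-head self-attention over time frames, ending in a 2-way softmax.
   Training is per-recording (single-instance) with mixup/cutout
   augmentation, class weight 3 on the murmur-present class, Adam, and a
   sigmoid-decay learning rate from 1e-3 to 1e-5.
4. **Patient-level scoring.** A patient's probability is the maximum over
   auscultation sites (AV/PV/TV/MV). A probability band (t_low, t_high),
   fitted by grid search to maximize the weighted accuracy of the training
   patients, carves the three-way Present / Unknown / Absent decision out of
   the binary model. Weighted accuracy scores the 3x3 confusion with expert
   weights 5 (Present), 3 (Unknown), 1 (Absent).

Because the public murmur corpora need a large download and undisclosed
splits, the package ships a synthetic-cohort generator (`mcheart.synthetic_pcg`)
that emits the same WAV / metadata-txt / segmentation-TSV dialect with known
ground truth, so every stage is testable at desk scale.

## Worked example

```python
from mcheart import run_pipeline

result = run_pipeline(n_patients=60, prevalence=0.3, seed=1, epochs=10)
rep = result["report_validation"]
print("validation weighted accuracy:", round(rep["Weighted Acc"], 3))
print("best constant predictor     :", round(result["best_constant"], 3))
print("AUROC:", round(rep["AUROC"], 3), " band:", rep["band"])
print("confusion:", rep["confusion"])
```

prints

```
validation weighted accuracy: 1.0
best constant predictor     : 0.781
AUROC: 1.0  band: [0.75, 0.75]
confusion: [[5, 0, 0], [0, 0, 0], [0, 0, 7]]
```

i.e. on a fresh 60-patient synthetic cohort (30% murmur prevalence) the
trained pipeline separates the 12 held-out validation patients perfectly
(confusion rows/columns ordered Present, Unknown, Absent), while the best
constant prediction for that cohort would score only 0.781. The fitted
band [0.75, 0.75] means patients with aggregated probability >= 0.75 are
called Present and the rest Absent (an empty Unknown band — the synthetic
cohort has no Unknown patients).

The same pipeline is available from the shell:

```bash
mcheart simulate --n 200 --prevalence 0.19 --seed 7 --out data/
mcheart split --data data/ --train-frac 0.8 --seed 0 --out split.json
mcheart featurize --in data/ --feature-id 9 --out features.npz
mcheart train --manifest data/ --out run/ --epochs 15 --seed 0
mcheart evaluate-run --run run/ --data data/ --split validation --report report.json
mcheart smoke --seed 1 --out smoke/        # full end-to-end demonstration
```

Feature combinations are selected by id (`--feature-id`); id 9 =
spectrogram + peak interval + smoothed murmur channel, the best-performing
combination. Ablation flags `--no-mha`, `--heads`, `--activation
{none,relu,swish}` build the structural model variants.

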