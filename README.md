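# gliaquant

Quantification pipelines for multi-modal studies of microglia–neuron
interactions in the mouse brain. The package re-implements, as one tested
library, the bespoke measurement procedures such studies chain together:

- **smFISH / RNAscope** (`gliaquant.smfish`) — nuclei-seeded cell
  segmentation (blur → threshold → close holes → dilate → watershed),
  per-cell transcript puncta counts in two modes (3D connected components,
  or prominence-filtered maxima on a background-subtracted projection),
  supervised x̄ ± 2σ intensity thresholds, molecule-count positivity rules
  (≥ 3 or ≥ 5 molecules per cell), co-expression proportions and
  expression regressions.
- **Fiber photometry** (`gliaquant.photometry`) — isosbestic correction by
  least-squares affine fit of the 405-nm control to the 465-nm signal,
  ΔF/F = signal − fitted control, z-scoring, two-stage MAD-rule calcium
  transient detection (exclude samples > median + 2·MAD, then peaks >
  median + 3·MAD within a 600-s window), and per-epoch event frequency /
  amplitude / AUC summaries split by zeitgeber phase.
- **Circadian wheel running** (`gliaquant.circadian`) — double-plotted
  actograms and activity-period estimation by grid-search harmonic
  regression: for each candidate period τ the normalized counts are fitted
  with a·sin(2πt/τ) + b·cos(2πt/τ) + c and the τ with minimal residual sum
  of squares is reported.
- **EEG/EMG telemetry** (`gliaquant.eeg`) — zero-phase band-pass filtering
  (EEG 0.3–50 Hz, EMG 10–100 Hz), 5-s-epoch spectral features, the strict
  > 10 %-of-epoch > 0.4 mV artifact rule, rule-based Wake/NREM/REM
  staging, bout statistics and microwake counts, the wake low/high theta
  (5–7 / 7–9 Hz) ratio, modified-Racine seizure outcome scoring with
  20-min censoring, and log-rank group comparisons of GTC incidence and
  mortality.
- **3D morphometry** (`gliaquant.micromorph`) — signed anisotropic
  Euclidean distances between synaptic puncta and microglia surfaces with
  the ±0.07 μm contact band (interior objects beyond the band are
  engulfed), voxelwise colocalization, Sholl profiles on physical shells,
  and structure-tensor dominant-orientation analysis.
- **snRNA-seq QC and DEGs** (`gliaquant.exprfilter`) — per-cell retention
  rules (500–5,000 detected genes, 1,000–30,000 UMIs, < 2.5 %
  mitochondrial reads, log10(genes)/log10(UMIs) > 0.8),
  Benjamini–Hochberg adjustment, and the |log2FC| ≥ log2(1.2) ∧ FDR < 0.05
  significance call.
- **Synthetic data** (`gliaquant.syndata`) — generators for all six
  modalities with recorded ground truth (cell masks and puncta counts,
  transient times and amplitudes, true activity period, true hypnogram and
  seizure intervals, true signed contact distances, QC pass flags and DE
  genes), so every stage is verifiable without animals or raw recordings.

## Worked example

Recover a free-running circadian period from two weeks of synthetic wheel
running in constant darkness, and detect calcium transients in a synthetic
photometry session:

```python
import numpy as np
from gliaquant.syndata import (WheelSpec, gen_wheel_activity,
                               PhotometrySpec, gen_photometry)
from gliaquant.circadian import estimate_period
from gliaquant import photometry

series, truth = gen_wheel_activity(
    WheelSpec(days=14, schedule="DD", period_h=25.1, seed=42))
est = estimate_period(series)
print(f"true period: {truth['period_h']} h")
print(f"estimated:   {est.period_h:.2f} h  (R^2 = {est.r_squared:.3f})")

rec, gt = gen_photometry(PhotometrySpec(
    duration_s=1320, n_transients=10, amplitude=0.25, noise_sd=0.02, seed=42))
fitted, (a, b) = photometry.fit_control(rec)
trace = photometry.compute_dff(rec, fitted)
events = photometry.detect_transients(trace)
print(f"isosbestic fit: signal ~ {a:.2f} x control + {b:.2f}")
print(f"detected {len(events.times_s)} transients (10 injected)")
```

prints

```
true period: 25.1 h
estimated:   25.09 h  (R^2 = 0.674)
isosbestic fit: signal ~ 1.89 x control + 10.54
detected 10 transients (10 injected)
```

The period estimate lands within one grid step of the generating 25.1-h
rhythm; the affine coefficients recover the drift map linking the two
photometry channels (the small departures from the generating a = 2,
b = 10 reflect channel noise); all ten injected transients are found with
no false events.

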