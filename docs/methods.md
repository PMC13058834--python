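# Methods

This note documents the measurement models implemented in `gliaquant`,
the defaults that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the procedures left room.

## smFISH quantification

Cells are defined by their nuclei: the DAPI channel is Gaussian-blurred
(σ = 1 voxel), thresholded (Otsu by default; a fixed threshold is
accepted), binarized, hole-filled, dilated by 2 voxels in x/y (0 in z, so
the ROI reaches into the perinuclear cytoplasm where transcripts sit),
split by a watershed seeded from smoothed maxima of the anisotropic
distance transform, labelled, and size-filtered (≥ 60 voxels). The
distance transform is computed in x/y-pixel units (z rescaled by the
pitch ratio) and smoothed at σ = 2 px before seeding, with seeds at least
10 px apart; without this, the flat-in-z plateau of a nucleus yields many
spurious seeds and over-segmentation. Each labelled ROI is one cell.

Puncta counting has two modes mirroring two common workflows:

- **cc3d** — 26-connected components of voxels above an intensity
  threshold, assigned to the cell containing the component centroid.
  Suited to full 3D stacks where each transcript is a compact bright blob.
- **maxima** — on a maximum-intensity projection: three rounds of 3×3
  median despeckling, rolling-ball background subtraction (radius 10 px),
  then h-maxima with h equal to the prominence parameter (typical
  600–1000, the lowest punctum intensity in a dataset). A peak of
  prominence below h — e.g. a 550-intensity spot against a flat
  background with h = 600 — is not counted.

Positivity is assigned either by molecule-count floors (≥ 3 molecules for
a sparsely expressed receptor transcript, ≥ 5 for abundant cell-type
markers; the comparison is inclusive) or by supervised intensity
thresholds: the mean and *sample* (n−1) standard deviation of ~10
visually classified reference cells give mean + 2σ when the references
are negative (cells above are positive, strict) and mean − 2σ when the
references are positive (cells at or above are positive). Counts are the
default classification currency; intensity rules exist for protocols
where per-cell mean intensity was the measured quantity.

Co-expression is reported as the percentage of anchor-positive cells also
positive for a second marker; with zero anchor-positive cells the
proportion is *missing*, never 0 %. Group means of per-cell counts and
fold changes over a named control group support enrichment-style
comparisons. Expression regressions are ordinary least squares with an
SE-based z test for slope differences.

## Fiber photometry

The 405-nm isosbestic channel captures calcium-independent variance
(motion, bleaching) shared with the 465-nm signal. The model is affine:
fitted control = a·control + b by least squares, and
ΔF/F = signal − fitted control (a subtraction, as in the source
workflow; divide-by-fitted is available but not default). The z-score is
(ΔF/F − mean)/SD over the analyzed trace; normalization is per analysis
window/epoch, the natural unit here, and callers may pass whole
recordings instead. Note that the affine fit propagates control-channel
noise into ΔF/F scaled by a, so the ΔF/F noise floor is
σ·√(1 + a²) for independent per-channel noise σ.

Transient detection is the two-stage MAD rule on 600-s windows: samples
above median + 2·MAD are excluded when forming reference statistics, and
peaks above reference median + 3·MAD are events. The MAD is unscaled (no
1.4826 factor). Two numerical choices make the rule usable on sampled
traces:

- peaks are located on a 0.25-s moving-average-smoothed copy — the raw
  3·MAD level sits near 2 SD for Gaussian-like noise, which any broadband
  trace crosses constantly; the acquisition chain low-pass filters the
  demodulated signals, and peak-picking a smoothed copy expresses the same
  assumption. Threshold statistics stay on the raw ΔF/F, and each event's
  time and amplitude are refined to the raw-trace maximum within the
  smoothing span, so a noise-free transient is located to the exact
  sample.
- a peak must also have prominence ≥ 3·MAD, which stops noise maxima
  riding on a transient's decay shoulder from registering as separate
  events. A minimum inter-event separation of 0.5 s applies; MAD = 0
  (constant trace) yields no events.

Epochs of 11 min are hard-trimmed to their final 600 s before any
statistic (the first minute carries tethering artifacts). Frequency is
events per minute over the analyzed span, amplitude the largest event
peak, AUC the trapezoid integral per 10-min bin. Phase aggregation maps
ZT hours 0–11 to the light phase and 12–23 to the dark phase.

## Circadian period

Counts are normalized to the animal's mean activity, and for each τ on a
20–28 h grid at 0.01-h steps the single-harmonic model
y ≈ a·sin(2πt/τ) + b·cos(2πt/τ) + c is fitted in closed form; the τ with
minimal residual sum of squares is reported, ties broken toward smaller
τ. Activity is square-wave-like rather than sinusoidal, but the
fundamental's period is unbiased, which the recovery tests confirm. Grid
search is deterministic and global — no iterative optimizer to trap in a
harmonic. Estimation requires ≥ 3 days of data; residual sum of squares
(equivalently R²) is the fit-quality measure. Actograms are double-plotted
(row d spans days d and d+1) after mean normalization.

## EEG/EMG sleep staging and seizure scoring

Biopotentials are band-pass filtered with zero-phase 4th-order
Butterworth sections (EEG 0.3–50 Hz, EMG 10–100 Hz) and cut into 5-s
epochs. Band powers use Welch periodograms with 1-s segments and 50 %
overlap, integrated over the configured band set: the sleep set (delta
0.5–4 Hz, theta 6–9 Hz — the 4–6 Hz gap is taken as configured) or the
six-band set used for seizure-era spectra (1–4, 4–8, 8–12, 12–30, 30–60,
60–90 Hz). At 1-Hz spectral resolution a tone at a band edge leaks about
one bin across it; tests therefore assert band dominance rather than
total containment.

An epoch is artifact iff strictly more than 10 % of its samples exceed
±0.4 mV on either channel. Staging is rule-based per non-artifact epoch:
high EMG RMS ⇒ Wake; else delta-dominant, high-amplitude EEG ⇒ NREM;
else theta-dominant, low-amplitude EEG ⇒ REM; unresolved epochs inherit
the previous state (first epoch defaults to Wake). The qualitative
criteria need per-recording thresholds: the EEG amplitude split defaults
to the median epoch RMS, and the EMG threshold defaults to an Otsu split
of the log epoch EMG RMS. Muscle tone is strongly bimodal (atonia in
sleep vs. tone in wake), and an occupancy-independent split is essential
— a fixed quantile misclassifies exactly when wake occupancy differs
from that quantile, which it always does across conditions. Both
thresholds are explicit configuration for recordings where derived values
are unsuitable.

Bout statistics are maximal same-state runs; per state and phase (day
ZT 0–11, night ZT 12–23, total) the bout count, mean duration and
percentage coverage are reported, hourly bins included; state coverages
plus artifact coverage sum to 100 % exactly. A *microwake* is a wake bout
of a single 5-s epoch — the shortest wake intrusion representable at this
epoching (the conventional "< 5 s" phrasing is not resolvable at 5-s
epochs). The wakefulness theta ratio is mean 5–7 Hz power over mean
7–9 Hz power across Wake epochs.

Seizure outcomes are scored from typed event annotations on the modified
Racine scale (electrographic spikes 1, myoclonic 3, generalized
tonic-clonic 5, death 6): worst score, GTC incidence, first-GTC latency
censored at the 20-min observation window for event-free animals, summed
GTC duration, and myoclonic count. Events beyond the window are clipped
with a warning. Group comparisons build Kaplan–Meier-based cumulative
incidence curves and the standard two-group log-rank test (lifelines);
for mortality curves death is the event, for GTC incidence the censored
GTC latency is used. A simple amplitude detector (epoch RMS > 5× the
recording median sustained ≥ 10 s) can propose GTC intervals, but
annotations are authoritative.

## 3D morphometry

Volumes are preprocessed by subtracting a large-scale background estimate
(Gaussian-smoothed copy at 53.1 μm, clipped at zero; rolling-ball is the
obvious alternative but the Gaussian is separable and anisotropy-aware)
and smoothing at 0.0707 μm; each width is converted to per-axis voxel
units and becomes a no-op on axes whose pitch exceeds it (with a
warning). Surfaces are 26-connected components above an intensity
threshold (default: a multiple of the channel mean), with volumes in μm³
from the anisotropic voxel volume.

Contact classification uses a signed anisotropic Euclidean distance with
a fixed voxel-center convention: for a voxel outside the microglia mask,
the distance to the nearest mask voxel center; for a voxel inside, minus
the distance to the nearest exterior voxel center. A synaptic object's
distance is the minimum over its voxels; it is a contact iff that
distance lies within ±0.07 μm and engulfed if deeper inside. The
convention is shared exactly by the brute-force pairwise oracle used in
tests. One consequence worth knowing: at 70.7 × 70.7 × 311 nm voxels the
smallest nonzero center-to-center distance (70.7 nm) already exceeds the
0.07-μm band, so at that pitch the band resolves only voxel-overlapping
contacts; finer grids resolve it properly. Tools that mesh sub-voxel
surfaces will therefore count somewhat more contacts at the acquisition-scale
pitch than the voxel-center convention does.

Colocalization is the voxelwise AND of two thresholded channels,
componentized and summed in μm³. Sholl profiles count 26-connected
components of the cell mask within concentric shells in physical units;
the shell half-thickness is half the voxel diagonal so a 26-connected
process cannot step over a shell unseen. Dominant orientation follows the
2D structure tensor smoothed with a Gaussian window (σ = 20 px for the
conventional "local window 20"), per-pixel angles in (−90°, 90°]
measured counterclockwise from the horizontal with y up; the histogram is
weighted by the tensor eigenvalue difference (anisotropy energy), the
dominant angle is its mode, and the reported value is the absolute angle.
Images with mean coherence below 0.2 (isotropic or constant) yield an
explicit "no dominant angle" flag.

## snRNA-seq QC and DEG calls

Per cell: detected genes (nonzero rows), UMIs (column sum), mitochondrial
percentage (by gene-name prefix, default `mt-`), and the library
complexity score log10(detected genes)/log10(UMIs). A cell is retained
iff detected genes ∈ [500, 5,000], UMIs ∈ [1,000, 30,000], mito < 2.5 %
(strict) and complexity > 0.8 (strict); a zero-UMI cell fails with an
explicit reason. The complexity score is deliberately the log-over-log
genes-per-UMI metric of the standard single-cell QC workflow: the raw
ratio genes/UMI never exceeds 1, so a log10 of it can never clear 0.8 —
the log-log form is the only reading under which the rule filters rather
than deletes. The filter is idempotent and monotone in every threshold.

P-values are Benjamini–Hochberg adjusted (statsmodels step-up;
Bonferroni available through the same statsmodels interface), and a gene
is differentially expressed iff |log2FC| ≥ log2(1.2) ≈ 0.263 and adjusted
p < 0.05, with direction from the sign of log2FC. The differential test
itself (e.g. a hurdle model run upstream) is out of scope; the module
consumes per-gene effect sizes and p-values.

## Synthetic data: what it emulates, and what it does not

Each generator is deterministic given its seed; per-object RNG streams
are derived from (seed, object index) so adding objects never reshuffles
earlier ones, and every injected observable is recorded in the returned
ground truth.

- **smFISH volumes** — ellipsoidal nuclei (semi-axes 3.5 μm in x/y,
  2.0 μm in z, matching hippocampal pyramidal-layer nuclei at a 60×
  field) with disjoint x/y footprints, optionally with touching pairs
  overlapping by 1–2 voxels to exercise watershed splitting; puncta are
  3D Gaussian spots (σ = 1.5 px) max-composed onto the background so the
  center voxel equals the stated peak exactly, spaced ≥ 8 px in x/y so
  neither thresholded components nor projected maxima merge. No optical
  PSF, no chromatic offsets, no tissue autofluorescence.
- **Photometry** — a shared polynomial drift in both channels linked by a
  fixed affine map, exponential-decay transients (τ = 1.5 s) at least 5 s
  apart injected into the signal only, and white per-channel noise.
  Recordings shorter than the 600-s window warn when transients are
  requested. No hemodynamic artifacts, no bleaching asymmetry between
  channels.
- **Wheel running** — Poisson counts around a raised-cosine nightly
  profile confined to the dark phase (LD, entrained at 24.0 h) or the
  subjective night of the stated free-running period (DD). Peak rate
  defaults to 30 rotations/min. No activity onsets drifting within a
  night, no nap structure.
- **EEG/EMG** — a Markov chain over Wake/NREM/REM at 5-s resolution;
  per state, EEG is Fourier-domain band-weighted white noise (NREM
  delta-heavy at 0.15 mV RMS, REM theta-heavy at 0.05 mV, Wake broadband
  at 0.05 mV) and EMG is 10–100 Hz noise at state-specific RMS (0.08 mV
  awake, 0.01 mV asleep), with ~10 % lognormal epoch-to-epoch RMS
  jitter. Square-pulse artifact segments and a 6-Hz high-amplitude GTC
  interval can be injected, with sample indices recorded. Epochs are
  synthesized independently (no spectral continuity across boundaries)
  and no real EEG microstructure (spindles, K-complexes, transitions) is
  modelled — passing staging tests shows the rules separate the stated
  band/amplitude profiles, not that they score real mice.
- **Microglia scenes** — branched tubes rasterized from polyline
  skeletons at the stated anisotropic pitch; single-voxel puncta placed
  at the voxel whose signed distance best matches the request, recording
  both requested and achieved distance (requests below half the largest
  pitch warn that discretization dominates).
- **Count matrices** — compliant cells are constructed directly inside
  the QC retention box; each planted violator breaks exactly one rule.
  DE genes are injected by Poisson thickening (up) or binomial thinning
  (down) in one group, keeping counts integer with the stated expected
  log2FC. No doublets, no ambient RNA, no batch structure.

## Problem sizes in tests and the acceptance script

Recovery tests use 14-day wheel series, 22-min photometry sessions
(10 seeds), 1–2-h EEG recordings (5 seeds), 20-cell smFISH fields,
64³-scale contact scenes, and matrices of a few thousand genes by tens of
cells — sizes at which every stochastic criterion is comfortably
resolved while the full suite runs in well under a minute of compute per
module. The acceptance script reports the period of a single 14-day
entrained series at the default generator conditions..

## Known limitations

- The staging rules have no transition constraints (e.g. REM entered only
  from NREM); they score epochs independently apart from inheritance of
  unresolved epochs.
- The contact band at acquisition-scale voxel pitch resolves only overlap-level
  contacts under the voxel-center convention (see above).
- `coexpression_summary` and the regression utilities expect tidy
  per-cell tables and do not model within-mouse nesting; mouse-level
  averaging is the caller's responsibility.
- EDF ingestion is not provided; EEG/EMG enter as arrays or CSV columns.
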