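# Methods

This note documents the models, conventions and design choices behind
`microsep`: the synthetic recording generator, the preprocessing and
analysis conventions, the decoder, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer from the code.

## Time base and marks

The canonical time unit is **samples at 6,103.52 Hz**; millisecond values
are labels. Per stimulus trigger `t_trig`:

| mark | offset | meaning |
|---|---|---|
| `t_stim` | +16 samples (≈2.6 ms) | stimulus arrival (artifact time) |
| `t_init` | +50 | earliest decode sample; clears the 5.2 ms artifact guard |
| `t_full` | +250 | end of the full-length window (200 samples ≈ 33 ms) |
| baseline | −598…0 | 98 ms pre-trigger baseline window |

Windows are half-open `[start, end)`, indices 0-based. The array plane uses
x increasing rightward (lateral→medial) and y increasing downward
(anterior→posterior), in micrometres; the 800 × 513 canvas is a frozen
uniform-scale affine placement of the plane (origin top-left).

## Array geometry

96 channels in three patches (A, B, C) of 32, each 8 columns × 4 rows at
700 µm pitch with 350 µm contacts. The patch dimensions are not dictated by
the recording hardware alone; 8 consecutive columns were chosen so that the
five finger foci (700 µm apart) can sit on actual contact columns of the
middle patch. Patches are laid left to right with a default inter-patch gap
of one patch width. Two channels (ids 5 and 70 by default, configurable)
are broken; one configurable "overlapping" contact at the A/B seam is
additionally excluded from spatial interpolation only.

## Synthetic recording model

Each non-broken channel's noiseless response to one stimulus is the sum of
two components, both with compact support (exactly zero outside it):

**Main complex** — a Hann-windowed ≈45 Hz cycle peaking at
`main_peak_ms` (default 19 ms post-stimulus, support 12–26 ms), plus a
Hann-windowed ≈140 Hz high-gamma burst at `hg_rel_amp` (0.35) relative
amplitude; the sum is normalized so the on-centre peak equals
`amp_peak_uv` (300 µV at 4 mA). Spatial weight is Gaussian,
`exp(−d²/2σ²)` with σ = `spatial_sigma_um` = 600 µm, measured to a
finger-specific source centre that drifts posteriorly at
`drift_um_per_ms` (50 µm/ms) and crosses its nominal centre exactly at the
peak time. Nominal centres are 700 µm apart on row 2 of patch B, ordered
D1→D5 lateral→medial.

**Early (sulcal) component** — one Hann-windowed sine cycle,
`−sin(2πu)·sin²(πu)` on `[onset, onset + 1.5·(peak−onset)]`
(defaults: 9–13.5 ms). This shape was chosen for three reasons:
its extrema fall at exactly u = 1/3 and 2/3, so the positive lobe peaks
exactly at `early_peak_ms` (12 ms); its integral is zero, so slow
(drift-like) rest noise barely projects onto it and the amplitude code
stays readable at matched-filter level; and its support ends before the
main-complex peak, so the on-centre peak amplitude remains exactly
`amp_peak_uv`. The component has one shared topography — Gaussian with
σ = `early_sigma_um` = 1000 µm (wider than the superficial foci, as
expected of a deeper generator) centred on a medial patch-B contact —
and a finger-specific amplitude ladder `early_amp_uv` =
(250, 325, 400, 475, 550) µV at 4 mA.

**Intensity** scales both components multiplicatively by
`intensity_gain` = 0.4 for 1 mA. The ladder and gain together place the
ten condition levels on the shared early template at least 30 µV apart
(worst case, including the 1 mA/4 mA crossover), about five matched-filter
standard deviations under the rest-noise model below. This is the designed
mechanism by which decoding from short (≤15 ms) windows and from single
channels is solvable; the main complex alone would leave adjacent-finger
1 mA conditions ambiguous at a single contact.

**Artifact** — a ±`artifact_amp_uv` (1000 µV) two-sample biphasic spike at
`t_stim` on all non-broken channels.

**Noise** — per channel, a white component plus a slow component mixed as
`noise_rms_uv`·(√(1−f)·white + √f·slow) with f = `slow_noise_fraction` = 0.5.
The slow component is a stationary AR(1) process (coefficient 0.97,
≈30 Hz bandwidth) built from a shared and an independent stream so that its
inter-channel correlation is `noise_spatial_corr` = 0.3. The mix is
calibrated so the rest-segment RMS is ≈18 µV per channel. Broken channels
carry 50 µV wide-band noise and no evoked component. Stimuli are presented
in contiguous per-condition blocks (200 trials each by default) at 305 ms
intervals; the whole recording is reproducible bit-for-bit from the seed.

**What the generator does not emulate.** Channel-to-channel gain and noise
heterogeneity (the synthetic inter-channel RMS spread is ≈0, where real
arrays show a wide spread), anatomy (sulcal curvature is flattened away by
construction), anesthesia-state fluctuations, trigger-timing corruption,
1/f broadband structure beyond the single AR(1) pole, and any nonlinearity
between stimulus intensity and response shape. Passing tests therefore
demonstrate the *pipeline's* correctness and sensitivity under a controlled
model — not that real recordings of this kind would decode at these
accuracies.

## Preprocessing conventions

Order of operations is CAR → baseline correction → epoching → feature
construction → z-scoring. The CAR set defaults to all 96 channels,
including broken ones (the raw signal is re-referenced before dead channels
are dropped); both choices are configurable. CAR and baseline correction
are linear mean-subtracting maps and commute. Decode trials are the first
100 per condition, in chronological order (1,000 total, balanced).

**Z-scoring.** Features are converted to z-scores using all-sample
statistics computed over train and test together, deliberately reproducing
the published procedure rather than fold-safe practice. Two readings of
"the all-sample mean and standard deviation" exist: one global scalar pair,
or one pair per feature column. The default is the **global** reading: it
is a single affine rescaling of the feature space, which leaves the SVM
solution (and hence the reported accuracies) invariant — consistent with a
z-scoring step that is a units convention rather than a re-weighting.
Per-column scaling remains available (`zscore_features(..., mode="columns")`)
but re-weights strong-signal features downward and demonstrably degrades a
linear SVM on data whose information content (checked by matched filter and
LDA) is intact. A fold-safe mode (`standardize="fold"` on the decoder) is
provided and is not the default.

## SEP analysis

Averaging is the pointwise mean per condition. The Morlet transform uses
ω₀ = 6 (as the pywt wavelet `cmor2.0-0.9549…`), 30 log-spaced analysis
frequencies over 10–1,000 Hz, and per-frequency normalization by the mean
pre-stimulus power of the same epoch. Band power uses, by default, a
zero-phase 4th-order Butterworth band-pass followed by the mean square over
the 33 ms window after `t_init` (deterministic, no window heuristics); a
periodogram-integral estimator is provided as well and is the one that is
exactly additive across disjoint bands. Rest noise is the RMS of 598-sample
segments starting 100 ms before `t_stim`, mean-zeroed per segment, averaged
over stimuli.

Note one deliberate property of the synthetic data: because the early
component carries a large amplitude code, the 80–200 Hz band maximum
co-locates with the maximum of the raw voltage amplitude (which may be the
early source's contact rather than the stimulated finger's focus). The
high-gamma map is therefore validated against the raw-amplitude map, which
is the physiologically meaningful statement.

## Spatial mapping and COG

Interpolation is linear barycentric on the Delaunay triangulation of the
used contacts' canvas pixels, with no extrapolation outside the hull.
(Natural-neighbour interpolation would be the closest classical analogue of
the original analysis; no maintained implementation exists in this
package's dependency set, and for these regular layouts the barycentric
interpolant agrees with it at the contacts and along edges. The oracle
tests compare against a brute-force evaluation of the same barycentric
form.) The per-frame COG is the voltage-weighted mean pixel coordinate
over pixels at or above the +150 µV threshold, undefined when no pixel
reaches it; COG is translation-equivariant and invariant to uniform
voltage scaling that preserves the threshold set. A `CanvasInterpolator`
precomputes barycentric weights once, so a 600-frame sequence is 600
sparse mat-vecs; frames can be exported as a PNG stack.

## Decoder

One-vs-one linear soft-margin SVM (libsvm via scikit-learn) with vote
aggregation; voting ties resolve to the lowest class index. Fold
assignment is one seeded global shuffle followed by contiguous folds of
100; stratification is monitored, not enforced. C defaults to 1 for
time-series features and 0.1 for single-time-point features; the sweep
grid is 20 log-spaced points in 10⁻¹⁰…10². For wide feature matrices the
linear kernel is precomputed once as a Gram matrix and sub-indexed per
fold, permutation replicate, and growing-window step (rank-one updates),
which is algebraically identical to refitting on raw features. The
subsampling analyses re-split CV folds with derived seeds on every channel
draw. The merged-channel analysis uses the 10-sample window starting 86
samples after `t_stim` — the printed sample count is taken as canonical
where the paired millisecond label disagrees — and a dyadic per-patch merge
scheme (3 → 6 → 24 → 94 groups) with broken channels removed.

## Problem sizes used in the shipped checks

The test suite exercises the full study geometry throughout; unit and
property tests run on a 30-trials-per-condition session, and the end-to-end
checks (chance control, decoding anchors, parameter recovery) run once on a
full 200-trials-per-condition session shared across tests. The spatial
subsampling monotonicity check uses a 5 × 5 grid of (N, T) cells with 5
channel draws per cell — a reduced version of the full 19 × 40 × 30 grid,
which remains available through `spatial_subsampling_grid`'s defaults.

## Known limitations

* The generator's separability is designed, not derived from tissue
  biophysics; absolute accuracies on synthetic data say nothing about new
  real recordings (see the emulation caveats above).
* Natural-neighbour interpolation is approximated by the barycentric
  interpolant (differences are confined to triangle interiors).
* The pooled (train+test) z-scoring leaks scale information by
  construction; use `standardize="fold"` for honest generalization
  estimates on real data.
* `frame_sequence` at full canvas resolution over 600 frames allocates
  ≈1 GB; use `step`, a narrower span, or the chunked COG path.
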