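# Methods

## Scope and data model

`cmcoh` implements a task-based corticomuscular coherence (CMC) analysis
for trial-structured grip recordings: synchronized high-density EEG
(256-electrode geodesic layout, 194 scalp electrodes retained) and surface
EMG from four upper-extremity muscles per arm, sampled at 1,000 Hz with
stimulus-onset event markers. Structural measures — percent corticospinal
tract (CST) injury and tract fractional anisotropy (FA) — enter as given
per-subject scalars; the package does not compute them from images, and it
does not implement ICA artifact removal (externally cleaned recordings are
injected through the `precleaned` hook).

Sample indexing is 0-based and all windows are half-open `[start, end)`.

## Preprocessing chain

1. **EEG bandpass** 0.5–50 Hz, zero-phase (forward–backward) Butterworth,
   default order 4 per pass. Zero-phase filtering preserves EEG–EMG
   relative timing, on which cross-spectral phase depends; the doubled
   effective order gives <1 dB passband ripple and >40 dB attenuation one
   octave outside the edges.
2. **Common-average re-reference** over the retained EEG channels. The
   reference scheme is configurable; common average is the conventional
   choice for high-density nets.
3. **Hjorth surface Laplacian**: `out(c) = in(c) − mean(in(neighbors(c)))`,
   a geometry-free spatial high-pass that sharpens local cortical activity.
   The packaged neighbor graph is built from the standard GSN HydroCel 256
   montage geometry (Delaunay triangulation of an azimuthal projection,
   long rim edges pruned) and is a synthetic stand-in — the actual
   acquisition's adjacency can be supplied as JSON. Spherical-spline
   Laplacians are out of scope.
4. **EMG conditioning**: bandpass (default 10–100 Hz, both edges config
   keys — published passband descriptions for this protocol are ambiguous
   between 10–50 and 70–100 Hz readings, and 10–100 Hz is the widest
   consistent interpretation), then Hilbert analytic-signal magnitude
   (envelope) of the unrectified signal, then rectification — a no-op on
   the nonnegative envelope, kept for fidelity to the conventional order.
5. **Segment cleaning**: the continuous record is cut into 1-s
   non-overlapping segments; segments whose peak EEG amplitude exceeds a
   threshold (default 200 μV) are dropped, and events whose trial window
   overlaps a dropped segment are discarded. This amplitude rule is a
   deliberate stand-in for manual/ICA cleaning; synthetic data is
   artifact-free, so the default pipeline drops nothing.
6. **Epoching**: one epoch per event, 1,000 ms before to 4,000 ms after
   stimulus onset. Events with truncated windows are skipped with a
   warning (zero-padding would bias spectra); zero usable events is an
   error.
7. **Hemisphere flip**: recordings from right-lesioned subjects are
   relabelled so the left hemisphere and right arm always denote the
   ipsilesional hemisphere and affected extremity. ROI electrode lists
   pair positionally left↔right (the midline SMA set maps to itself) and
   EMG sides swap. Only addressing changes — sample values are preserved
   exactly and the flip is an involution.

The chain is fully deterministic; no preprocessing step draws random
numbers.

## Spectral estimation

Magnitude-squared coherence is estimated Welch-style: each epoch's 0–4,000
ms post-onset task window (the pre-stimulus second is retained in the
epoch for future baseline use but excluded from CMC — a grip-task CMC
measures the task period) is cut into non-overlapping 1-s segments; each
segment contributes a Hann-tapered periodogram and cross-periodogram
(per-segment mean removed, one-sided density scaling); spectra are
averaged over all L segments of all trials. 1-s segments give Δf = 1 Hz,
so the bands delta 1–3, low beta 13–19 and high beta 20–30 Hz (inclusive
endpoints) contain exactly 3, 7 and 11 bins. With the default 40 trials,
L = 160.

Pair-level coherence spectra are averaged *as coherences* (not pooled
spectra) across all ROI-electrode × muscle-EMG pairs, then across in-band
bins, yielding the 4 regions × 4 muscles × 3 bands = 48-cell per-subject
table. Coherence is scale-invariant per channel and its magnitude is
invariant to a pure delay of the coupled component; the estimator's
small-sample behaviour under independence is a bias floor of approximately
1/L.

The estimator was cross-checked bin-for-bin against an independent Welch
implementation on contiguous data (agreement to numerical precision with
matching taper and segmentation).

## Synthetic data

The generator's defaults encode the study conditions the pipeline is
designed for: 5-s trials, inter-trial intervals uniform on 7–15 s, two
blocks of 20 trials (40 events), fs = 1,000 Hz, 194 EEG + 8 EMG channels.

**Pair-level (spectral oracle).** A band-limited Gaussian source s(t)
(white noise through the same zero-phase Butterworth family as the
pipeline's filters) drives an EMG trace additively:
`emg = g·s(t−τ) + b(t) + w(t)` with b an independent band-limited
component sharing the source's filter and w white. Because s and b share
one filter, their PSD ratio is flat across the band and coherence has a
closed form at every bin,

    γ²(f) = g²φ_s(f)² / [(φ_s(f)+φ_e)(g²φ_s(f)+φ_b(f)+φ_n)],

with φ the one-sided PSDs (white terms 2σ²/fs, band-limited terms σ²·h(f)
where h integrates to 1). With no white noise this collapses to
γ² = g²σ_s²/(g²σ_s²+σ_b²) at all in-band frequencies regardless of filter
shape. `CouplingSpec.for_target_coherence` inverts the plateau form for
the gain; delays are integer-sample (1 ms at 1 kHz, finer than any
physiological claim here).

**Subject-level (full-pipeline realism).** Raw surface EMG is an
interference pattern whose *amplitude*, not its waveform, carries the
corticospinal drive — and the pipeline's envelope step demodulates
amplitude. Subject recordings therefore model the coupled EMG as a
broadband carrier (band-limited 60–100 Hz) amplitude-modulated by the
delayed source with depth κ = √γ²; other muscles are modulated by
independent signals. Envelope demodulation then recovers in-band coherence
monotone in κ (measured: κ = 0.3/0.6/0.9 → band coherence ≈
0.50/0.73/0.79, delta band at the bias floor), so subject-level checks are
rank-based against the recorded ground-truth γ². The cortical source is
injected into the target ROI's electrodes with a per-electrode spatial
profile drawn from U(0.6, 1.4), so a surface Laplacian attenuates but
cannot cancel it.

**Cohort level.** Percent CST injury is a bimodal mixture — a
mild-moderate truncated-normal component on [0, 50] (mean 13.6, sd 19.3)
and a severe component on [75, 100] (mean 86.8, sd 9.9), mixture weight
11/21 — reproducing the empty 50–75% range characteristic of early
subacute cohorts; FA is normal (0.60, 0.08) truncated to [0, 1] and
missing for a fraction 4/21 of subjects. The structure–function link is
linear on the standardized covariate: γ²ᵢ = clip(μ + s·(ρ*zᵢ +
√(1−ρ*²)ηᵢ)) with μ = 0.35, s = 0.12, range [0.02, 0.90], giving
corr(covariate, γ²) = ρ* in expectation. `generate_cohort_frame` is a
statistics-level fast path that emits covariates joined directly to 48
cell values (null cells lognormal around the 1/L bias floor; planted cells
add estimation noise with sd √(2γ²)(1−γ²)/√(L·n_bins), crediting the
band-bin averaging but not the spatially correlated electrode-pair
averaging), enabling replicate counts the signal-level generator cannot
reach.

What the generator does **not** emulate: volume conduction and realistic
head-model mixing, artifacts (blinks, line noise), nonstationary coupling,
within-trial force dynamics. Passing tests therefore demonstrate
correctness of the estimators and inference on data satisfying the
generative assumptions, not robustness to real-data confounds.

## Statistical layer

Organized as a model/results pair: `CMCCorrelation` holds the cohort frame
and the analysis plan; `fit()` returns `CMCCorrelationResults` with the
per-cell estimates, adjusted p-values, power annotations, `summary()` and
a markdown `report()`.

- **Stratification**: median splits with boundary conventions matching
  their definitions — injury ≤ median is mild-moderate, FA ≥ median is
  high integrity. Degenerate (zero-spread) splits are errors.
- **Normality gate**: Shapiro–Wilk at α = 0.05 on the raw sample; on
  failure, on log(x) when all values are positive (the transformed sample
  is then used); otherwise the rank path.
- **Correlation**: Pearson with t-based two-tailed p when both samples are
  normal(izable); otherwise Spearman with midranks. For n ≤ 9 the Spearman
  p is exact by full enumeration of rank permutations (under ties, of the
  observed midrank vectors); above, the t-approximation. The exact branch
  matters because subgroup sizes (8–11) sit where the approximation is
  weakest.
- **FDR**: Benjamini–Hochberg step-up within each analysis family of 48
  tests (full cohort and each subgroup × covariate are separate families,
  mirroring per-analysis correction); adjusted
  p_(i) = min_{j≥i} m·p_(j)/j, capped at 1.
- **Post hoc power**: achieved power of the two-tailed zero-correlation
  test taking the observed coefficient as the population value. The
  `exact` method numerically integrates the bivariate-normal sampling
  density of the sample correlation (hypergeometric form, log-gamma
  stabilized) over |r| > r_crit with r_crit from the t distribution; the
  `fisher_z` method uses the normal approximation on atanh(r) with SE
  1/√(n−3). Both are reported: at subgroup sample sizes they differ
  visibly (e.g. 0.94 vs 0.92 at r = 0.83, n = 11), and the z-approximation
  runs ~0.02 low against Monte-Carlo at n = 20. Power is strictly
  increasing in |r| and n, and the methods converge as n grows.
- **Exploratory correlations** of significant cells with behavioral scores
  (UEFM, ARAT) are uncorrected and labelled exploratory.
- Missing FA is handled pairwise per analysis; families below a minimum n
  (default 4) are skipped with a logged reason.

## Numerical and design choices

- Coherence values are clipped to [0, 1] against roundoff; bins with zero
  auto-spectrum yield NaN with a warning.
- The EDF writer is minimal (16-bit, 1-s records, per-channel physical
  scaling); events and subject metadata travel in a JSON sidecar rather
  than EDF+ annotation structures. Reading goes through MNE.
- The 62-electrode exclusion list ships as a synthetic stand-in derived
  from standard montage geometry (the 62 most inferior positions); only
  the retained count (194) is a hard invariant, and user-supplied lists
  are accepted.
- Configuration is strict: unknown keys are rejected before any
  computation, and every run writes a provenance sidecar (config hash,
  package version).
- Problem sizes in the shipped tests are deliberately desk-scale: 1-channel
  coupled pairs at L = 160 segments for the estimator oracles, 6-trial
  subjects for full-pipeline checks, and frame-level cohorts for replicate
  studies (100–200 replicates). The full 40-trial, 21-subject configuration
  runs through the same code paths.

## Known limitations

- The Hjorth Laplacian with a montage-derived stand-in adjacency is not
  the acquisition's true geometry; results on real data should use the
  true neighbor structure.
- Subject-level coherence after envelope demodulation has no closed form;
  quantitative estimator validation lives at the pair level, subject-level
  validation is rank-based.
- No confidence intervals on single-subject coherence; no directional or
  time-resolved coupling measures; no source-space analysis.
- The planted-correlation link is linear with Gaussian perturbation — the
  simplest model consistent with a target correlation; real
  structure–function relationships need not be linear.
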