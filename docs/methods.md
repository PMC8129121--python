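# Methods

## Signal model and preprocessing

Recordings are channel × time matrices in microvolts with a 10–20
montage. The conditioning chain mirrors a standard resting-state alpha
analysis: polyphase resampling to 500 Hz, re-referencing to the
instantaneous average of all electrodes, zero-phase Hamming-window FIR
band-pass filtering from 6 to 14 Hz (filter length from MNE's default
design rule for that band — the filter family is fixed, the order is
not, so the library default is used), and segmentation into
non-overlapping 2000 ms epochs (floor division, remainder discarded;
half-open sample intervals, 0-based).

ROI extraction has two modes. The default, *back-projection*, matches
component topographies (from an ICA decomposition, or the generator's
ground-truth mixing) against four fixed spatial templates — two
central-frontal and one parieto-occipital per hemisphere — by absolute
Pearson correlation with a 0.80 threshold, retaining between one and
three components per template, each component assigned to at most one
template (largest |r| wins). Matching is single-pass: only the threshold
of the original multistep procedure is published, so no iterative
template refinement is attempted. The selected components are
back-projected to the scalp and all subsequent feature computation
(spectra *and* connectivity) runs on that reconstruction. The fallback,
*cluster-average*, simply averages the raw electrodes of each cluster.
The fallback is kept because it needs no decomposition, but it is not
equivalent for directional connectivity: strong posterior sources leak
into frontal channels through the average reference and spatial spread,
and this common-mode contamination (which wPLI ignores by design) biases
the time-lag estimate severely — in synthetic tests cluster-average TLI
saturated near ±45 ms where the true lags were ±3–9 ms. Back-projection
removes the unselected activity and restores sign- and
magnitude-faithful lags. How multiple matched components are combined is
unpublished; their back-projections are summed.

ICA itself is delegated: a thin FastICA wrapper is provided, and any
precomputed decomposition (or the generator's `synthetic-truth`
component set) is accepted. The solver is deliberately outside the
tested surface.

Electrode clusters: left frontal {F1, FC1, C1, FC3}, right frontal
{F2, FC2, C2, FC4}, left parieto-occipital {PO7, PO3, O1}, right
parieto-occipital {PO8, PO4, O2}.

## Spectral features

Per ROI, 2000 ms epochs are Hann-tapered, zero-padded to a ≤ 0.05 Hz
grid, scaled so a sinusoid's spectral peak reads its total power in μV²,
and averaged (Welch). The native resolution of a 2 s epoch is 0.5 Hz,
which cannot support a 0.24 Hz smoother; zero-padding to 0.05 Hz maps
the 0.24 Hz Savitzky–Golay resolution to five grid points per side
(an 11-point window, polynomial order 5). The IAF is the frequency of
the in-band (7–13 Hz) maximum of the smoothed dB curve, accepted only if
it is a strict local maximum; otherwise the subject's IAF is *missing*
(NaN), and such subjects are excluded listwise from the ANOVA and the
classifier (with the exclusion visible in the degrees of freedom).
Richer peak-quality heuristics of automated IAF detectors (gradient
criteria, minimum prominence) are not published parameters and are not
reimplemented. Alpha amplitude is the maximum *raw* dB power in band:
the published definition is "maximum power", so the smoothed curve
locates the peak but does not supply the amplitude.

## Connectivity

Signals are cut into non-overlapping 2500 ms windows (48 per 120 s
recording). Per window the cross-spectrum is evaluated at the Fourier
grid frequency nearest the subject's posterior alpha peak (mean of the
two posterior IAFs; 10 Hz fallback when both are missing), with the
phase convention `arg S_xy > 0 ⇔ x lags y`.

- wPLI = |mean Im S| / mean |Im S| over windows, in [0, 1]. The 0/0
  convention (pure zero-lag coupling → 0) is applied with a relative
  tolerance of 1e-12 of the cross-spectral magnitude, because exact
  zeros do not survive floating-point complex multiplication.
- TLI uses the circular (resultant-vector) mean of the per-window
  phases — wrap-safe where an arithmetic mean of wrapped phases is
  not — converted to milliseconds at the evaluation frequency. A
  vanishing resultant yields a missing value.

A 14 × 14 symmetric wPLI matrix is computed over the cluster electrodes
(fixed order F1, FC1, C1, FC3, F2, FC2, C2, FC4, PO7, PO3, O1, PO8, PO4,
O2). The three wPLI features are means over *inter-cluster* electrode
pairs only (left intra 4×3, right intra 4×3, posterior inter 3×3). TLI
features are computed on cluster-mean time series for the same three
pairs — averaging pairwise lags is unstable when individual pairs sit
near antiphase — with the frontal (intra) or left (inter) signal first.
The plain wPLI is used, not the debiased variant.

## Group statistics

The 2 × 2 × 2 mixed ANOVA (group between; hemisphere and region within)
uses the classical balanced sums-of-squares decomposition with separate
error strata: subjects-within-group for the between effect, and the
subject × factor interaction pooled within groups for each within
effect. All within factors have two levels, so sphericity holds and no
correction is needed. Partial η² = SS_effect / (SS_effect + SS_error);
90% CIs invert the noncentral-F distribution
(η² = λ/(λ + df₁ + df₂ + 1)). t-tests are pooled-variance independent or
paired, with Cohen's d = t·√(1/n₁ + 1/n₂) (independent) or t/√n
(paired) and 90% CIs from the noncentral-t pivot — these conversions
reproduce every published-style d and CI to printed precision, which is
why they were adopted over direct pooled-SD formulas. One-tailed tests
require the direction as an explicit argument; it is never inferred from
the data. Multiple comparisons use the Dunn–Šidák per-test threshold
1 − (1 − α)^(1/k) (0.013 for k = 4 alpha-activity tests, 0.017 for
k = 3 connectivity tests).

## Pattern classifier

Features: the 14-dimensional alpha vector; positive class is the
high-schizotypy group. The nested stratified CV uses k = 10 outer folds;
the inner loop also targets k = 10, shrinking to the largest feasible
stratified k ≥ 2 when an outer training stratum is too small. The inner
loop scores every (feature combination, family, C) by mean balanced
accuracy; ties prefer fewer features, then lower C, then logistic
regression before the SVM, then catalogue order (parsimony and
determinism). The feature-combination catalogue is a reconstruction —
the original list is not published beyond the constraints that right-only
combinations ranked first and left-only ones were never selected — and is
config-driven: {left, right, both} × {posterior activity, posterior
activity + intra connectivity, all activity, all + intra, all + intra +
inter}, 15 entries. Standardization (z-scoring) is fit on training rows
only, at both levels. Decision scores are signed distances oriented so
larger = more HSG-like; AUC is the rank statistic (ties count ½) per
outer fold, with single-class folds recorded as missing and skipped in
ROC averaging. The averaged ROC interpolates each fold's curve onto a
101-point false-positive-rate grid, anchored at (0,0) and (1,1), and
reports the vertical mean, SD and normal-approximation 99.9% CI of the
mean.

For inner-loop scoring the package calls the underlying libsvm/liblinear
solvers directly (the same libraries the scikit-learn estimators wrap);
the estimator API's per-call overhead dominates at ~9000 fits per
repetition. Equivalence of the two routes is asserted in the test suite,
and the final per-fold models are fit through the public estimators.

## Synthetic cohorts

The generator is artifact-side: the study it emulates published no
generative model, so the structure below encodes only what the
downstream pipeline must be able to detect.

Per subject and hemisphere, a narrow-band driver (white noise shaped by
a Gaussian spectral window, σ = 0.25 Hz, bandwidth < 1 Hz — realistic
phase jitter) oscillates at the hemisphere's posterior alpha frequency.
The posterior source is the driver advanced by `lag_ms` (positive lag ⇒
posterior leads ⇒ the frontal signal lags, matching the TLI sign
convention); the frontal source mixes the driver (weight c, the coupling
strength) with an independent narrow-band component at the frontal alpha
frequency (weight √(1−c²)). Lags are implemented as exact band-limited
(FFT phase-ramp) fractional-sample shifts, since lags like 7.04 ms are
not integer samples at 500 Hz; lags beyond half an alpha period raise a
wrap-ambiguity error, and sampled lags are clipped to 80% of that bound.
A pure-sinusoid mode replaces the oscillators for exact-oracle tests.
Each source is scaled to its configured μV RMS, mixed with 1/f^1
background noise (1.5 μV RMS default; the background exponent is
configurable), projected to the scalp through fixed Gaussian-falloff
topographies (σ = 4.5 cm around each cluster centroid, positions from
the standard 10-20 montage), and corrupted by 1 μV white sensor noise.
These same topographies serve as the matching templates, so the
template-matching path is exercised non-trivially but with a known
answer. All randomness flows from one integer seed; identical
(config, seed) pairs are bit-identical.

Shipped two-group defaults: posterior IAF means 10.39/10.70 Hz (LSG
left/right) and 10.39/10.09 Hz (HSG), frontal 10.25/10.38 Hz for both
groups, with SDs from the reported standard errors (SE·√24: 0.83 Hz
posterior, 0.59 Hz frontal). Amplitudes: ~3 μV posterior vs. ~1.2 μV
frontal source RMS with a 0.4 μV right-posterior deficit in the HSG;
their SDs (0.35/0.25 μV) are a design choice, not a conversion — the
reported amplitude dispersions are in dB of the spectral peak, which has
no unique μV-RMS preimage — sized a priori so the right-posterior
amplitude contrast is reliably detectable at n = 24 per group. Coupling
0.5 everywhere except the right hemisphere (LSG 0.6, HSG 0.35); lags
−11 ms (anterior-to-posterior, frontal leads) everywhere except the
HSG's right hemisphere (+7.04 ms, reversed), SD 8 ms — likewise sized
a priori rather than converted from the reported SEs (SE·√24 ≈ 22 ms
would straddle zero and make the sign pattern unrecoverable in
principle).

What the generator does *not* emulate: ocular/muscle artifacts, volume
conduction through a head model, non-alpha rhythms, non-stationarity,
inter-hemispheric posterior coupling. Passing tests therefore show the
*pipeline* recovers what it is pointed at under clean mixing — they do
not certify performance on real EEG, where component separation and the
bias floor of 48-window wPLI are the binding constraints.

## Scale choices and degenerate inputs

Test and acceptance runs use 24 subjects per group (120 s at 500 Hz),
the 14-cluster-electrode montage for generation (the projection and
extraction only involve those electrodes; the full 64-channel montage is
the pipeline default and covered by unit tests) and 50 CV repetitions;
1000 repetitions remain a config switch. Degenerate inputs are handled
explicitly: all-zero spectra warn and return zeros; identical samples
give t = 0 with p = 1; inner-CV strata with fewer than two subjects per
class are a hard error; ANOVA designs must be complete and balanced, and
incomplete subjects are dropped before the frame is built. The realized
per-cohort probability that all four group contrasts point the right way
is about 0.92–0.96 — the IAF contrast inherits the honest SE-derived
dispersion (z ≈ 2.3), and cluster-level TLI is attenuated roughly a
third by spatial spread — so direction-recovery rates across independent
cohort streams land between 85% and 100%.

## Known limitations

Single-pass template matching; no artifact rejection; the
cluster-average TLI bias described above; the feature-combination
catalogue is a plausible reconstruction; EDF/BrainVision are read-only
(delimited text is the write format); effect-size CIs use noncentral
pivots, which can differ in the second decimal from other CI
conventions for η².
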