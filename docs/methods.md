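# Methods

This note documents the models, conventions and numerical choices behind
`triadscan`, what the synthetic-data generator does and does not emulate,
and the known limitations of each stage.

## Data model

A chromosome is a uniform 1-D grid of 67 nm pixels (the effective camera
pixel of the acquisition system) carrying one non-negative ADU intensity
series per channel role: `crossover` (a ZMM crossover marker such as Zip3 or
Zip2), `axis` (the HORMAD component Hop1) and `sc` (the SC transverse
filament Zip1). Keying by role rather than molecule lets Zip3- and
Zip2-based experiments share one code path. Traced chromosomes are ~3.15 ±
0.4 µm, ~47–60 pixels. Coordinates are 0-based pixel indices at pixel
centers; all distances are reported in µm. Input CSVs in the Fiji
Plot-Profile dialect may carry distances in pixels or µm; the reader
auto-detects by grid step (a step near 1 is a pixel grid) and can be
overridden. Distances are snapped to exact multiples of the pixel size to
absorb export rounding; profile CSVs round-trip bit-for-bit (shortest-repr
floats on write, round-trip float parsing on read).

Z-normalization uses the sample standard deviation (denominator N−1)
throughout; the choice is arbitrary but fixed so dissimilarity indices are
reproducible. Constant channels z-map to all zeros and are flagged.

## Spectral analysis

Amplitude spectra are plain discrete Fourier transforms — no windowing, no
detrending — presented one-sided with the convention |X_j|/N, doubled at
interior bins, so an on-grid unit cosine has amplitude 1 at its own bin.
Every downstream quantity is invariant to this convention. Wave vectors are
k_j = 2πj/(NΔ); each corresponds to a wavelength l = 2π/k.

**Two most prominent periodicities.** Interior local maxima of the
amplitude spectrum (plateaus resolved leftmost, amplitude ties broken
toward smaller k) are ranked by amplitude within a wavelength window of
0.2–2.0 µm. The window excludes the DC bin and the confinement mode at the
chromosome's own length — a finite object produces a k-vector peak at its
own size regardless of any internal periodicity — as well as sub-resolution
wavelengths. Spectra with fewer than two local maxima in the window yield a
flagged missing value and are excluded (and logged) from cohort
distributions. Cohort distributions of (l1, l2) are fit with a
two-component Gaussian mixture: EM with k-means++ initialization, 50
restarts, fixed seed, best likelihood kept; means reported sorted, inputs
sorted first so the fit is order-invariant.

**Summed periodicity distributions.** Per profile: scale raw intensities to
unit maximum (each chromosome contributes equally), compute the amplitude
spectrum, and linearly interpolate it onto a common uniform k-grid (512
points spanning the largest shared fundamental to the Nyquist wave vector;
amplitudes outside a chromosome's native range contribute zero; 512 points
over-resolve the native ~25-bin spectra). Interpolated spectra are summed,
converted to wavelength space with the Jacobian weight dk/dl = 2π/l², and
restricted to an observable window of 0.2–2.5 µm before normalization. The
window matters: the 1/l² weight amplifies the spectral leakage floor of
finite, end-truncated profiles, which would otherwise dominate the
normalization at wavelengths below the ~0.2 µm optical resolution limit
where no genuine image structure exists. Final curves are scaled to maximum
1 for experimental cohorts and 0.95 for simulated cohorts (the convention
keeps the two curves distinguishable on one axis and slightly
under-subtracts, so residua are conservative).

**Subtraction analysis.** The matched control for a cohort is a
re-rendering of the same chromosomes from ground truth with only the
shorter-periodicity peak trains (identical positions, jitter and heights;
no longer component, no noise). Subtracting its summed distribution
(normalized to 0.95) from the full cohort's (normalized to 1) leaves a
residuum that is near zero at 0.5 µm in absolute terms (≈ +0.05, the
deliberate 5% under-subtraction) and peaks near 1.1–1.2 µm. Note the
structural limit: with both curves max-normalized, the subtraction aligns
the shorter-periodicity content only while each cohort's maximum sits at
its shorter-periodicity peak, and the 5% offset bounds how completely the
0.5 µm region can cancel relative to the residuum maximum. The residuum's
location and its absolute smallness at 0.5 µm are the robust diagnostics;
ratio criteria tighter than ~5%/max are at the mercy of this convention.

## Band decomposition

The full complex DFT of a channel is partitioned by wavelength at 875 nm:
coefficients with l < 875 nm reconstruct the shorter component, l ≥ 875 nm
(equality assigned to the longer side; the DC term too, so the shorter band
is zero-mean) the longer component. Conjugate-symmetric pairs stay
together, both reconstructions are real, and shorter + longer equals the
input to floating-point precision on any input — this identity is tested on
random data. No tapering is applied; the brick-wall mask is the method, and
its edge ringing is handled downstream. The threshold must lie strictly
between two pixels and the chromosome length.

## Peak detection

Peaks are located at one-pixel (67 nm) resolution, deliberately without
sub-pixel interpolation: inter-channel triad distances are measured on the
pixel grid, so their modal value is 0 or 1 pixel by construction.

Shorter-band signals are smoothed with a centered 3-pixel moving average
(endpoints unchanged) before detection. Interior strict local maxima are
found first (plateaus resolve leftmost; endpoints are never peaks). A
second pass rescues shoulders ("humps") that never become maxima: a
shoulder is a dip in the slope magnitude without a sign change — a local
maximum of the first derivative with negative value (falling flank) or a
local minimum with positive value (rising flank). The rescued hump is
placed at the pixel of the dip on the side away from the nearest maximum
and must be more than 1 px from any detected maximum. The original
detector's shoulder-acceptance rules are unpublished; this reconstruction
is sign-based, deterministic, and configurable (`hump_exclusion_px`,
`rescue_humps`), and humps are tagged so they can be excluded in
sensitivity analyses.

By default only peaks with positive signal value are kept
(`positive_only=True`). In a band-reconstructed signal an intensity peak is
a positive excursion; local maxima at or below zero are ringing or
band-passed-noise artifacts of the brick-wall filter. On ground-truthed
cohorts the filter removes most false detections (precision 0.89–0.95
across noise levels versus 0.75–0.85 without) at a small recall cost, and
the downstream gamma spacing mode then tracks the generator truth within
~1%; the unthresholded behavior is available by flag. Measured operating
points (matching radius 2 px, shorter band): recall 0.94–0.95 throughout,
precision 0.95 / 0.92 / 0.89 at noise 0 / 0.05 / 0.1 × mean peak height.

## Interference statistics

**CoC.** Chromosomes are divided into equal *relative-length* intervals
(half-open bins, last bin closed), because traced chromosomes vary in
length; distances are reported through the cohort mean length. "Event in
interval" is binary. For every interval pair the observed co-occupancy
frequency is divided by the product of the single-interval frequencies;
pair CoCs are averaged within each separation |i−j|. Pairs with zero
expected frequency are excluded and counted. 30 intervals are used for
shorter-band and total events, 17 for longer-band events. The implementation
is property-tested against an independent brute-force enumeration on all
small instances. Monte-Carlo precision per separation scales as
1/√(n_chromosomes · n_pairs); separations near the full chromosome length
have only one or two interval pairs, so their CoC carries error ~0.16 even
at 1000 chromosomes — calibration checks should average over a distance
range rather than read single extreme separations.

**L_CoC** interpolates linearly at the first upward crossing of 0.5 on the
unsmoothed mean curve; a curve already above 0.5 at its first point is
interpolated from the origin, and a curve that never crosses yields a
flagged missing value.

**Spacings and fits.** Adjacent-event spacings are pooled across
chromosomes. The gamma fit is maximum likelihood with location fixed at 0;
the mode (α−1)θ and shape α are the reported summaries. The two-Gaussian
spacing fit shares the mixture implementation above and resolves spacings
quantized at small integer multiples of the 0.23 µm inter-precursor
distance.

**Triad colocalization.** For each peak of one channel, the distance to the
nearest peak of another channel, pooled; chromosomes lacking the second
channel are skipped and logged. The chance reference has two parts: the
empirical null from circular shifts (each chromosome's second-channel array
shifted by a uniform offset modulo length, preserving its internal
spacings; uniform resampling available by flag) — a decreasing density with
median ≈ s/4 — and the analytic half-mean-spacing value s/2, the
conventional "expected by chance" line for arrays of mean spacing s. Modes
of pixel-quantized distances are computed on histograms whose bins are
centered on pixel multiples.

**bp → µm** uses 324 bp/nm, the average DNA packing ratio of pachytene
chromosomes obtained from known Mb sizes over measured axis lengths.

## Abundance analyses

The dissimilarity index of two channels is the mean unsigned difference of
their z-scored series; band-component indices z-score the band signal
itself, treating each iFFT component as a signal in its own right.
Independent series score near 2/√π ≈ 1.128 (the closed-form expectation for
standard normals), identical shapes score 0. Genotype comparisons use
two-sided two-sample t-tests per channel pair × signal class with no
multiplicity correction (each cell is reported as its own comparison; apply
a correction downstream if desired). Population averages cubic-spline
interpolate (natural boundary) each profile onto 101 relative positions in
[0,1] and average pointwise; symmetrization with the mirrored profile is on
by default because spread chromosomes carry no orientation, and can be
disabled to look for terminal enrichment.

## Synthetic data

`generate_profiles` emulates the statistical structure the analysis
assumes: chromosome lengths N(3.15, 0.4²) µm on a 67 nm grid; per
component, a renewal peak train with gamma-distributed gaps (heterogeneity
matching the gamma fits observed for real spacing distributions), the first
peak offset by a uniform fraction of one spacing to avoid cohort-wide phase
locking, peaks truncated at chromosome ends; Gaussian peak shapes (σ 0.10
µm for the shorter component ≈ the diffraction-limited focus, 0.30 µm for
the domainal longer component); gamma-distributed peak heights (CV 0.3);
the three channels share peak positions up to N(0, 0.03²) µm per-channel
jitter (triads); additive Gaussian noise (default sd 5% of mean peak
height) clipped at zero. Defaults are calibrated so the shorter component's
adjacent-gap distribution has gamma mode ≈ 0.49 µm at shape ≈ 9 (gap mean
0.55 µm, CV 1/3) and the longer component mode ≈ 0.93 µm (mean 1.05 µm) —
the measured spacing regimes. Per-channel longer-component amplitude scales
(crossover 0.5, axis 1.0, sc 2.0) encode the observed molecule-specific
balance of focal versus domainal signal. What the generator does *not*
emulate: 2-D point-spread rendering and line tracing, bleed-through,
background gradients, intensity falloff at chromosome tips, or correlated
(non-white) noise — so passing tests validate the 1-D analysis chain, not
image acquisition.

`generate_two_tier_events` lays a precursor lattice at 0.23 µm (optional
jitter) and designates canonical events sequentially at steps of 2 (weight
0.7) or 3 precursor units. The second round is itself an interference
round: gaps between adjacent canonical events are visited left to right and
receive a minority event at a random unoccupied precursor with probability
0.85, never in two consecutive gaps — so minority events end up ~4–6
precursor units apart, one precursor unit from the nearest canonical event,
at a minority:canonical ratio ≈ 0.42:1. This reproduces the diagnostic
signatures: canonical L_CoC ≈ 0.33 µm < minority L_CoC ≈ 0.6–0.7 µm;
canonical CoC exactly 0 at the smallest separation while total events stay
> 0 there; minority spacings quantized near 0.92 and 1.3 µm.

`generate_independent_events` is the homogeneous Poisson null used to
calibrate CoC ≈ 1.

All generators are deterministic given their seed; every cohort ships with
a ground-truth table (component, shared triad position, per-channel
jittered position, height) for exact recovery scoring.

## Problem sizes and determinism

Test and acceptance computations use cohorts of 40–100 profiles and event
sets of 200–10 000 chromosomes — sizes at which the pooled statistics are
stable to a few percent while the whole suite runs in well under a minute.
All stochastic steps (generators, GMM restarts, randomization nulls) take
explicit seeds, and the pipeline records its configuration and seed in
every results bundle; reruns are byte-identical.

## Known limitations

- The brick-wall band split rings at sharp features; the positive-excursion
  filter mitigates but does not eliminate spurious detections near strong
  peaks, and recall/precision cannot both exceed ~0.95 on noisy cohorts.
- CoC values at separations spanning nearly the whole chromosome rest on
  one or two interval pairs and are statistically fragile at any realistic
  cohort size.
- The subtraction analysis inherits the 1.0/0.95 normalization convention;
  its residuum at 0.5 µm has a deliberate ~+0.05 floor (see above).
- Chromosomes are pooled by relative coordinates without identification;
  all statistics assume the cohort is a homogeneous ~3.15 µm size class.
- The hump-rescue rule is a reconstruction of unpublished logic; humps are
  tagged so analyses can be repeated without them.
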