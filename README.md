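# triadscan

Quantitative analysis of multi-channel fluorescence intensity profiles traced
along meiotic pachytene chromosomes.

During meiosis, crossover recombination sites, chromosome-axis proteins and
synaptonemal-complex (SC) proteins form co-localized intensity peaks
("triads") along spread chromosomes, arranged in two interdigitated periodic
patterns: a shorter-periodicity array (~0.5 µm, the canonical crossover
spacing) and a longer-periodicity array (~1 µm). `triadscan` implements the
full signal-analysis pipeline used to characterize this multiscale
patterning from 1-D linescans ("Plot Profile" CSV exports of traced
chromosomes, 67 nm pixels, one intensity channel per immunostained
molecule):

- **Fourier analysis** — one-sided amplitude spectra per channel;
  extraction of the two most prominent periodicities per chromosome and
  two-component Gaussian-mixture fits of their cohort distribution;
  cohort-summed periodicity probability distributions in position space
  (with the `dk/dl = 2π/l²` Jacobian), and subtraction of a matched
  shorter-periodicity-only simulation to isolate the longer-periodicity
  residuum.
- **Band decomposition** — brick-wall split of each channel at a 875 nm
  wavelength threshold into shorter- and longer-periodicity components via
  zeroed Fourier coefficients and the inverse transform (the two components
  sum exactly back to the input).
- **Peak detection** — pixel-resolution local maxima (3-px moving-average
  smoothing for the shorter band) plus rescue of "humps": shoulders visible
  as slope-magnitude dips in the first derivative.
- **Interference statistics** — adjacent-spacing distributions with
  maximum-likelihood gamma fits (shape α, mode (α−1)θ) and two-Gaussian
  mixture fits; coefficient-of-coincidence (CoC) curves over equal
  relative-length intervals with L_CoC (the distance at which CoC first
  reaches 0.5); nearest-heterologous-peak (triad) distances with a circular
  randomization null; longer-vs-shorter peak relations (median distance,
  interdigitation fraction, count ratios); bp→µm conversion of DNA-defined
  crossovers at 324 bp/nm.
- **Abundance analysis** — the dissimilarity index (mean |z_a − z_b| of two
  z-scored channels) per chromosome × channel pair × signal class,
  genotype comparisons by two-sample t-tests, unit-length population-average
  profiles, and per-channel mean intensities.
- **Synthetic data** — generators for ground-truthed profile cohorts
  (gamma-gap Gaussian peak trains, triad jitter, pixelation, noise), Poisson
  event maps (the no-interference null), and two-round "designation" event
  maps on a 0.23 µm precursor lattice (canonical events at 2–3 precursor
  steps; minority events at unreacted precursors between them).

## The coefficient of coincidence

For chromosomes divided into `n` equal relative-length intervals, the CoC of
an interval pair (i, j) is

    CoC(i,j) = f_obs(i ∧ j) / (f_i · f_j)

where `f_i` is the fraction of chromosomes with ≥1 event in interval `i` and
`f_obs(i ∧ j)` the fraction with events in both. Values are averaged over
pairs sharing the separation |i−j| and plotted against separation in µm
(via the cohort mean length). CoC = 1 means independent placement; CoC = 0
at small distances is the hallmark of crossover interference, and L_CoC
summarizes its range.

## Worked example

```python
from triadscan import (ProfileSimSpec, generate_profiles, split_bands,
                       detect_band_peaks, peaks_to_eventmap,
                       adjacent_spacings, fit_gamma, coc_curve, l_coc)

profiles, truth = generate_profiles(ProfileSimSpec(n_chromosomes=100, seed=1))
lengths = {p.chromosome_id: p.length_um for p in profiles}

peaks = [detect_band_peaks(split_bands(p, "crossover"), "shorter")
         for p in profiles]
events = peaks_to_eventmap(peaks, lengths)

fit = fit_gamma(adjacent_spacings(events))
curve = coc_curve(events, n_intervals=30)
print(f"gamma mode {fit.mode_um:.2f} um, alpha {fit.alpha:.1f}, "
      f"L_CoC {l_coc(curve):.2f} um")
```

prints

```
gamma mode 0.49 um, alpha 10.8, L_CoC 0.33 um
```

i.e. the shorter-band peaks recovered by the pipeline are spaced ~0.5 µm
apart with the strongly even (high-α) spacing characteristic of crossover
interference, and their coincidence falls to half its independent level at
~0.3 µm — the canonical-crossover signature.

The same pipeline runs from the shell:

```bash
triadscan simulate --n 100 --seed 1 --out sim/
triadscan run --manifest sim/manifest.csv --out results/
triadscan report --bundle results/bundle.json
```

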