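"""FFT amplitude spectra and periodicity-probability distributions.

A linescan of N pixels at step D (um) has one-sided wave vectors
k_j = 2*pi*j / (N*D) for j = 0..floor(N/2); each k corresponds to a spatial
wavelength l = 2*pi/k.  The analyses here are: per-profile one-sided
amplitude spectra (no windowing, no detrending), extraction of the two most
prominent periodicities per spectrum, a cohort-summed periodicity
probability distribution in position space (with the Jacobian weight for the
k -> l change of variable), and subtraction of a simulated distribution from
an experimental one to isolate the longer-periodicity residuum.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .profile_io import ChromosomeProfile, normalize_max_unity

_MIN_N = 16


@dataclasses.dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum of a single channel.

    Amplitude convention: |X_j|/N doubled at interior bins, so an on-grid
    unit cosine contributes amplitude 1 at its own bin.  All downstream
    results are invariant to this choice.
    """

    n_samples: int
    pixel_size_um: float
    k: np.ndarray  # rad/um, ascending from 0
    amplitude: np.ndarray

    @property
    def wavelengths_um(self) -> np.ndarray:
        """l = 2*pi/k (inf at the DC bin)."""
        with np.errstate(divide="ignore"):
            return 2 * np.pi / self.k


@dataclasses.dataclass
class PeriodicityDistribution:
    """Probability of each periodicity l (um) across a cohort."""

    wavelengths_um: np.ndarray  # ascending
    probability: np.ndarray
    normalization: str  # 'max1' | 'max0.95' | 'none'
    n_profiles: int = 0

    def peak_wavelength_um(self) -> float:
        return float(self.wavelengths_um[int(np.argmax(self.probability))])


@dataclasses.dataclass
class GaussianMixtureFit:
    """Two-component 1-D Gaussian mixture (means sorted ascending)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    converged: bool
    degenerate: bool
    seed: int
    n: int


def amplitude_spectrum(series: np.ndarray, pixel_size_um: float) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of a uniformly sampled series."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < _MIN_N:
        raise ValueError(f"need at least {_MIN_N} samples, got {n}")
    coeffs = np.fft.rfft(x)
    amp = np.abs(coeffs) / n
    # double interior bins (all but DC, and Nyquist when n is even)
    hi = amp.size - 1 if n % 2 == 0 else amp.size
    amp[1:hi] *= 2
    j = np.arange(amp.size)
    k = 2 * np.pi * j / (n * pixel_size_um)
    return AmplitudeSpectrum(n_samples=n, pixel_size_um=pixel_size_um, k=k, amplitude=amp)


def profile_spectrum(profile: ChromosomeProfile, channel: str) -> AmplitudeSpectrum:
    return amplitude_spectrum(profile.channels[channel], profile.pixel_size_um)


@dataclasses.dataclass
class ProminentPeriodicities:
    """Result of the two-most-prominent-periodicities extraction."""

    l1_um: Optional[float]  # higher-amplitude local maximum
    l2_um: Optional[float]
    reason: Optional[str] = None  # set when the spectrum was unusable

    @property
    def ok(self) -> bool:
        return self.reason is None


def top_two_periodicities(
    spectrum: AmplitudeSpectrum, l_range_um: tuple = (0.2, 2.0)
) -> ProminentPeriodicities:
    """Periodicities of the two highest-amplitude interior local maxima.

    Restricted to ``l_range_um`` (default 0.2-2.0 um), which excludes the DC
    bin and the confinement mode at the chromosome's own length.  Ties break
    toward smaller k (longer periodicity).  Spectra with fewer than two local
    maxima in range yield a flagged missing result.
    """
    amp = spectrum.amplitude
    l = spectrum.wavelengths_um
    lo, hi = l_range_um
    # interior strict local maxima, plateaus resolved leftmost
    candidates = []
    for j in range(1, amp.size - 1):
        left = amp[j - 1]
        m = j
        while m + 1 < amp.size and amp[m + 1] == amp[j]:
            m += 1
        if m == amp.size - 1:
            break
        if amp[j] > left and amp[j] > amp[m + 1] and lo <= l[j] <= hi:
            candidates.append(j)
    if len(candidates) < 2:
        return ProminentPeriodicities(None, None, reason=f"{len(candidates)} local maxima in range")
    # sort by amplitude descending, then smaller k (smaller j) first
    candidates.sort(key=lambda j: (-amp[j], j))
    j1, j2 = candidates[0], candidates[1]
    return ProminentPeriodicities(l1_um=float(l[j1]), l2_um=float(l[j2]))


def fit_gmm2(values: Iterable, seed: int = 0, n_init: int = 50) -> GaussianMixtureFit:
    """Deterministic two-component Gaussian mixture fit (EM, k-means++ init,
    best of ``n_init`` restarts)."""
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 values, got {x.size}")
    if np.ptp(x) == 0:
        return GaussianMixtureFit(
            means=np.array([x[0], x[0]]),
            sds=np.array([0.0, 0.0]),
            weights=np.array([0.5, 0.5]),
            log_likelihood=float("nan"),
            converged=False,
            degenerate=True,
            seed=seed,
            n=x.size,
        )
    X = np.sort(x)[:, None]  # sorting makes the fit order-invariant
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-10,
    ).fit(X)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    return GaussianMixtureFit(
        means=means[order],
        sds=sds[order],
        weights=gm.weights_[order],
        log_likelihood=float(gm.score(X) * x.size),
        converged=bool(gm.converged_),
        degenerate=False,
        seed=seed,
        n=x.size,
    )


def summed_periodicity_distribution(
    profiles: Sequence[ChromosomeProfile],
    channel: str,
    mode: str = "experimental",
    n_grid: int = 512,
    l_range_um: tuple = (0.2, 2.5),
) -> PeriodicityDistribution:
    """Cohort-summed periodicity probability distribution in position space.

    Per profile: scale the raw intensities so the maximum is 1 (equal weight
    per chromosome), take the one-sided amplitude spectrum, and linearly
    interpolate it onto a common uniform k-grid spanning the largest shared
    fundamental up to the Nyquist wave vector (amplitudes outside a
    chromosome's native range contribute zero).  The interpolated spectra
    are summed, converted to wavelength space with the Jacobian weight
    dk/dl = 2*pi/l**2, restricted to the observable wavelength window
    ``l_range_um`` (default 0.2-2.5 um: from the diffraction resolution
    limit to beyond the confinement scale; sub-resolution wavelengths carry
    only spectral leakage and noise), and the result rescaled so its maximum
    is 1 (``mode='experimental'``) or 0.95 (``mode='simulated'``).
    """
    if not profiles:
        raise ValueError("cohort is empty")
    pixel_sizes = {p.pixel_size_um for p in profiles}
    if len(pixel_sizes) > 1:
        raise ValueError(f"incompatible pixel sizes in cohort: {sorted(pixel_sizes)}")
    delta = pixel_sizes.pop()

    k_min = max(2 * np.pi / (p.n_pixels * delta) for p in profiles)
    k_max = np.pi / delta
    k_grid = np.linspace(k_min, k_max, n_grid)

    total = np.zeros(n_grid)
    for p in profiles:
        spec = amplitude_spectrum(normalize_max_unity(p.channels[channel]), delta)
        total += np.interp(k_grid, spec.k, spec.amplitude, left=0.0, right=0.0)

    l = 2 * np.pi / k_grid  # descending
    prob = total * (2 * np.pi / l**2)  # Jacobian of k -> l
    order = np.argsort(l)
    l, prob = l[order], prob[order]
    if l_range_um is not None:
        keep = (l >= l_range_um[0]) & (l <= l_range_um[1])
        l, prob = l[keep], prob[keep]

    if mode == "experimental":
        prob, norm = prob / prob.max(), "max1"
    elif mode == "simulated":
        prob, norm = 0.95 * prob / prob.max(), "max0.95"
    elif mode == "none":
        norm = "none"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PeriodicityDistribution(
        wavelengths_um=l, probability=prob, normalization=norm, n_profiles=len(profiles)
    )


def subtract_distributions(
    experimental: PeriodicityDistribution, simulated: PeriodicityDistribution
) -> PeriodicityDistribution:
    """Pointwise residuum experimental - simulated on the experimental grid.

    The simulated distribution is linearly interpolated onto the experimental
    wavelength grid if the grids differ; negative residuum values are kept.
    """
    le = experimental.wavelengths_um
    ls = simulated.wavelengths_um
    if le.shape == ls.shape and np.allclose(le, ls):
        sim = simulated.probability
    else:
        if ls[0] > le[-1] or ls[-1] < le[0]:
            raise ValueError("wavelength grids do not overlap; cannot interpolate")
        sim = np.interp(le, ls, simulated.probability, left=0.0, right=0.0)
    return PeriodicityDistribution(
        wavelengths_um=le.copy(),
        probability=experimental.probability - sim,
        normalization="none",
        n_profiles=experimental.n_profiles,
    )
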