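"""Synthetic chromosome profiles and event lists with known ground truth.

Two generators are provided.

``generate_profiles`` builds cohorts of three-channel intensity linescans:
Gaussian peak trains with gamma-distributed inter-peak gaps (a shorter
~0.5 um regime and an optional longer ~1 um regime), heterogeneous peak
heights and chromosome lengths, shared peak positions across channels up to
a small per-channel jitter (triads), 67 nm pixelation, and additive noise.
Every cohort comes with a ground-truth table of true peak positions so that
downstream peak recovery can be scored exactly.

``generate_two_tier_events`` emulates sequential crossover designation on a
regular precursor array: canonical events separated by two or three
inter-precursor distances, then minority events dropped onto unreacted
precursors between adjacent canonical events.  ``generate_independent_events``
is the Poisson null used to calibrate coincidence statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .profile_io import CHANNEL_ROLES, DEFAULT_PIXEL_SIZE_UM, ChromosomeProfile
from .interference import EventMap


@dataclasses.dataclass
class ComponentSpec:
    """One periodic peak-train component of a simulated channel.

    ``mean_spacing_um`` and ``spacing_cv`` parameterize gamma-distributed
    inter-peak gaps; ``peak_sigma_um`` is the Gaussian peak width and
    ``height_cv`` the coefficient of variation of per-peak heights.

    Default spacing parameters are calibrated to the measured adjacent-peak
    spacing distributions of the shorter-periodicity group: gamma mode
    ~0.49 um with shape ~9, i.e. a gap mean of ~0.55 um ("~0.5 um" average)
    at cv = 1/3.
    """

    mean_spacing_um: float = 0.55
    spacing_cv: float = 1 / 3
    peak_sigma_um: float = 0.10
    height_cv: float = 0.3
    mean_height: float = 1.0
    present: bool = True


@dataclasses.dataclass
class ProfileSimSpec:
    """Cohort-level recipe for simulated three-channel profiles.

    Defaults reproduce the wild-type study conditions: ~3.15 +/- 0.4 um
    chromosomes on a 67 nm grid, a shorter peak train whose adjacent-peak
    spacings have gamma mode ~0.49 um, a longer train with ~1 um typical
    spacing and broader peaks, ~30 nm triad jitter between channels, and
    mild additive noise.
    """

    n_chromosomes: int = 100
    length_mean_um: float = 3.15
    length_sd_um: float = 0.4
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    short_component: ComponentSpec = dataclasses.field(default_factory=ComponentSpec)
    long_component: ComponentSpec = dataclasses.field(
        default_factory=lambda: ComponentSpec(
            mean_spacing_um=1.05, spacing_cv=1 / 3, peak_sigma_um=0.30, height_cv=0.3
        )
    )
    triad_jitter_um: float = 0.03
    noise_sd: float = 0.05
    #: Per-channel multiplier on the longer-component peak height, encoding
    #: the observed molecule-specific balance of focal vs domainal signal:
    #: narrow (focal) signal dominates for the crossover marker, the two are
    #: comparable for the axis component, and broad domainal fluctuations
    #: dominate for the SC transverse filament.
    channel_long_scale: dict = dataclasses.field(
        default_factory=lambda: {"crossover": 0.5, "axis": 1.0, "sc": 2.0}
    )
    genotype: str = "simulated"
    seed: int = 0

    def __post_init__(self):
        for comp in (self.short_component, self.long_component):
            if comp.present:
                if comp.mean_spacing_um <= 0 or comp.peak_sigma_um <= 0:
                    raise ValueError("component spacings and sigmas must be positive")
                if comp.spacing_cv < 0 or comp.height_cv < 0:
                    raise ValueError("CVs must be non-negative")
                if comp.mean_spacing_um < 3 * self.pixel_size_um:
                    raise ValueError(
                        f"mean spacing {comp.mean_spacing_um} um is below 3 pixels and unresolvable"
                    )
        if self.length_mean_um <= 0 or self.length_sd_um < 0:
            raise ValueError("invalid length parameters")
        if self.noise_sd < 0 or self.triad_jitter_um < 0:
            raise ValueError("noise and jitter must be non-negative")


@dataclasses.dataclass
class PrecursorSimSpec:
    """Two-tier crossover-designation recipe on a regular precursor array.

    Precursors are laid every ``inter_precursor_um`` (0.23 um).  Canonical
    events walk along the array in steps of two (weight ``weight_two``) or
    three precursor units.  The second designation round is itself an
    interference round: inter-canonical gaps are visited left to right and a
    gap receives a minority event (at a random unoccupied precursor within
    it) with probability ``minority_fill_prob``, but never in two adjacent
    gaps -- so minority events end up separated by roughly two canonical
    spacings (four to six precursor units), as observed.  The default fill
    probability 0.85 yields a minority:canonical count ratio near the
    observed ~0.46:1.
    """

    n_chromosomes: int = 100
    length_mean_um: float = 3.15
    length_sd_um: float = 0.4
    inter_precursor_um: float = 0.23
    precursor_jitter_um: float = 0.0
    canonical_multiples: tuple = (2, 3)
    weight_two: float = 0.7
    minority_fill_prob: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if any(int(m) != m or m <= 0 for m in self.canonical_multiples):
            raise ValueError("canonical multiples must be positive integers")
        if not 0 <= self.weight_two <= 1:
            raise ValueError("weight_two must be in [0, 1]")
        if not 0 <= self.minority_fill_prob <= 1:
            raise ValueError("minority_fill_prob must be in [0, 1]")
        if self.inter_precursor_um <= 0:
            raise ValueError("inter_precursor_um must be positive")


def _draw_gaps(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    """Gamma-distributed gaps with given mean and coefficient of variation."""
    if cv == 0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=n)


def _peak_positions(rng, length_um, comp: ComponentSpec) -> np.ndarray:
    """Lay a peak train over [0, length]: first peak offset by a uniform
    fraction of one spacing (avoids cohort-wide phase locking), subsequent
    peaks at gamma gaps, truncated at the chromosome end."""
    positions = []
    x = rng.uniform(0, 1) * comp.mean_spacing_um
    while x < length_um:
        positions.append(x)
        x += _draw_gaps(rng, 1, comp.mean_spacing_um, comp.spacing_cv)[0]
    return np.array(positions)


def _render_train(grid, centers, heights, sigma):
    y = np.zeros_like(grid)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    return y


def generate_profiles(spec: ProfileSimSpec, forced_peaks: Optional[dict] = None):
    """Generate a cohort of simulated profiles plus its ground-truth table.

    Parameters
    ----------
    spec : ProfileSimSpec
        Cohort recipe; all randomness flows from ``spec.seed``.
    forced_peaks : dict, optional
        Mapping ``component -> positions`` overriding the random peak trains
        on every chromosome (used for noiseless placement checks).

    Returns
    -------
    profiles : list of ChromosomeProfile
    ground_truth : pandas.DataFrame
        Columns chromosome_id, channel, component, true_position_um (shared
        triad position) and channel_position_um (after per-channel jitter).
    """
    rng = np.random.default_rng(spec.seed)
    profiles, truth_rows = [], []
    components = [("short", spec.short_component)]
    if spec.long_component.present:
        components.append(("long", spec.long_component))

    for i in range(spec.n_chromosomes):
        length = max(spec.length_mean_um / 4, rng.normal(spec.length_mean_um, spec.length_sd_um))
        n_px = int(round(length / spec.pixel_size_um)) + 1
        grid = np.arange(n_px) * spec.pixel_size_um
        cid = f"sim{i:04d}"

        comp_centers = {}
        for name, comp in components:
            if forced_peaks is not None and name in forced_peaks:
                comp_centers[name] = np.asarray(forced_peaks[name], dtype=float)
            else:
                comp_centers[name] = _peak_positions(rng, grid[-1], comp)

        channels = {}
        for role in CHANNEL_ROLES:
            y = np.zeros_like(grid)
            mean_height = 0.0
            for name, comp in components:
                centers = comp_centers[name]
                if centers.size == 0:
                    continue
                jitter = (
                    rng.normal(0, spec.triad_jitter_um, size=centers.size)
                    if spec.triad_jitter_um > 0
                    else np.zeros(centers.size)
                )
                jittered = centers + jitter
                scale = (
                    spec.channel_long_scale.get(role, 1.0) if name == "long" else 1.0
                )
                if comp.height_cv > 0:
                    shape = 1.0 / comp.height_cv**2
                    heights = rng.gamma(
                        shape, scale * comp.mean_height / shape, size=centers.size
                    )
                else:
                    heights = np.full(centers.size, scale * comp.mean_height)
                y += _render_train(grid, jittered, heights, comp.peak_sigma_um)
                mean_height = max(mean_height, comp.mean_height)
                for c, j, h in zip(centers, jittered, heights):
                    truth_rows.append(
                        {
                            "chromosome_id": cid,
                            "channel": role,
                            "component": name,
                            "true_position_um": c,
                            "channel_position_um": j,
                            "height": h,
                        }
                    )
            if spec.noise_sd > 0:
                y += rng.normal(0, spec.noise_sd * mean_height, size=y.size)
            channels[role] = np.clip(y, 0, None)

        profiles.append(
            ChromosomeProfile(
                chromosome_id=cid,
                genotype=spec.genotype,
                pixel_size_um=spec.pixel_size_um,
                positions=grid,
                channels=channels,
            )
        )

    return profiles, pd.DataFrame(truth_rows)


def generate_matched_pair(spec: ProfileSimSpec):
    """Generate a cohort and its matched shorter-periodicity-only control.

    The control cohort reproduces the exact short-component peak trains
    (positions, jitter, heights) of the full cohort and omits the longer
    component and noise -- the synthetic analogue of simulating profiles
    that match the shorter-periodicity peaks visible in experimental data,
    as used for the subtraction analysis of the summed periodicity
    distributions.

    Returns ``(full_profiles, short_only_profiles, ground_truth)``.
    """
    if not spec.long_component.present:
        raise ValueError("matched pair needs a long component in the full cohort")
    full, truth = generate_profiles(spec)
    control = []
    for p in full:
        channels = {}
        for role in CHANNEL_ROLES:
            sub = truth.query(
                "chromosome_id == @p.chromosome_id and channel == @role and component == 'short'"
            )
            y = _render_train(
                p.positions,
                sub["channel_position_um"].to_numpy(),
                sub["height"].to_numpy(),
                spec.short_component.peak_sigma_um,
            )
            channels[role] = np.clip(y, 0, None)
        control.append(
            ChromosomeProfile(
                chromosome_id=p.chromosome_id,
                genotype="matched-control",
                pixel_size_um=p.pixel_size_um,
                positions=p.positions.copy(),
                channels=channels,
            )
        )
    return full, control, truth


def generate_independent_events(
    n_chromosomes: int,
    length_um: float,
    rate_per_um: float,
    seed: int = 0,
    source: str = "simulated",
) -> EventMap:
    """Homogeneous Poisson event placement -- the no-interference null."""
    if rate_per_um < 0:
        raise ValueError("rate must be non-negative")
    if length_um <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    chromosomes = {}
    for i in range(n_chromosomes):
        n = rng.poisson(rate_per_um * length_um)
        chromosomes[f"null{i:05d}"] = (np.sort(rng.uniform(0, length_um, size=n)), length_um)
    return EventMap.from_dict(chromosomes, source=source)


def generate_two_tier_events(spec: PrecursorSimSpec):
    """Sequential two-round crossover designation on a precursor array.

    Returns
    -------
    dict with keys ``canonical``, ``minority`` and ``total`` (:class:`EventMap`);
    minority events occupy precursors strictly between adjacent canonical
    events, so the two maps are disjoint by construction.
    """
    rng = np.random.default_rng(spec.seed)
    canonical, minority = {}, {}
    multiples = np.array(spec.canonical_multiples, dtype=int)
    if multiples.size == 2:
        weights = np.array([spec.weight_two, 1 - spec.weight_two])
    else:
        weights = np.full(multiples.size, 1 / multiples.size)

    for i in range(spec.n_chromosomes):
        length = max(
            2 * spec.inter_precursor_um,
            rng.normal(spec.length_mean_um, spec.length_sd_um),
        )
        cid = f"tier{i:04d}"
        n_prec = int(np.floor(length / spec.inter_precursor_um)) + 1
        precursors = np.arange(n_prec) * spec.inter_precursor_um
        if spec.precursor_jitter_um > 0:
            precursors = precursors + rng.normal(0, spec.precursor_jitter_um, size=n_prec)
            precursors = np.clip(np.sort(precursors), 0, length)
        if n_prec < 3:
            canonical[cid] = (np.array([]), length)
            minority[cid] = (np.array([]), length)
            continue

        # round 1: canonical designations, quantized at 2 or 3 precursor units
        first_step = int(rng.choice(multiples, p=weights))
        idx = int(rng.integers(0, first_step))
        canon_idx = []
        while idx < n_prec:
            canon_idx.append(idx)
            idx += int(rng.choice(multiples, p=weights))

        # round 2: minority designations at unreacted precursors between
        # adjacent canonical events (highest residual designation potential);
        # adjacent gaps are never both filled, so round-2 events interfere
        minor_idx = []
        prev_filled = False
        for a, b in zip(canon_idx[:-1], canon_idx[1:]):
            free = list(range(a + 1, b))
            if free and not prev_filled and rng.uniform() < spec.minority_fill_prob:
                minor_idx.append(int(rng.choice(free)))
                prev_filled = True
            else:
                prev_filled = False

        canonical[cid] = (precursors[canon_idx], length)
        minority[cid] = (precursors[minor_idx], length)

    canonical_map = EventMap.from_dict(canonical, source="simulated")
    minority_map = EventMap.from_dict(minority, source="simulated")
    total = {
        cid: (
            np.sort(np.concatenate([canonical[cid][0], minority[cid][0]])),
            canonical[cid][1],
        )
        for cid in canonical
    }
    return {
        "canonical": canonical_map,
        "minority": minority_map,
        "total": EventMap.from_dict(total, source="simulated"),
    }
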