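"""Event-pattern statistics: spacings, fits, colocalization, and coincidence.

The central container is :class:`EventMap` -- per-chromosome sorted lists of
event positions in micrometers, whether those events are iFFT-band intensity
peaks, cytological crossover foci, DNA-defined crossovers converted from bp,
or simulated designations.

Crossover interference is quantified two ways:

* the coefficient of coincidence (CoC): chromosomes are cut into equal
  relative-length intervals; for each interval pair the observed frequency of
  chromosomes with an event in both is divided by the product of the two
  single-interval frequencies.  CoC = 1 means independence, 0 complete
  interference.  ``l_coc`` reports the inter-interval distance at which the
  curve first reaches 0.5.
* the distribution of adjacent-event spacings, summarized by a single gamma
  fit (shape alpha measures evenness; the mode is the typical spacing) or by
  a two-component Gaussian mixture (resolving spacings quantized at small
  integer multiples of the ~0.23 um inter-precursor distance).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

#: Conversion between DNA length and pachytene axis length.
DEFAULT_BP_PER_NM = 324.0

#: Interval counts used for CoC analysis of each event class.
N_INTERVALS = {"shorter": 30, "total": 30, "longer": 17}


@dataclasses.dataclass
class EventMap:
    """Per-chromosome event positions (um) on chromosomes of known length."""

    positions: dict  # chromosome_id -> ndarray of sorted positions (um)
    lengths: dict  # chromosome_id -> length (um)
    source: str = "unspecified"

    def __post_init__(self):
        for cid, pos in self.positions.items():
            pos = np.sort(np.asarray(pos, dtype=float))
            length = self.lengths[cid]
            if length <= 0:
                raise ValueError(f"{cid}: non-positive length")
            if pos.size and (pos[0] < 0 or pos[-1] > length + 1e-9):
                raise ValueError(f"{cid}: events outside [0, {length}]")
            self.positions[cid] = pos

    @classmethod
    def from_dict(cls, chromosomes: Mapping, source: str = "unspecified") -> "EventMap":
        """Build from ``{chromosome_id: (positions, length_um)}``."""
        return cls(
            positions={cid: np.asarray(p, dtype=float) for cid, (p, _) in chromosomes.items()},
            lengths={cid: float(length) for cid, (_, length) in chromosomes.items()},
            source=source,
        )

    @property
    def chromosome_ids(self):
        return list(self.positions)

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def n_events(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    @property
    def mean_length_um(self) -> float:
        return float(np.mean(list(self.lengths.values())))

    def reversed(self) -> "EventMap":
        """Flip every chromosome end-for-end (distance statistics invariant)."""
        return EventMap(
            positions={
                cid: np.sort(self.lengths[cid] - p) for cid, p in self.positions.items()
            },
            lengths=dict(self.lengths),
            source=self.source,
        )


@dataclasses.dataclass
class CoCCurve:
    """Mean coefficient of coincidence vs inter-interval distance."""

    n_intervals: int
    distances_um: np.ndarray  # one per inter-interval separation 1..n-1
    coc: np.ndarray  # NaN where every pair at that separation had zero expectation
    n_pairs: np.ndarray  # pairs contributing at each separation
    n_excluded: int  # pairs dropped for zero expected frequency
    mean_length_um: float
    n_chromosomes: int


@dataclasses.dataclass
class GammaFit:
    """Maximum-likelihood single gamma fit to a spacing distribution."""

    alpha: float  # shape; larger = more even spacing
    scale_um: float
    log_likelihood: float
    n: int

    @property
    def mode_um(self) -> float:
        return max(self.alpha - 1.0, 0.0) * self.scale_um

    @property
    def mean_um(self) -> float:
        return self.alpha * self.scale_um


def peaks_to_eventmap(peaksets: Sequence, lengths: Mapping, mode: str = "single") -> EventMap:
    """Assemble an :class:`EventMap` from per-chromosome :class:`PeakSet` s.

    Parameters
    ----------
    peaksets : sequence of PeakSet
        All from one channel.  With ``mode='single'`` every peakset must be
        from the same band; ``mode='union'`` merges shorter and longer bands
        into "total" events, dropping duplicate pixels.
    lengths : mapping chromosome_id -> length_um
        Needed so chromosomes whose peakset is empty still contribute to CoC
        denominators.
    """
    channels = {ps.channel for ps in peaksets}
    if len(channels) > 1:
        raise ValueError(f"peaksets mix channels {sorted(channels)}; build one map per channel")
    bands = {ps.band for ps in peaksets}
    if mode == "single" and len(bands) > 1:
        raise ValueError(f"peaksets mix bands {sorted(bands)}; pass mode='union' to merge")

    pooled: dict = {cid: [] for cid in lengths}
    for ps in peaksets:
        pooled.setdefault(ps.chromosome_id, []).extend(ps.positions_um)
    positions = {cid: np.unique(np.asarray(vals, dtype=float)) for cid, vals in pooled.items()}
    band = bands.pop() if len(bands) == 1 else "total"
    return EventMap(
        positions=positions,
        lengths={cid: float(lengths[cid]) for cid in positions},
        source=f"iFFT-{band}",
    )


def adjacent_spacings(events: EventMap) -> np.ndarray:
    """All consecutive within-chromosome event spacings, pooled (um)."""
    gaps = [np.diff(p) for p in events.positions.values() if p.size >= 2]
    return np.concatenate(gaps) if gaps else np.array([])


def fit_gamma(spacings: Iterable) -> GammaFit:
    """Maximum-likelihood gamma fit (location fixed at 0)."""
    x = np.asarray(list(spacings), dtype=float)
    if x.size < 20:
        raise ValueError(f"need at least 20 spacings, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("spacings must be strictly positive")
    alpha, _, scale = stats.gamma.fit(x, floc=0)
    ll = float(np.sum(stats.gamma.logpdf(x, alpha, loc=0, scale=scale)))
    return GammaFit(alpha=float(alpha), scale_um=float(scale), log_likelihood=ll, n=x.size)


def fit_two_gaussian_spacings(spacings: Iterable, seed: int = 0):
    """Two-component Gaussian mixture fit to a spacing distribution.

    Shares the EM implementation of :func:`triadscan.spectral.fit_gmm2`;
    means come back sorted ascending.
    """
    from .spectral import fit_gmm2

    return fit_gmm2(np.asarray(list(spacings), dtype=float), seed=seed)


def nearest_heterologous_distances(
    peaks_a: Mapping, peaks_b: Mapping, log: Optional[list] = None
) -> np.ndarray:
    """For every A-event, the distance to the nearest B-event (pooled, um).

    ``peaks_a``/``peaks_b`` map chromosome_id -> positions; chromosomes
    missing from B (or with no B events) are skipped and optionally logged.
    """
    out = []
    for cid, a in peaks_a.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(peaks_b.get(cid, []), dtype=float)
        if a.size == 0:
            continue
        if b.size == 0:
            if log is not None:
                log.append(f"{cid}: no B events; skipped")
            continue
        out.append(np.min(np.abs(a[:, None] - b[None, :]), axis=1))
    return np.concatenate(out) if out else np.array([])


def modal_value(values: np.ndarray, bin_width_um: float = 0.067) -> float:
    """Histogram mode with bins centered on multiples of ``bin_width_um``.

    Pixel-quantized distances (0, 67, 134 ... nm) each fall at a bin center,
    so the mode is reported on the pixel grid itself.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan")
    edges = np.arange(-bin_width_um / 2, values.max() + 1.5 * bin_width_um, bin_width_um)
    counts, _ = np.histogram(values, bins=edges)
    return float(bin_width_um * int(np.argmax(counts)))


@dataclasses.dataclass
class ChanceExpectation:
    """Null nearest-distance distribution from circular randomization.

    ``half_mean_spacing_um`` is the analytic chance reference: half the mean
    adjacent spacing of the randomized channel -- the farthest a point can
    sit from a regular array of that spacing, and the conventional dashed
    "expected by chance" line.  The empirical shuffle null itself is a
    decreasing density (mode at zero, median about a quarter of the
    spacing); both are reported.
    """

    distances_um: np.ndarray
    mode_um: float
    median_um: float
    mean_um: float
    half_mean_spacing_um: float
    n_rounds: int


def chance_expectation(
    peaks_a: Mapping,
    peaks_b: Mapping,
    lengths: Mapping,
    n_rounds: int = 200,
    seed: int = 0,
    method: str = "circular",
    bin_width_um: float = 0.067,
) -> ChanceExpectation:
    """Distances expected if the B channel were positioned independently of A.

    ``method='circular'`` shifts each chromosome's B events by a uniform
    random offset modulo chromosome length, preserving B's internal spacing
    structure; ``method='uniform'`` redraws B positions uniformly.
    """
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_rounds):
        shifted = {}
        for cid, b in peaks_b.items():
            b = np.asarray(b, dtype=float)
            length = lengths[cid]
            if method == "circular":
                shifted[cid] = np.sort((b + rng.uniform(0, length)) % length)
            elif method == "uniform":
                shifted[cid] = np.sort(rng.uniform(0, length, size=b.size))
            else:
                raise ValueError(f"unknown randomization method {method!r}")
        pooled.append(nearest_heterologous_distances(peaks_a, shifted))
    distances = np.concatenate([d for d in pooled if d.size]) if pooled else np.array([])
    b_gaps = [np.diff(np.sort(np.asarray(b, dtype=float))) for b in peaks_b.values()]
    b_gaps = np.concatenate([g for g in b_gaps if g.size]) if b_gaps else np.array([])
    return ChanceExpectation(
        distances_um=distances,
        mode_um=modal_value(distances, bin_width_um),
        median_um=float(np.median(distances)) if distances.size else float("nan"),
        mean_um=float(np.mean(distances)) if distances.size else float("nan"),
        half_mean_spacing_um=float(np.mean(b_gaps) / 2) if b_gaps.size else float("nan"),
        n_rounds=n_rounds,
    )


@dataclasses.dataclass
class LongerShorterRelation:
    """Spatial relation of longer-band peaks to the shorter-band array."""

    distances_um: np.ndarray  # each longer peak -> nearest shorter peak
    median_um: float
    fraction_ge_100nm: float  # interdigitation fraction
    count_ratios: np.ndarray  # per-chromosome (#longer / #shorter)
    median_ratio: float
    n_peak_pairs: int


def longer_vs_shorter_relation(
    peaks_long: Mapping, peaks_short: Mapping, log: Optional[list] = None
) -> LongerShorterRelation:
    """Distances from each longer-periodicity peak to its nearest
    shorter-periodicity peak of the same molecule, plus per-chromosome
    longer:shorter count ratios."""
    distances = nearest_heterologous_distances(peaks_long, peaks_short, log=log)
    ratios = []
    for cid, lp in peaks_long.items():
        sp = np.asarray(peaks_short.get(cid, []), dtype=float)
        if sp.size == 0:
            if log is not None:
                log.append(f"{cid}: no shorter-band peaks; ratio skipped")
            continue
        ratios.append(len(lp) / sp.size)
    ratios = np.asarray(ratios)
    return LongerShorterRelation(
        distances_um=distances,
        median_um=float(np.median(distances)) if distances.size else float("nan"),
        fraction_ge_100nm=float(np.mean(distances >= 0.100)) if distances.size else float("nan"),
        count_ratios=ratios,
        median_ratio=float(np.median(ratios)) if ratios.size else float("nan"),
        n_peak_pairs=int(distances.size),
    )


def _occupancy(events: EventMap, n_intervals: int) -> np.ndarray:
    """Binary chromosome x interval matrix; intervals are equal relative-length
    bins [i/n, (i+1)/n), last bin closed."""
    occ = np.zeros((events.n_chromosomes, n_intervals), dtype=bool)
    for row, (cid, pos) in enumerate(events.positions.items()):
        if pos.size == 0:
            continue
        rel = pos / events.lengths[cid]
        idx = np.minimum((rel * n_intervals).astype(int), n_intervals - 1)
        occ[row, idx] = True
    return occ


def coc_curve(events: EventMap, n_intervals: int = 30) -> CoCCurve:
    """Coefficient-of-coincidence curve over all interval pairs.

    Each chromosome is divided into ``n_intervals`` equal relative-length
    bins.  For every interval pair (i < j) the CoC is the observed fraction
    of chromosomes with an event in both bins divided by the product of the
    two single-bin fractions; values are averaged over pairs sharing the same
    separation ``|i - j|``.  Distances are reported in micrometers via the
    cohort mean chromosome length.  Pairs whose expected frequency is zero
    are excluded and counted.
    """
    if events.n_chromosomes < 20:
        warnings.warn(
            f"CoC on only {events.n_chromosomes} chromosomes is noisy", stacklevel=2
        )
    occ = _occupancy(events, n_intervals)
    f = occ.mean(axis=0)
    mean_len = events.mean_length_um

    sums = np.zeros(n_intervals)  # index = separation
    counts = np.zeros(n_intervals, dtype=int)
    excluded = 0
    for i in range(n_intervals):
        for j in range(i + 1, n_intervals):
            expected = f[i] * f[j]
            if expected == 0:
                excluded += 1
                continue
            observed = np.mean(occ[:, i] & occ[:, j])
            sep = j - i
            sums[sep] += observed / expected
            counts[sep] += 1

    seps = np.arange(1, n_intervals)
    with np.errstate(invalid="ignore"):
        coc = np.where(counts[seps] > 0, sums[seps] / np.maximum(counts[seps], 1), np.nan)
    return CoCCurve(
        n_intervals=n_intervals,
        distances_um=seps * mean_len / n_intervals,
        coc=coc,
        n_pairs=counts[seps],
        n_excluded=excluded,
        mean_length_um=mean_len,
        n_chromosomes=events.n_chromosomes,
    )


def l_coc(curve: CoCCurve, level: float = 0.5) -> float:
    """Inter-interval distance at which the CoC curve first reaches ``level``.

    Linear interpolation at the first upward crossing along increasing
    distance.  A curve already at or above the level at its first defined
    point is interpolated from the origin (CoC -> 0 as distance -> 0 under
    complete interference).  Returns NaN when the curve never crosses.
    """
    d = curve.distances_um
    c = curve.coc
    valid = ~np.isnan(c)
    d, c = d[valid], c[valid]
    if d.size == 0:
        return float("nan")
    if c[0] >= level:
        return float(d[0] * level / c[0]) if c[0] > 0 else float("nan")
    for k in range(1, c.size):
        if c[k - 1] < level <= c[k]:
            frac = (level - c[k - 1]) / (c[k] - c[k - 1])
            return float(d[k - 1] + frac * (d[k] - d[k - 1]))
    return float("nan")


def bp_to_um(positions_bp: Iterable, bp_per_nm: float = DEFAULT_BP_PER_NM) -> np.ndarray:
    """Convert DNA coordinates (bp) to pachytene axis distance (um).

    The default 324 bp/nm is the average packing ratio of yeast pachytene
    chromosomes (known Mb sizes over measured axis lengths).
    """
    pos = np.asarray(list(positions_bp) if not isinstance(positions_bp, np.ndarray) else positions_bp, dtype=float)
    if np.any(pos < 0):
        raise ValueError("bp positions must be non-negative")
    return pos / (bp_per_nm * 1000.0)
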