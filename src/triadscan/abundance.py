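"""Abundance and co-abundance statistics across channels and genotypes.

The dissimilarity index quantifies how differently two molecules are loaded
along one chromosome: both series are z-scored (mean 0, sd 1) and the mean
unsigned difference of the two z-series is reported.  Identically shaped
profiles score 0; independent profiles score near E|Z1 - Z2| = 2/sqrt(pi)
for standard normals.  The index is computed for every channel pair on the
total signal and on each iFFT band component (each band z-scored as a signal
in its own right), and compared across genotypes with two-sample t-tests.

Population-average profiles rescale every chromosome to unit length (cubic
spline interpolation onto a common relative grid) and average pointwise;
because spread chromosomes have no intrinsic orientation, the average is
symmetrized with its mirror image by default.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .bands import split_bands
from .profile_io import ChromosomeProfile, zscore

CHANNEL_PAIRS = (("axis", "sc"), ("crossover", "axis"), ("crossover", "sc"))
SIGNAL_CLASSES = ("total", "shorter", "longer")


def dissimilarity_index(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Mean unsigned difference of the two z-scored series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("series must share a length of at least 2")
    za, const_a = zscore(a)
    zb, const_b = zscore(b)
    if const_a or const_b:
        raise ValueError("dissimilarity undefined for a constant series")
    return float(np.mean(np.abs(za - zb)))


def dissimilarity_table(
    profiles: Sequence[ChromosomeProfile],
    threshold_nm: float = 875.0,
    log: Optional[list] = None,
) -> pd.DataFrame:
    """Dissimilarity index per chromosome x channel pair x signal class.

    Classes: ``total`` (raw signal), ``shorter`` and ``longer`` (iFFT band
    components, z-scored as signals in their own right).
    """
    rows = []
    for p in profiles:
        series = {("total", role): p.channels[role] for role in p.roles}
        for role in p.roles:
            comp = split_bands(p, role, threshold_nm=threshold_nm)
            series[("shorter", role)] = comp.shorter
            series[("longer", role)] = comp.longer
        for sig_class in SIGNAL_CLASSES:
            for a, b in CHANNEL_PAIRS:
                if a not in p.roles or b not in p.roles:
                    continue
                try:
                    idx = dissimilarity_index(series[(sig_class, a)], series[(sig_class, b)])
                except ValueError as exc:
                    if log is not None:
                        log.append(f"{p.chromosome_id} {sig_class} {a}-{b}: {exc}")
                    continue
                rows.append(
                    {
                        "chromosome_id": p.chromosome_id,
                        "genotype": p.genotype,
                        "pair": f"{a}-{b}",
                        "signal_class": sig_class,
                        "dissimilarity": idx,
                    }
                )
    return pd.DataFrame(rows)


def compare_groups(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    """Per pair/class two-sided two-sample t-test between genotype groups.

    No multiplicity correction is applied by default (each pair/class cell is
    reported as its own comparison); apply one downstream if needed.
    """
    rows = []
    cells = set(map(tuple, records_a[["pair", "signal_class"]].to_numpy())) | set(
        map(tuple, records_b[["pair", "signal_class"]].to_numpy())
    )
    for pair, sig_class in sorted(cells):
        xa = records_a.query("pair == @pair and signal_class == @sig_class")["dissimilarity"]
        xb = records_b.query("pair == @pair and signal_class == @sig_class")["dissimilarity"]
        row = {
            "pair": pair,
            "signal_class": sig_class,
            "n_a": len(xa),
            "n_b": len(xb),
            "mean_a": xa.mean() if len(xa) else np.nan,
            "mean_b": xb.mean() if len(xb) else np.nan,
        }
        if len(xa) >= 3 and len(xb) >= 3:
            t, p = stats.ttest_ind(xa, xb)
            row.update(mean_difference=xa.mean() - xb.mean(), t=float(t), p=float(p))
        else:
            row.update(mean_difference=np.nan, t=np.nan, p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def population_average(
    profiles: Sequence[ChromosomeProfile],
    channel: str,
    n_grid: int = 101,
    symmetrize: bool = True,
) -> pd.DataFrame:
    """Unit-length population-average profile of one channel.

    Each profile is cubic-spline interpolated (natural boundary) onto a
    common grid of ``n_grid`` relative positions in [0, 1] and averaged
    pointwise.  ``symmetrize`` averages the result with its reverse, since
    chromosome ends are unoriented in spreads.
    """
    if not profiles:
        raise ValueError("cohort is empty")
    grid = np.linspace(0, 1, n_grid)
    stack = []
    for p in profiles:
        rel = p.positions / p.positions[-1]
        spline = CubicSpline(rel, p.channels[channel], bc_type="natural")
        stack.append(spline(grid))
    mean = np.mean(stack, axis=0)
    if symmetrize:
        mean = (mean + mean[::-1]) / 2
    return pd.DataFrame({"relative_position": grid, "mean_intensity": mean})


def mean_channel_intensity(profiles: Sequence[ChromosomeProfile]) -> pd.DataFrame:
    """Per-chromosome channel means with genotype labels (ADU)."""
    rows = []
    for p in profiles:
        for role in p.roles:
            rows.append(
                {
                    "chromosome_id": p.chromosome_id,
                    "genotype": p.genotype,
                    "channel": role,
                    "mean_intensity": float(p.channels[role].mean()),
                }
            )
    return pd.DataFrame(rows)


def genotype_intensity_summary(per_chromosome: pd.DataFrame) -> pd.DataFrame:
    """Genotype x channel mean of per-chromosome mean intensities."""
    return (
        per_chromosome.groupby(["genotype", "channel"], as_index=False)["mean_intensity"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
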