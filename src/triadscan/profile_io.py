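"""Reading, validation and normalization of chromosome intensity profiles.

Profiles are one-dimensional linescans traced along the mid-line of a spread
pachytene chromosome, one intensity series per immunostained molecule.  The
canonical on-disk dialect is the Fiji "Plot Profile" CSV export: a distance
column (pixels or micrometers) and a gray-value column, one file per channel,
all channels sharing the same traced path and therefore the same grid.

Channels are keyed by *role* rather than by molecule name so that Zip3- and
Zip2-based experiments share one code path:

    ``crossover``  -- ZMM crossover marker (Zip3 or Zip2)
    ``axis``       -- axis/HORMAD component (Hop1)
    ``sc``         -- synaptonemal-complex transverse filament (Zip1)
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Effective camera pixel size of the acquisition system, in micrometers.
DEFAULT_PIXEL_SIZE_UM = 0.067

#: Recognised channel roles, in canonical order.
CHANNEL_ROLES = ("crossover", "axis", "sc")

_GRID_TOL = 1e-9


class ProfileDialectError(ValueError):
    """Input CSVs disagree in shape or grid, or cannot be parsed."""


@dataclasses.dataclass
class ChromosomeProfile:
    """One traced chromosome: a uniform position grid plus per-channel ADU series.

    Parameters
    ----------
    chromosome_id : str
        Identifier carried through every downstream table.
    genotype : str
        Free-text genotype label (e.g. ``"WT"``, ``"pch2D"``, ``"top2"``).
    pixel_size_um : float
        Grid step in micrometers (67 nm camera pixels by default).
    positions : ndarray
        Strictly ascending uniform grid in micrometers, length ``N >= 16``
        for spectral work (construction allows ``N >= 2``; spectral
        operations enforce their own minimum).
    channels : dict of str -> ndarray
        Intensity series (ADU, finite, non-negative) keyed by channel role.
    """

    chromosome_id: str
    genotype: str = "WT"
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    positions: np.ndarray = None
    channels: dict = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self._validate()

    def _validate(self):
        n = self.positions.size
        if n < 2:
            raise ValueError(f"{self.chromosome_id}: need at least 2 positions, got {n}")
        steps = np.diff(self.positions)
        if np.any(steps <= 0):
            raise ValueError(f"{self.chromosome_id}: positions must be strictly increasing")
        if np.any(np.abs(steps - self.pixel_size_um) > _GRID_TOL):
            raise ValueError(
                f"{self.chromosome_id}: non-uniform grid (expected step {self.pixel_size_um} um)"
            )
        for role, series in self.channels.items():
            if series.shape != self.positions.shape:
                raise ValueError(
                    f"{self.chromosome_id}: channel '{role}' has length {series.size}, "
                    f"grid has {n}"
                )
            if not np.all(np.isfinite(series)):
                raise ValueError(f"{self.chromosome_id}: channel '{role}' has non-finite values")
            if np.any(series < 0):
                raise ValueError(f"{self.chromosome_id}: channel '{role}' has negative intensities")

    @property
    def n_pixels(self) -> int:
        return self.positions.size

    @property
    def length_um(self) -> float:
        """Traced length, (N-1) * pixel size."""
        return (self.positions.size - 1) * self.pixel_size_um

    @property
    def roles(self) -> tuple:
        return tuple(self.channels)


@dataclasses.dataclass
class NormalizedProfile:
    """Z-scored counterpart of :class:`ChromosomeProfile`.

    Each channel is stored as the number of standard deviations from that
    channel's own mean.  Constant raw channels map to all-zero series and are
    listed in ``constant_channels``.
    """

    chromosome_id: str
    genotype: str
    pixel_size_um: float
    positions: np.ndarray
    channels: dict
    constant_channels: tuple = ()


def _read_one_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap for a uniform error surface
        raise ProfileDialectError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise ProfileDialectError(f"{path}: expected a distance and an intensity column")
    df = df.iloc[:, :2]
    df.columns = ["distance", "intensity"]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ProfileDialectError(f"{path}: non-numeric value in column '{col}' at row {row}")
        df[col] = coerced
    return df


def _distances_to_um(distance: np.ndarray, pixel_size_um: float, units: str) -> np.ndarray:
    """Convert a Plot-Profile distance column to micrometers.

    Fiji exports pixels by default; calibrated images export micrometers.
    ``units='auto'`` distinguishes the two by the grid step (a step near 1 is
    a pixel grid, a step near the pixel size is already micrometers).
    """
    step = float(np.median(np.diff(distance)))
    if units == "auto":
        units = "px" if abs(step - 1.0) < abs(step - pixel_size_um) else "um"
    if units == "px":
        return distance * pixel_size_um
    if units == "um":
        return distance.astype(float)
    raise ValueError(f"unknown distance units {units!r}")


def read_plot_profile(
    paths: Mapping[str, "str | Path"],
    chromosome_id: str,
    genotype: str = "WT",
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    distance_units: str = "auto",
) -> ChromosomeProfile:
    """Merge one Plot-Profile CSV per channel into a :class:`ChromosomeProfile`.

    Parameters
    ----------
    paths : mapping of role -> path
        One CSV per channel role; all files must share row count and grid.
    distance_units : {'auto', 'px', 'um'}
        Interpretation of the distance column; auto-detected by default.
    """
    frames = {}
    for role, path in paths.items():
        if role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}")
        frames[role] = (Path(path), _read_one_csv(path))

    counts = {role: len(df) for role, (_, df) in frames.items()}
    if len(set(counts.values())) > 1:
        majority = max(set(counts.values()), key=list(counts.values()).count)
        offending = [str(frames[r][0]) for r, c in counts.items() if c != majority]
        raise ProfileDialectError(
            f"row-count mismatch between channels: {counts}; offending file(s): {offending}"
        )

    ref_role = next(iter(frames))
    ref_path, ref_df = frames[ref_role]
    ref_dist = ref_df["distance"].to_numpy()
    for role, (path, df) in frames.items():
        if not np.allclose(df["distance"].to_numpy(), ref_dist, atol=1e-9, rtol=0):
            raise ProfileDialectError(
                f"distance grid of {path} does not match {ref_path}"
            )

    positions = _distances_to_um(ref_dist, pixel_size_um, distance_units)
    # re-grid onto exact multiples of the pixel size to absorb export rounding
    start = positions[0]
    idx = np.round((positions - start) / pixel_size_um)
    positions = start + idx * pixel_size_um
    return ChromosomeProfile(
        chromosome_id=chromosome_id,
        genotype=genotype,
        pixel_size_um=pixel_size_um,
        positions=positions,
        channels={role: df["intensity"].to_numpy() for role, (_, df) in frames.items()},
    )


def read_wide_profile(
    path,
    chromosome_id: str = None,
    genotype: str = "WT",
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> ChromosomeProfile:
    """Read the canonical wide CSV (columns position_um, crossover, axis, sc)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "position_um" not in df.columns:
        raise ProfileDialectError(f"{path}: missing 'position_um' column")
    roles = [r for r in CHANNEL_ROLES if r in df.columns]
    if not roles:
        raise ProfileDialectError(f"{path}: no channel columns among {CHANNEL_ROLES}")
    return ChromosomeProfile(
        chromosome_id=chromosome_id or Path(path).stem,
        genotype=genotype,
        pixel_size_um=pixel_size_um,
        positions=df["position_um"].to_numpy(float),
        channels={r: df[r].to_numpy(float) for r in roles},
    )


def write_profile(profile: ChromosomeProfile, path) -> Path:
    """Write the canonical wide CSV; round-trips at full float precision."""
    path = Path(path)
    df = pd.DataFrame({"position_um": profile.positions})
    for role in profile.roles:
        df[role] = profile.channels[role]
    # pandas' default float formatting is the shortest round-trip repr,
    # so values survive write/read bit-for-bit
    df.to_csv(path, index=False)
    return path


def write_manifest(profiles: Iterable[ChromosomeProfile], paths: Sequence, out_path) -> Path:
    """Write a cohort manifest CSV (chromosome_id, genotype, file, length_um)."""
    rows = [
        {
            "chromosome_id": p.chromosome_id,
            "genotype": p.genotype,
            "file": str(fp),
            "length_um": p.length_um,
        }
        for p, fp in zip(profiles, paths)
    ]
    out_path = Path(out_path)
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path


def read_manifest(path) -> list:
    """Load every profile referenced by a manifest CSV.

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    profiles = []
    for _, row in df.iterrows():
        fp = Path(row["file"])
        if not fp.is_absolute():
            fp = path.parent / fp
        if not fp.exists():
            raise FileNotFoundError(f"manifest entry missing on disk: {fp}")
        profiles.append(
            read_wide_profile(fp, chromosome_id=row["chromosome_id"], genotype=row.get("genotype", "WT"))
        )
    return profiles


def zscore(series: np.ndarray, ddof: int = 1) -> tuple:
    """Z-score a series with the sample standard deviation (ddof=1).

    Returns ``(z, is_constant)``; a constant series maps to all zeros.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples to z-score")
    sd = series.std(ddof=ddof)
    if sd == 0:
        return np.zeros_like(series), True
    return (series - series.mean()) / sd, False


def normalize_by_std(profile: ChromosomeProfile) -> NormalizedProfile:
    """Express every channel as standard deviations from its own mean.

    The sample standard deviation (denominator N-1) is used throughout the
    package so that dissimilarity indices are reproducible.
    """
    channels, constant = {}, []
    for role, series in profile.channels.items():
        z, is_const = zscore(series)
        channels[role] = z
        if is_const:
            constant.append(role)
    return NormalizedProfile(
        chromosome_id=profile.chromosome_id,
        genotype=profile.genotype,
        pixel_size_um=profile.pixel_size_um,
        positions=profile.positions.copy(),
        channels=channels,
        constant_channels=tuple(constant),
    )


def normalize_max_unity(series: np.ndarray) -> np.ndarray:
    """Scale a series so its largest value equals 1 (shape-preserving)."""
    series = np.asarray(series, dtype=float)
    m = series.max()
    if m <= 0:
        raise ValueError("cannot normalize a series with non-positive maximum")
    return series / m
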