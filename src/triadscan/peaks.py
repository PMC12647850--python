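"""Peak detection on band-decomposed signals at one-pixel resolution.

Detection has two stages.  Interior local maxima are found first (after a
3-pixel centered moving average for shorter-band signals, which damps
pixel-level noise without moving 0.5 um-scale peaks).  A second pass rescues
"humps": shoulders on the flank of a detected maximum that never become
local maxima themselves.  A shoulder is a dip in the slope magnitude with no
sign change -- on a falling flank it appears as a local maximum of the first
derivative with negative value, on a rising flank as a local minimum with
positive value.  The rescued hump is placed at the pixel of that slope-
magnitude dip, provided it is farther than ``hump_exclusion_px`` (default 1)
from any detected maximum.  Endpoints are never reported as peaks, and no
sub-pixel interpolation is performed: positions are deliberately
pixel-quantized (67 nm).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks

#: Minimum pixel separation between a detected maximum and a rescued hump.
HUMP_EXCLUSION_PX = 1


@dataclasses.dataclass
class PeakSet:
    """Pixel-resolved peak positions for one channel/band of one chromosome."""

    chromosome_id: str
    channel: str
    band: str  # 'shorter' | 'longer' | 'total'
    positions_um: np.ndarray  # strictly increasing, on the pixel grid
    kinds: np.ndarray  # 'maximum' | 'hump' per peak
    heights: np.ndarray
    pixel_size_um: float

    @property
    def n_peaks(self) -> int:
        return self.positions_um.size

    def maxima_only(self) -> "PeakSet":
        keep = self.kinds == "maximum"
        return dataclasses.replace(
            self,
            positions_um=self.positions_um[keep],
            kinds=self.kinds[keep],
            heights=self.heights[keep],
        )


def moving_average3(y: np.ndarray) -> np.ndarray:
    """Centered 3-pixel moving average; the window shrinks to 1 at the ends."""
    y = np.asarray(y, dtype=float)
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Interior local maxima; plateaus resolve to their leftmost pixel."""
    idx, props = find_peaks(y, plateau_size=(1, None))
    return props["left_edges"].astype(int)


def _rescue_humps(y: np.ndarray, max_idx: np.ndarray, exclusion_px: int) -> list:
    """Shoulder rescue on the first derivative (see module docstring).

    Derivative index k measures the step between pixels k and k+1; the dip
    rounds to the pixel on the far side of the nearest maximum, where the
    hidden component is centered (k+1 on a falling flank, k on a rising one).
    """
    d = np.diff(y)
    if d.size < 3 or max_idx.size == 0:
        return []
    tol = 1e-12 * max(np.abs(d).max(), 1e-300)
    candidates = []  # (derivative index, pixel)
    for k in _local_maxima(d):
        if d[k] < -tol:  # slope relaxes toward zero while still falling
            candidates.append((k, k + 1))
    for k in _local_maxima(-d):
        if d[k] > tol:  # slope dips while still rising
            candidates.append((k, k))
    humps = []
    for k, p in candidates:
        # a genuine shoulder keeps one slope sign between the dip and the
        # nearest detected maximum (no intervening extremum of the signal)
        m = int(max_idx[np.argmin(np.abs(max_idx - p))])
        lo, hi = (p, m) if p < m else (m + 1, k)
        seg = d[lo:hi]
        signs = np.sign(seg[np.abs(seg) > tol])
        if signs.size and not np.all(signs == signs[0]):
            continue
        if np.min(np.abs(max_idx - p)) > exclusion_px and 0 < p < y.size - 1:
            humps.append(p)
    return humps


def detect_peaks(
    series: np.ndarray,
    band: str,
    pixel_size_um: float,
    chromosome_id: str = "",
    channel: str = "",
    min_prominence: float = None,
    rescue_humps: bool = True,
    hump_exclusion_px: int = HUMP_EXCLUSION_PX,
    positive_only: bool = True,
) -> PeakSet:
    """Locate peaks (maxima plus rescued humps) in a band component.

    Parameters
    ----------
    series : ndarray
        Band-decomposed (or raw) intensity series, length >= 5.
    band : {'shorter', 'longer', 'total'}
        Shorter-band signals are smoothed with a 3-pixel moving average
        before detection.
    min_prominence : float, optional
        Off by default (the detector mimics a plain local-maximum finder);
        set for noisy data.
    positive_only : bool
        Keep only peaks whose signal value is positive (default on).  In a
        band-reconstructed signal an intensity peak is a positive excursion;
        local maxima at or below zero are ringing or noise artifacts of the
        brick-wall filter, and discarding them removes most false detections
        at a small recall cost.  Set False for the raw unthresholded
        detector behavior.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 5:
        raise ValueError(f"need at least 5 samples, got {y.size}")
    if band not in ("shorter", "longer", "total"):
        raise ValueError(f"unknown band {band!r}")
    if band == "shorter":
        y = moving_average3(y)

    if min_prominence is not None:
        max_idx, _ = find_peaks(y, prominence=min_prominence)
        max_idx = max_idx.astype(int)
    else:
        max_idx = _local_maxima(y)

    hump_idx = _rescue_humps(y, max_idx, hump_exclusion_px) if rescue_humps else []

    all_idx = np.concatenate([max_idx, np.asarray(hump_idx, dtype=int)])
    kinds = np.array(["maximum"] * max_idx.size + ["hump"] * len(hump_idx))
    order = np.argsort(all_idx)
    all_idx, kinds = all_idx[order], kinds[order]
    if all_idx.size:
        keep = np.concatenate([[True], np.diff(all_idx) > 0])  # drop coincident pixels
        all_idx, kinds = all_idx[keep], kinds[keep]
    if positive_only and all_idx.size:
        pos_mask = y[all_idx] > 0
        all_idx, kinds = all_idx[pos_mask], kinds[pos_mask]

    return PeakSet(
        chromosome_id=chromosome_id,
        channel=channel,
        band=band,
        positions_um=all_idx * pixel_size_um,
        kinds=kinds,
        heights=y[all_idx],
        pixel_size_um=pixel_size_um,
    )


def detect_band_peaks(components, band: str, **kwargs) -> PeakSet:
    """Detect peaks in one band of a :class:`triadscan.bands.BandComponents`."""
    series = getattr(components, band) if band != "total" else components.total
    return detect_peaks(
        series,
        band,
        components.pixel_size_um,
        chromosome_id=components.chromosome_id,
        channel=components.channel,
        **kwargs,
    )
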