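"""Apical-basal axis intensity-profile statistics.

Profiles are fluorescence line scans along the apical-basal axis of
groups of follicle cells, position 0 at the apical end.  Localization
along the axis is summarised by the position at which the cumulative
trapezoidal area under the profile reaches 50% of the total (auc50):
apically concentrated signal gives auc50 < 0.5, uniform signal gives
exactly 0.5.  The module also computes integrated-density fractions over
the apical-cortical / subapical / basal subdomains used for thresholded
smFISH signal, channel-wise 0-1 normalization for multi-channel line
scans, and a peak-coincidence score as a quantitative colocalization
proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from apicobasal.polarity import TestResult, two_sample_t

logger = logging.getLogger(__name__)


class ZeroAreaError(ValueError):
    """Profile has zero total area; auc50 is undefined."""


class NoSignalError(ValueError):
    """All signal falls below the threshold; fractions are undefined."""


class NoPeaksError(ValueError):
    """No peaks detected in the reference channel."""


@dataclass
class AxisProfile:
    """Single-channel intensity samples along the apical-basal axis.

    ``positions`` are strictly increasing with 0 at the apical end;
    ``values`` are non-negative intensities of the same length.
    """

    profile_id: str
    positions: np.ndarray
    values: np.ndarray
    channel: str = "default"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be equal-length 1-d arrays")
        if len(self.positions) >= 2 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SubdomainFractions:
    """Percent of integrated signal per axis subdomain (sums to 100)."""

    pct_apical_cortical: float
    pct_subapical: float
    pct_basal: float


@dataclass
class Auc50Result:
    profile_id: str
    auc50_position: float


def normalize_profile(p: AxisProfile) -> AxisProfile:
    """Min-max normalize values to [0, 1] and map positions onto [0, 1].

    Constant profiles carry no positional information and map to
    all-zero values (logged, rather than dividing by zero).
    Idempotent.
    """
    if len(p) < 3:
        raise ValueError("profile needs at least 3 points")
    pos = (p.positions - p.positions[0]) / (p.positions[-1] - p.positions[0])
    vmin, vmax = p.values.min(), p.values.max()
    if vmax == vmin:
        logger.warning("profile %r is constant; normalized to all zeros", p.profile_id)
        values = np.zeros_like(p.values)
    else:
        values = (p.values - vmin) / (vmax - vmin)
    return replace(p, positions=pos, values=values, normalized=True)


def auc50_position(p: AxisProfile) -> Auc50Result:
    """Axis position at 50% of the cumulative area under the profile.

    Cumulative trapezoidal area from the apical end; the half-area
    crossing is located by linear interpolation within the bracketing
    segment, ties (a plateau exactly at 50%) resolved to the apical-most
    crossing.  The returned position is expressed on the profile's
    [0, 1] axis span.
    """
    if len(p) < 3:
        raise ValueError("profile needs at least 3 points")
    if (p.values < 0).any():
        raise ValueError("profile values must be non-negative")
    cum = cumulative_trapezoid(p.values, p.positions, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise ZeroAreaError(f"profile {p.profile_id!r} has zero total area")
    half = total / 2.0
    i = int(np.searchsorted(cum, half, side="left"))
    if i == 0:
        x = p.positions[0]
    else:
        d = cum[i] - cum[i - 1]
        frac = 0.0 if d == 0 else (half - cum[i - 1]) / d
        x = p.positions[i - 1] + frac * (p.positions[i] - p.positions[i - 1])
    span = p.positions[-1] - p.positions[0]
    return Auc50Result(p.profile_id, float((x - p.positions[0]) / span))


def compare_auc50(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Welch two-sided t-test between two groups of auc50 positions."""
    return two_sample_t(group_a, group_b, pooled=False)


def _region_area(positions: np.ndarray, values: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area of the piecewise-linear profile on [lo, hi]."""
    if hi <= lo:
        return 0.0
    inside = (positions > lo) & (positions < hi)
    xs = np.concatenate(([lo], positions[inside], [hi]))
    ys = np.interp(xs, positions, values)
    return float(np.trapezoid(ys, xs))


def subdomain_fractions(
    p: AxisProfile, apical_boundary: float, threshold: float = 0.0
) -> SubdomainFractions:
    """Percent of integrated signal in the three axis subdomains.

    Values below ``threshold`` are zeroed, then the trapezoidal
    integrated density is split into apical-cortical (apical-most third
    of the apical region), subapical (its remaining two-thirds) and
    basal (beyond ``apical_boundary``), and expressed as percentages of
    the total.

    Raises :class:`NoSignalError` when everything falls below threshold
    (no quantifiable signal, distinct from a zero-area profile).
    """
    if len(p) < 3:
        raise ValueError("profile needs at least 3 points")
    start, end = p.positions[0], p.positions[-1]
    if not (start < apical_boundary < end):
        raise ValueError("apical_boundary must lie strictly inside the position range")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    values = np.where(p.values >= threshold, p.values, 0.0)
    if not values.any():
        raise NoSignalError(
            f"profile {p.profile_id!r}: no signal above threshold {threshold}"
        )
    cortical_end = start + (apical_boundary - start) / 3.0
    a_cort = _region_area(p.positions, values, start, cortical_end)
    a_sub = _region_area(p.positions, values, cortical_end, apical_boundary)
    a_bas = _region_area(p.positions, values, apical_boundary, end)
    total = a_cort + a_sub + a_bas
    if total <= 0:
        raise NoSignalError(
            f"profile {p.profile_id!r}: thresholded signal has zero area"
        )
    return SubdomainFractions(
        pct_apical_cortical=100.0 * a_cort / total,
        pct_subapical=100.0 * a_sub / total,
        pct_basal=100.0 * a_bas / total,
    )


def linescan_profiles(channels: Sequence[AxisProfile]) -> list[AxisProfile]:
    """Normalize each channel of a multi-channel line scan to 0-1.

    All channels must share the same position grid; channel order and
    labels are preserved.
    """
    if not channels:
        return []
    ref = channels[0].positions
    for c in channels[1:]:
        if len(c.positions) != len(ref) or not np.allclose(c.positions, ref):
            raise ValueError(
                f"channel {c.channel!r} is on a different position grid"
            )
    return [normalize_profile(c) for c in channels]


def peak_coincidence(
    a: AxisProfile,
    b: AxisProfile,
    tolerance: float,
    prominence: float = 0.1,
) -> float:
    """Fraction of peaks in ``a`` lying within ``tolerance`` of a ``b`` peak.

    Both profiles must be normalized onto the same grid.  Local maxima
    with prominence above ``prominence`` (default 0.1 of the normalized
    range) count as peaks.  Raises :class:`NoPeaksError` when ``a`` has
    no peaks — distinct from a genuine coincidence of 0.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not (a.normalized and b.normalized):
        raise ValueError("profiles must be normalized (see normalize_profile)")
    if len(a.positions) != len(b.positions) or not np.allclose(a.positions, b.positions):
        raise ValueError("profiles must share the same position grid")
    peaks_a, _ = find_peaks(a.values, prominence=prominence)
    peaks_b, _ = find_peaks(b.values, prominence=prominence)
    if len(peaks_a) == 0:
        raise NoPeaksError(f"no peaks detected in profile {a.profile_id!r}")
    if len(peaks_b) == 0:
        return 0.0
    pos_a = a.positions[peaks_a]
    pos_b = b.positions[peaks_b]
    hits = sum(np.min(np.abs(pos_b - x)) <= tolerance for x in pos_a)
    return float(hits) / len(pos_a)
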