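"""Densitometry-based selection of matched MNase digests.

Matched digests are chosen from a digestion titration run on an agarose
gel: each lane's intensity-versus-migration profile is calibrated
against a size ladder ("relative front"), resampled onto a common
fragment-size grid, checked for completeness (no visible di-nucleosome
band), and compared pairwise by Pearson correlation.  Two lanes are a
match when both are complete and r > 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .digestion import MONO_MAX_BP, MONO_MIN_BP

__all__ = [
    "LaneProfile",
    "LadderCalibration",
    "SizeProfile",
    "MatchReport",
    "calibrate_ladder",
    "lane_to_size_profile",
    "completeness_check",
    "match_score",
    "select_matched",
    "simulate_gel_lane",
]


class CalibrationError(ValueError):
    """Ladder band table unusable for calibration."""


@dataclass
class LaneProfile:
    """One gel lane: intensity sampled along the migration axis."""

    distance: np.ndarray
    intensity: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.distance.ndim != 1 or self.distance.shape != self.intensity.shape:
            raise ValueError("distance and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(self.distance) <= 0):
            raise ValueError("migration distances must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class LadderCalibration:
    """Monotone mapping between fragment size (bp) and migration distance,
    interpolated linearly in log(size)."""

    sizes: np.ndarray
    distances: np.ndarray

    def distance_of(self, size_bp) -> np.ndarray:
        """Migration distance for fragment size(s); log-linear
        interpolation, end segments extended for out-of-range sizes."""
        size_bp = np.asarray(size_bp, dtype=float)
        logs = np.log(self.sizes)
        x = np.log(np.maximum(size_bp, 1e-9))
        return self._interp_extrap(x, logs, self.distances)

    def size_of(self, distance) -> np.ndarray:
        """Inverse mapping: fragment size at a migration distance."""
        d = np.asarray(distance, dtype=float)
        # distances descending in size; flip for interp
        logs = self._interp_extrap(d, self.distances[::-1], np.log(self.sizes)[::-1])
        return np.exp(logs)

    def is_extrapolated(self, size_bp) -> np.ndarray:
        size_bp = np.asarray(size_bp, dtype=float)
        return (size_bp < self.sizes[0]) | (size_bp > self.sizes[-1])

    @staticmethod
    def _interp_extrap(x, xp, fp) -> np.ndarray:
        """np.interp with linear extrapolation from the end segments."""
        if xp[0] > xp[-1]:
            xp, fp = xp[::-1], fp[::-1]
        y = np.interp(x, xp, fp)
        lo = x < xp[0]
        hi = x > xp[-1]
        if np.any(lo):
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
        if np.any(hi):
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
        return y


@dataclass
class SizeProfile:
    """Lane intensity resampled onto a 1-bp fragment-size grid."""

    sizes: np.ndarray
    intensity: np.ndarray
    name: str = ""
    extrapolated: np.ndarray | None = None


@dataclass
class MatchReport:
    """Pairwise lane comparison: correlations, completeness, matches."""

    names: list[str]
    r_matrix: np.ndarray
    complete: np.ndarray
    matched_pairs: list[tuple[int, int]]
    r_threshold: float = 0.9


def calibrate_ladder(bands: dict | Sequence[tuple[float, float]]) -> LadderCalibration:
    """Fit the size<->distance mapping from a ladder band table.

    ``bands`` maps fragment size (bp) to migration distance; at least 3
    bands are required and distance must decrease strictly with size.
    """
    if isinstance(bands, dict):
        items = sorted(bands.items())
    else:
        items = sorted((float(s), float(d)) for s, d in bands)
    if len(items) < 3:
        raise CalibrationError(f"need >= 3 ladder bands, got {len(items)}")
    sizes = np.array([s for s, _ in items], dtype=float)
    dists = np.array([d for _, d in items], dtype=float)
    if np.any(sizes <= 0):
        raise CalibrationError("ladder sizes must be > 0")
    if np.any(np.diff(dists) >= 0):
        raise CalibrationError(
            "ladder distances must decrease strictly with fragment size"
        )
    return LadderCalibration(sizes=sizes, distances=dists)


def lane_to_size_profile(
    lane: LaneProfile,
    cal: LadderCalibration,
    size_range: tuple[int, int] = (0, 400),
    preserve_area: bool = True,
) -> SizeProfile:
    """Resample a lane onto a 1-bp fragment-size grid.

    With ``preserve_area`` (default) intensity is treated as a density
    along the migration axis and converted with the Jacobian
    |d(distance)/d(size)| so band areas survive the change of variable;
    otherwise intensity values are carried over as-is (plain relative-
    front resampling).  Sizes whose calibrated distance falls outside
    the lane's sampled span get zero intensity.
    """
    lo = max(size_range[0], 1)
    hi = size_range[1]
    if hi <= lo:
        raise ValueError(f"empty size range {size_range}")
    sizes = np.arange(lo, hi + 1, dtype=float)
    dist = cal.distance_of(sizes)
    if dist.max() < lane.distance[0] or dist.min() > lane.distance[-1]:
        raise ValueError("lane does not overlap the calibrated migration region")
    inten = np.interp(dist, lane.distance, lane.intensity, left=0.0, right=0.0)
    if preserve_area:
        inten = inten * np.abs(np.gradient(dist))
    return SizeProfile(
        sizes=sizes,
        intensity=inten,
        name=lane.name,
        extrapolated=cal.is_extrapolated(sizes),
    )


def completeness_check(
    profile: SizeProfile,
    di_range: tuple[int, int] = (250, 350),
    max_di_fraction: float = 0.05,
    mono_range: tuple[int, int] = (MONO_MIN_BP, MONO_MAX_BP),
) -> tuple[bool, dict]:
    """A digest is complete when no di-nucleosome band is visible:
    peak intensity in ``di_range`` below ``max_di_fraction`` of the
    mono-band peak."""
    s = profile.sizes
    di_mask = (s >= di_range[0]) & (s <= di_range[1])
    mono_mask = (s >= mono_range[0]) & (s <= mono_range[1])
    if not di_mask.any():
        raise ValueError("size profile does not cover the di-nucleosome range")
    di_peak = float(profile.intensity[di_mask].max())
    mono_peak = float(profile.intensity[mono_mask].max()) if mono_mask.any() else 0.0
    complete = di_peak < max_di_fraction * mono_peak
    return complete, {
        "di_peak": di_peak,
        "mono_peak": mono_peak,
        "di_fraction": di_peak / mono_peak if mono_peak > 0 else np.inf,
    }


def match_score(a: SizeProfile, b: SizeProfile) -> float:
    """Pearson correlation between two size profiles on the same grid.

    Returns NaN when either profile has zero variance.
    """
    if a.sizes.shape != b.sizes.shape or np.any(a.sizes != b.sizes):
        raise ValueError("size profiles are on different grids")
    x, y = a.intensity, b.intensity
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def select_matched(
    profiles: Sequence[SizeProfile],
    r_threshold: float = 0.9,
    di_range: tuple[int, int] = (250, 350),
    max_di_fraction: float = 0.05,
) -> MatchReport:
    """Pairwise matching: a pair is matched iff both lanes pass the
    completeness check and r strictly exceeds ``r_threshold``."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 lanes to match")
    n = len(profiles)
    r = np.eye(n)
    complete = np.zeros(n, dtype=bool)
    for i, p in enumerate(profiles):
        complete[i], _ = completeness_check(
            p, di_range=di_range, max_di_fraction=max_di_fraction
        )
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = match_score(profiles[i], profiles[j])
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if complete[i] and complete[j] and r[i, j] > r_threshold
    ]
    names = [p.name or f"lane{i + 1}" for i, p in enumerate(profiles)]
    return MatchReport(
        names=names,
        r_matrix=r,
        complete=complete,
        matched_pairs=pairs,
        r_threshold=r_threshold,
    )


def simulate_gel_lane(
    fragment_lengths,
    band_sigma: float = 1.5,
    mass_weighted: bool = True,
    rng=None,
    mobility: tuple[float, float] = (160.0, 20.0),
    grid_step: float = 0.25,
    name: str = "",
) -> LaneProfile:
    """Render a fragment-length multiset as a synthetic gel lane.

    Migration follows the log-linear mobility law ``d = a - b*log(size)``;
    each fragment contributes a Gaussian band of width ``band_sigma``
    (distance units), weighted by count x length when ``mass_weighted``
    (intercalating-dye staining).  ``rng`` is accepted for interface
    symmetry; the rendered profile is the noise-free expectation.
    """
    lengths = np.asarray(fragment_lengths, dtype=float)
    lengths = lengths[lengths > 0]
    if lengths.size == 0:
        raise ValueError("empty fragment multiset")
    a, b = mobility
    uniq, counts = np.unique(lengths, return_counts=True)
    centers = a - b * np.log(uniq)
    weights = counts * uniq if mass_weighted else counts.astype(float)
    d_lo = max(0.0, centers.min() - 5 * band_sigma)
    d_hi = centers.max() + 5 * band_sigma
    grid = np.arange(d_lo, d_hi + grid_step, grid_step)
    # sum of Gaussian bands; normalized so integrated intensity = weight
    diff = (grid[None, :] - centers[:, None]) / band_sigma
    dens = np.exp(-0.5 * diff**2) / (band_sigma * np.sqrt(2 * np.pi))
    intensity = weights @ dens
    return LaneProfile(distance=grid, intensity=intensity, name=name)
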