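"""Genome-wide comparison of MNase-seq coverage tracks.

Two experiments are compared as binned coverage tracks: counts are
standardized to a common total (the analogue of equalizing read
numbers), Pearson correlations are computed in 1-kb windows tiling or
sliding across the genome, and stretches where the tracks decorrelate
(r < 0.5 over >= 1 kb) are reported as dissimilar chromatin regions.
Average dyad-aligned profiles stratified by flanking-linker class
(normal 10-20 bp vs long 21-221 bp) expose the digestion-dependent
sampling bias on real or simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSizes

NORMAL_LINKER = (10, 20)
LONG_LINKER = (21, 221)

__all__ = [
    "CoverageTrack",
    "WindowCorrelationSet",
    "DissimilarRegionSet",
    "NucleosomeReference",
    "coverage_from_fragments",
    "standardize_track",
    "window_correlations",
    "correlation_histogram",
    "genome_correlation",
    "dissimilar_regions",
    "linker_class_profiles",
]


@dataclass
class CoverageTrack:
    """Binned numeric signal over a genome, one array per sequence."""

    genome: GenomeSizes
    bin_bp: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, length in self.genome:
            n_bins = -(-length // self.bin_bp)
            arr = np.asarray(self.data.get(name), dtype=float)
            if arr.shape != (n_bins,):
                raise ValueError(
                    f"{name}: expected {n_bins} bins of {self.bin_bp} bp, "
                    f"got shape {arr.shape}"
                )
            self.data[name] = arr

    @property
    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def concat(self) -> np.ndarray:
        return np.concatenate([self.data[n] for n in self.genome.names])

    def rebin(self, new_bin_bp: int) -> "CoverageTrack":
        """Aggregate to a coarser bin width (mean of constituent bins)."""
        if new_bin_bp % self.bin_bp:
            raise ValueError("new bin width must be a multiple of the current one")
        k = new_bin_bp // self.bin_bp
        out = {}
        for name, length in self.genome:
            a = self.data[name]
            n_new = -(-len(a) // k)
            pad = np.full(n_new * k - len(a), np.nan)
            padded = np.concatenate([a, pad]).reshape(n_new, k)
            out[name] = np.nanmean(padded, axis=1)
        return CoverageTrack(genome=self.genome, bin_bp=new_bin_bp, data=out)


@dataclass
class WindowCorrelationSet:
    """Per-window Pearson correlations between two tracks."""

    windows: pd.DataFrame  # chrom, start, end, r (NaN = undefined)
    window_bp: int
    step_bp: int

    @property
    def r(self) -> np.ndarray:
        return self.windows["r"].to_numpy()

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.r)


@dataclass
class DissimilarRegionSet:
    """Merged regions where two tracks decorrelate."""

    regions: pd.DataFrame  # chrom, start, end, min_r, length
    r_cutoff: float
    min_span_bp: int
    window_bp: int
    step_bp: int

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def mean_size_bp(self) -> float:
        if len(self.regions) == 0:
            return 0.0
        return float(self.regions["length"].mean())

    @property
    def total_bp(self) -> int:
        return int(self.regions["length"].sum())


@dataclass
class NucleosomeReference:
    """Reference nucleosome positions with flanking-linker annotation.

    Linker sizes are the gaps to the nearest neighbouring nucleosome on
    each side; nucleosomes at a sequence boundary get NaN on the outer
    side.  Each side is classified as normal, long or other.
    """

    positions: pd.DataFrame  # chrom, start, end (sorted per chrom)
    normal: tuple[int, int] = NORMAL_LINKER
    long: tuple[int, int] = LONG_LINKER
    annotated: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = (
            self.positions.sort_values(["chrom", "start"])
            .reset_index(drop=True)
            .copy()
        )
        left = df["start"] - df.groupby("chrom")["end"].shift(1)
        right = df.groupby("chrom")["start"].shift(-1) - df["end"]
        df["left_linker"] = left
        df["right_linker"] = right
        df["left_class"] = left.map(self._classify)
        df["right_class"] = right.map(self._classify)
        df["dyad"] = (df["start"] + df["end"] - 1) // 2
        self.annotated = df

    def _classify(self, size: float) -> str:
        if pd.isna(size) or size < 0:
            return "other"
        if self.normal[0] <= size <= self.normal[1]:
            return "normal"
        if self.long[0] <= size <= self.long[1]:
            return "long"
        return "other"

    def both_class(self, cls: str) -> pd.DataFrame:
        df = self.annotated
        return df[(df["left_class"] == cls) & (df["right_class"] == cls)]


def coverage_from_fragments(
    records: Iterable[tuple],
    genome: GenomeSizes,
    bin_bp: int = 10,
    extend_to: int | None = None,
) -> CoverageTrack:
    """Per-bin mean per-base coverage from fragment intervals.

    ``records`` are (chrom, start, end[, ...]) with 0-based half-open
    coordinates.  Single-end reads may be extended 3'-ward to a fixed
    fragment length with ``extend_to``; fragment/paired-end records are
    used as-is.
    """
    deltas = {name: np.zeros(length + 1) for name, length in genome}
    unknown = set()
    for rec in records:
        chrom, start, end = rec[0], int(rec[1]), int(rec[2])
        if chrom not in deltas:
            unknown.add(chrom)
            continue
        if extend_to is not None:
            end = start + extend_to
        length = genome[chrom]
        start = max(0, min(start, length))
        end = max(0, min(end, length))
        if end > start:
            deltas[chrom][start] += 1
            deltas[chrom][end] -= 1
    if unknown:
        raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")
    data = {}
    for name, length in genome:
        perbase = np.cumsum(deltas[name][:-1])
        data[name] = _bin_mean(perbase, bin_bp)
    return CoverageTrack(genome=genome, bin_bp=bin_bp, data=data)


def _bin_mean(perbase: np.ndarray, bin_bp: int) -> np.ndarray:
    n_bins = -(-len(perbase) // bin_bp)
    pad = np.full(n_bins * bin_bp - len(perbase), np.nan)
    padded = np.concatenate([perbase, pad]).reshape(n_bins, bin_bp)
    return np.nanmean(padded, axis=1)


def standardize_track(track: CoverageTrack, target_total: float = 1_000_000.0) -> CoverageTrack:
    """Scale so the genome-wide bin total equals ``target_total``."""
    total = track.total
    if total <= 0:
        raise ValueError("cannot standardize a zero-total track")
    f = target_total / total
    return CoverageTrack(
        genome=track.genome,
        bin_bp=track.bin_bp,
        data={k: v * f for k, v in track.data.items()},
    )


def _check_compatible(a: CoverageTrack, b: CoverageTrack) -> None:
    if a.genome.items != b.genome.items:
        raise ValueError("tracks are on different genomes")
    if a.bin_bp != b.bin_bp:
        raise ValueError("tracks have different bin widths")


def _sliding_r(x: np.ndarray, y: np.ndarray, w: int, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r for windows of ``w`` bins every ``s`` bins.

    Cumulative-sum formulation on globally centred values; windows with
    (near-)zero variance in either track come back NaN.
    """
    n = len(x)
    if n < w:
        return np.array([], dtype=int), np.array([])
    xc = x - x.mean()
    yc = y - y.mean()
    starts = np.arange(0, n - w + 1, s)

    def wsum(v):
        c = np.concatenate([[0.0], np.cumsum(v)])
        return c[starts + w] - c[starts]

    sx, sy = wsum(xc), wsum(yc)
    sxx, syy, sxy = wsum(xc * xc), wsum(yc * yc), wsum(xc * yc)
    vx = sxx - sx * sx / w
    vy = syy - sy * sy / w
    cov = sxy - sx * sy / w
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    bad = (vx <= 1e-12 * np.maximum(sxx, 1e-300)) | (
        vy <= 1e-12 * np.maximum(syy, 1e-300)
    )
    r[bad] = np.nan
    return starts, np.clip(r, -1.0, 1.0, out=r)


def window_correlations(
    a: CoverageTrack,
    b: CoverageTrack,
    window_bp: int = 1000,
    step_bp: int | None = None,
) -> WindowCorrelationSet:
    """Pearson r between two tracks for windows across the genome.

    ``step_bp`` defaults to ``window_bp`` (non-overlapping tiling); both
    must be multiples of the bin width.
    """
    _check_compatible(a, b)
    bin_bp = a.bin_bp
    step_bp = window_bp if step_bp is None else step_bp
    if window_bp % bin_bp or step_bp % bin_bp:
        raise ValueError("window and step must be multiples of the bin width")
    w, s = window_bp // bin_bp, step_bp // bin_bp
    rows = []
    for name, length in a.genome:
        starts, r = _sliding_r(a.data[name], b.data[name], w, s)
        for i, rv in zip(starts, r):
            rows.append((name, int(i) * bin_bp, int(i) * bin_bp + window_bp, rv))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "r"])
    return WindowCorrelationSet(windows=df, window_bp=window_bp, step_bp=step_bp)


def correlation_histogram(
    wcs: WindowCorrelationSet, bin_edges: np.ndarray | None = None
) -> dict:
    """Histogram of window correlations plus the summary fractions used
    to compare preparations (fraction of windows with r > 0.9 and with
    r < 0.5).  Undefined (zero-variance) windows are excluded."""
    if bin_edges is None:
        bin_edges = np.linspace(-1.0, 1.0, 41)
    r = wcs.r[wcs.defined]
    counts, edges = np.histogram(r, bins=bin_edges)
    n = len(r)
    return {
        "counts": counts,
        "bin_edges": edges,
        "n_defined": n,
        "n_undefined": int((~wcs.defined).sum()),
        "fraction_gt_0.9": float((r > 0.9).sum() / n) if n else np.nan,
        "fraction_lt_0.5": float((r < 0.5).sum() / n) if n else np.nan,
    }


def genome_correlation(
    a: CoverageTrack, b: CoverageTrack, resolution_bp: int = 100
) -> float:
    """Single genome-to-genome Pearson r at the given resolution."""
    _check_compatible(a, b)
    if resolution_bp != a.bin_bp:
        a = a.rebin(resolution_bp)
        b = b.rebin(resolution_bp)
    x, y = a.concat(), b.concat()
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def dissimilar_regions(
    a: CoverageTrack,
    b: CoverageTrack,
    r_cutoff: float = 0.5,
    min_span_bp: int = 1000,
    window_bp: int = 1000,
    step_bp: int = 10,
) -> DissimilarRegionSet:
    """Detect regions where the tracks decorrelate.

    A window slides at ``step_bp``; windows with defined r below
    ``r_cutoff`` are marked, overlapping/abutting marked windows are
    merged, and merged regions spanning at least ``min_span_bp`` are
    returned.  Zero-variance windows are never marked.
    """
    wcs = window_correlations(a, b, window_bp=window_bp, step_bp=step_bp)
    df = wcs.windows
    marked = df[(~df["r"].isna()) & (df["r"] < r_cutoff)]
    rows = []
    for chrom, grp in marked.groupby("chrom", sort=False):
        cur_start = cur_end = None
        cur_min = np.inf
        for start, end, r in zip(grp["start"], grp["end"], grp["r"]):
            if cur_start is None:
                cur_start, cur_end, cur_min = start, end, r
            elif start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, end)
                cur_min = min(cur_min, r)
            else:
                rows.append((chrom, cur_start, cur_end, cur_min))
                cur_start, cur_end, cur_min = start, end, r
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end, cur_min))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "min_r"])
    out["length"] = out["end"] - out["start"]
    out = out[out["length"] >= min_span_bp].reset_index(drop=True)
    return DissimilarRegionSet(
        regions=out,
        r_cutoff=r_cutoff,
        min_span_bp=min_span_bp,
        window_bp=window_bp,
        step_bp=step_bp,
    )


def linker_class_profiles(
    track: CoverageTrack,
    ref: NucleosomeReference,
    flank_bp: int = 200,
) -> dict:
    """Average dyad-aligned signal for nucleosomes whose two flanking
    linkers are both normal (10-20 bp) or both long (21-221 bp).

    Returns per-class mean profiles over ``+-flank_bp`` around the dyad
    at the track's bin resolution, with the nucleosome counts entering
    each average.
    """
    bin_bp = track.bin_bp
    half = flank_bp // bin_bp
    offsets = (np.arange(-half, half + 1)) * bin_bp
    out: dict = {"offsets_bp": offsets, "counts": {}}
    for cls in ("normal", "long"):
        rows = []
        for _, nuc in ref.both_class(cls).iterrows():
            chrom = nuc["chrom"]
            if chrom not in track.data:
                continue
            arr = track.data[chrom]
            c = int(nuc["dyad"]) // bin_bp
            if c - half < 0 or c + half >= len(arr):
                continue
            rows.append(arr[c - half : c + half + 1])
        out["counts"][cls] = len(rows)
        out[cls] = np.mean(rows, axis=0) if rows else np.full(2 * half + 1, np.nan)
    return out
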