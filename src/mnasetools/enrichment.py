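"""Binding enrichment at dissimilar chromatin regions.

Probe-level ChIP log2 ratios are smoothed into a continuous binding
profile with a sliding-window average, per-region mean binding is
computed for the dissimilar regions under test, and the same statistic
over a large set of random regions (matched in size) forms the null.
Significance of the enrichment is assessed with a one-tailed Welch
(heteroscedastic) t-test for observed > null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSizes

__all__ = [
    "BindingProfile",
    "EnrichmentResult",
    "continuous_binding_profile",
    "region_mean_binding",
    "random_regions",
    "enrichment_test",
    "enrichment_analysis",
]


@dataclass
class BindingProfile:
    """Continuous log2-ratio binding signal at step-resolution bins.

    Bin ``k`` of a sequence holds the mean log2 ratio of probes whose
    midpoints fall inside the window ``[k*step, k*step + window)``; bins
    whose window contains no probe are NaN (no data).
    """

    genome: GenomeSizes
    window_bp: int
    step_bp: int
    data: dict[str, np.ndarray]


@dataclass
class EnrichmentResult:
    """Welch-test comparison of per-region binding vs a random null."""

    t: float
    p: float
    n_observed: int
    n_null: int
    observed_mean: float
    null_mean: float
    n_excluded: int = 0
    degenerate: bool = False


def continuous_binding_profile(
    probes: pd.DataFrame | Iterable[tuple],
    genome: GenomeSizes,
    window_bp: int = 500,
    step_bp: int = 250,
) -> BindingProfile:
    """Sliding-window average of probe log2 ratios.

    ``probes``: (chrom, start, end, log2ratio) records.  Windows of
    ``window_bp`` advance by ``step_bp``; each window's value is the
    mean ratio of probes whose midpoints fall inside it.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    if not isinstance(probes, pd.DataFrame):
        probes = pd.DataFrame(
            list(probes), columns=["chrom", "start", "end", "log2ratio"]
        )
    data = {}
    for name, length in genome:
        n_bins = -(-length // step_bp)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        sub = probes[probes["chrom"] == name]
        if len(sub):
            mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(int)
            vals = sub["log2ratio"].to_numpy(dtype=float)
            # probe midpoint at m contributes to every window whose span
            # [k*step, k*step+window) contains m
            k_hi = mids // step_bp  # last window index starting at/before m
            k_lo = np.maximum(0, (mids - window_bp) // step_bp + 1)
            for lo, hi, v in zip(k_lo, np.minimum(k_hi, n_bins - 1), vals):
                sums[lo : hi + 1] += v
                counts[lo : hi + 1] += 1
        with np.errstate(invalid="ignore"):
            prof = sums / counts
        prof[counts == 0] = np.nan
        data[name] = prof
    return BindingProfile(genome=genome, window_bp=window_bp, step_bp=step_bp, data=data)


def region_mean_binding(
    profile: BindingProfile, regions: pd.DataFrame | Sequence[tuple]
) -> tuple[np.ndarray, int]:
    """Mean of non-missing profile bins overlapping each region.

    Regions with no binding data are excluded; returns the per-region
    means (for the regions retained, in order) and the excluded count.
    """
    if not isinstance(regions, pd.DataFrame):
        regions = pd.DataFrame(list(regions), columns=["chrom", "start", "end"])
    step = profile.step_bp
    means = []
    excluded = 0
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        arr = profile.data.get(chrom)
        if arr is None:
            excluded += 1
            continue
        lo = int(start) // step
        hi = -(-int(end) // step)
        vals = arr[lo:hi]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            excluded += 1
            continue
        means.append(vals.mean())
    return np.asarray(means), excluded


def random_regions(
    genome: GenomeSizes, count: int = 10000, size_bp: int = 1000, rng=None
) -> pd.DataFrame:
    """Uniformly placed fixed-size regions.

    Chromosomes are weighted by placeable length (length - size + 1) so
    every valid placement genome-wide is equally likely.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    names, weights = [], []
    for name, length in genome:
        w = length - size_bp + 1
        if w > 0:
            names.append(name)
            weights.append(w)
    if not names:
        raise ValueError(f"region size {size_bp} exceeds every chromosome")
    weights = np.asarray(weights, dtype=float)
    probs = weights / weights.sum()
    chrom_idx = gen.choice(len(names), size=count, p=probs)
    starts = np.empty(count, dtype=int)
    for i, n in enumerate(names):
        mask = chrom_idx == i
        starts[mask] = gen.integers(0, int(weights[i]), size=int(mask.sum()))
    return pd.DataFrame(
        {
            "chrom": [names[i] for i in chrom_idx],
            "start": starts,
            "end": starts + size_bp,
        }
    )


def enrichment_test(observed_means, null_means) -> EnrichmentResult:
    """One-tailed Welch t-test for observed mean binding > null."""
    obs = np.asarray(observed_means, dtype=float)
    null = np.asarray(null_means, dtype=float)
    if len(obs) < 2 or len(null) < 2:
        raise ValueError("need >= 2 values per group")
    degenerate = obs.std(ddof=1) == 0 and null.std(ddof=1) == 0
    if degenerate:
        t, p = np.nan, np.nan
    else:
        t, p = stats.ttest_ind(obs, null, equal_var=False, alternative="greater")
    return EnrichmentResult(
        t=float(t),
        p=float(p),
        n_observed=len(obs),
        n_null=len(null),
        observed_mean=float(obs.mean()),
        null_mean=float(null.mean()),
        degenerate=degenerate,
    )


def enrichment_analysis(
    probes,
    regions,
    genome: GenomeSizes,
    n_random: int = 10000,
    random_size_bp: int | None = None,
    window_bp: int = 500,
    step_bp: int = 250,
    rng=None,
) -> EnrichmentResult:
    """Full pipeline: binding profile, per-region means, size-matched
    random null, Welch test.  ``random_size_bp`` defaults to the mean
    size of the regions under test."""
    if not isinstance(regions, pd.DataFrame):
        regions = pd.DataFrame(list(regions), columns=["chrom", "start", "end"])
    profile = continuous_binding_profile(
        probes, genome, window_bp=window_bp, step_bp=step_bp
    )
    obs, excl = region_mean_binding(profile, regions)
    if random_size_bp is None:
        sizes = regions["end"] - regions["start"]
        random_size_bp = int(round(sizes.mean())) if len(sizes) else 1000
    null_regions = random_regions(
        genome, count=n_random, size_bp=random_size_bp, rng=rng
    )
    null, _ = region_mean_binding(profile, null_regions)
    result = enrichment_test(obs, null)
    result.n_excluded = excl
    return result
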