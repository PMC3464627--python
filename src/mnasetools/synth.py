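"""Synthetic data generators.

These emulate the statistical structure that replicate MNase-seq
comparisons assume: a shared underlying nucleosome occupancy signal
(peaks every ~165 bp, the yeast nucleosome repeat), independent
per-track counting (Poisson) noise at a chosen read depth, and
optionally planted "dissimilar" regions where one track's underlying
signal is replaced, so detection can be scored against known truth.

``digestion_track_pair`` goes one step further and derives the
underlying signal from the digestion simulator itself, so that
matched-versus-unmatched comparisons inherit the neighborhood bias of
partial MNase digestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
import pandas as pd

from .digestion import simulate_population, tabulate_signal
from .genome import GenomeSizes
from .templates import ChromatinTemplate, packed_template
from .tracks import CoverageTrack

DEFAULT_GENOME = GenomeSizes([("chrI", 500_000), ("chrII", 500_000)])

__all__ = [
    "DEFAULT_GENOME",
    "SyntheticTrackSpec",
    "synth_track_pair",
    "synth_binding",
    "digestion_track_pair",
]


@dataclass
class SyntheticTrackSpec:
    """Parameters of a synthetic replicate-pair experiment.

    depth is the mean count per bin before standardization; peaks are
    Gaussians of width ``peak_sigma`` at ~``peak_spacing`` intervals
    with lognormal height variation.  ``plants`` are intervals where
    track b's underlying signal is replaced by an independent draw.
    """

    genome: GenomeSizes = dataclass_field(default_factory=lambda: DEFAULT_GENOME)
    bin_bp: int = 10
    peak_spacing: float = 165.0
    spacing_jitter: float = 10.0
    peak_sigma: float = 40.0
    height_cv: float = 0.5
    baseline: float = 0.10
    depth: float = 50.0
    poisson_noise: bool = True
    plants: Sequence[tuple[str, int, int]] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        for chrom, start, end in self.plants:
            if chrom not in self.genome or not (0 <= start < end <= self.genome[chrom]):
                raise ValueError(f"plant {(chrom, start, end)} outside genome")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


def _peak_signal(length: int, bin_bp: int, spec: SyntheticTrackSpec, rng) -> np.ndarray:
    """Underlying occupancy: jittered Gaussian peak train, per bin."""
    n_bins = -(-length // bin_bp)
    sig = np.full(n_bins, spec.baseline)
    x = (np.arange(n_bins) + 0.5) * bin_bp
    pos = rng.uniform(0, spec.peak_spacing)
    sigma_ln = np.sqrt(np.log(1 + spec.height_cv**2))
    while pos < length:
        h = rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)
        lo = np.searchsorted(x, pos - 4 * spec.peak_sigma)
        hi = np.searchsorted(x, pos + 4 * spec.peak_sigma)
        sig[lo:hi] += h * np.exp(-0.5 * ((x[lo:hi] - pos) / spec.peak_sigma) ** 2)
        pos += max(rng.normal(spec.peak_spacing, spec.spacing_jitter), 50.0)
    return sig


def synth_track_pair(
    spec: SyntheticTrackSpec,
) -> tuple[CoverageTrack, CoverageTrack, pd.DataFrame]:
    """Matched synthetic replicate pair plus planted-region truth.

    Both tracks share one underlying signal and get independent Poisson
    counting noise; inside each planted interval, track b's underlying
    signal is an independent draw (a genuine structural difference).
    Deterministic for a given spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    base = {name: _peak_signal(length, spec.bin_bp, spec, rng) for name, length in spec.genome}
    alt = {name: _peak_signal(length, spec.bin_bp, spec, rng) for name, length in spec.genome}
    b_signal = {name: arr.copy() for name, arr in base.items()}
    for chrom, start, end in spec.plants:
        lo, hi = start // spec.bin_bp, -(-end // spec.bin_bp)
        b_signal[chrom][lo:hi] = alt[chrom][lo:hi]
    mean_sig = np.mean([arr.mean() for arr in base.values()])
    data_a, data_b = {}, {}
    for name, _ in spec.genome:
        lam_a = spec.depth * base[name] / mean_sig
        lam_b = spec.depth * b_signal[name] / mean_sig
        if spec.poisson_noise:
            data_a[name] = rng.poisson(lam_a).astype(float)
            data_b[name] = rng.poisson(lam_b).astype(float)
        else:
            data_a[name] = lam_a
            data_b[name] = lam_b
    a = CoverageTrack(genome=spec.genome, bin_bp=spec.bin_bp, data=data_a)
    b = CoverageTrack(genome=spec.genome, bin_bp=spec.bin_bp, data=data_b)
    truth = pd.DataFrame(list(spec.plants), columns=["chrom", "start", "end"])
    return a, b, truth


def synth_binding(
    genome: GenomeSizes,
    regions: pd.DataFrame | Sequence[tuple],
    background_mean: float = 0.0,
    effect: float = 0.0,
    probe_spacing: int = 50,
    probe_length: int = 50,
    noise_sd: float = 0.5,
    seed=None,
) -> pd.DataFrame:
    """Probe-level log2-ratio records tiled across the genome.

    Probe midpoints sit every ``probe_spacing`` bp; the log2 ratio is
    ``background + effect`` for probes whose midpoint falls inside any
    of ``regions`` plus Gaussian noise.  Deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not isinstance(regions, pd.DataFrame):
        regions = pd.DataFrame(list(regions), columns=["chrom", "start", "end"])
    rows = []
    for name, length in genome:
        mids = np.arange(0, length + 1, probe_spacing)
        inside = np.zeros(len(mids), dtype=bool)
        sub = regions[regions["chrom"] == name]
        for start, end in zip(sub["start"], sub["end"]):
            inside |= (mids >= start) & (mids < end)
        vals = background_mean + effect * inside + rng.normal(0, noise_sd, len(mids))
        starts = np.maximum(mids - probe_length // 2, 0)
        ends = np.minimum(starts + probe_length, length)
        for s, e, v in zip(starts, ends, vals):
            rows.append((name, int(s), int(e), float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2ratio"])


def _layout_profiles(
    layouts: list[ChromatinTemplate],
    n_cuts: int,
    n_templates: int,
    bin_bp: int,
    rng,
    baseline_frac: float = 0.05,
) -> list[np.ndarray]:
    """Binned mono-fragment coverage per layout at one digestion extent."""
    profiles = []
    for tpl in layouts:
        res = simulate_population(tpl, n_cuts=n_cuts, n_templates=n_templates, rng=rng)
        counts = tabulate_signal(res.selected, tpl).counts
        n_bins = tpl.length // bin_bp
        binned = counts[: n_bins * bin_bp].reshape(n_bins, bin_bp).mean(axis=1)
        mean = binned.mean()
        if mean == 0:
            binned = np.ones(n_bins)
            mean = 1.0
        profiles.append(binned + baseline_frac * mean)
    return profiles


def digestion_track_pair(
    n_cuts_a: int,
    n_cuts_b: int,
    genome_bp: int = 1_000_000,
    template_bp: int = 4000,
    n_layouts: int = 6,
    n_plant_slots: int = 12,
    n_templates: int = 2000,
    bin_bp: int = 10,
    depth: float = 400.0,
    seed=None,
) -> tuple[CoverageTrack, CoverageTrack, pd.DataFrame, dict]:
    """Wild-type vs mutant track pair whose underlying signal comes from
    the digestion simulator.

    The genome is tiled with 4-kb chromatin layouts (nucleosome arrays
    with occasional long linkers, at layout-specific phases).  Track a
    is a "wild-type" digested with ``n_cuts_a`` per template; track b is
    a "mutant" digested with ``n_cuts_b`` whose nucleosomes are
    repositioned by half a repeat inside ``n_plant_slots`` randomly
    chosen slots (the planted biological difference).  Comparing tracks
    generated at equal vs unequal cut numbers reproduces the
    matched-versus-unmatched contrast: unequal extents add
    neighborhood-bias differences on top of the planted ones.

    Returns (track_a, track_b, truth regions, info) where info carries
    the percent_monos reached at each extent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_slots = genome_bp // template_bp
    genome = GenomeSizes([("chrI", n_slots * template_bp)])

    offsets = [int(round(i * 161.5 / n_layouts + 5)) for i in range(n_layouts)]
    layouts, shifted = [], []
    for i in range(n_layouts):
        n_gaps = template_bp // 162
        n_long = 1 + int(rng.integers(0, 3))
        gap_idx = rng.choice(n_gaps - 2, size=n_long, replace=False) + 1
        special = {int(g): int(rng.integers(80, 250)) for g in gap_idx}
        layouts.append(
            packed_template(template_bp, 15, special_linkers=special, offset=offsets[i])
        )
        # mutant version: same linker pattern, repositioned by half a repeat
        shifted.append(
            packed_template(
                template_bp, 15, special_linkers=special, offset=offsets[i] + 81
            )
        )

    prof = {}
    pm = {}
    for key, n_cuts in (("a", n_cuts_a), ("b", n_cuts_b)):
        prof[(key, "wt")] = _layout_profiles(layouts, n_cuts, n_templates, bin_bp, rng)
        prof[(key, "mut")] = _layout_profiles(shifted, n_cuts, n_templates, bin_bp, rng)
        res = simulate_population(
            layouts[0], n_cuts=n_cuts, n_templates=n_templates, rng=rng
        )
        pm[key] = res.percent_monos

    slot_layout = rng.integers(0, n_layouts, size=n_slots)
    plant_slots = set(rng.choice(n_slots, size=n_plant_slots, replace=False).tolist())

    def build(key: str, mutant: bool) -> CoverageTrack:
        parts = []
        for s in range(n_slots):
            which = "mut" if (mutant and s in plant_slots) else "wt"
            parts.append(prof[(key, which)][slot_layout[s]])
        lam = np.concatenate(parts)
        lam = depth * lam / lam.mean()
        counts = rng.poisson(lam).astype(float)
        return CoverageTrack(genome=genome, bin_bp=bin_bp, data={"chrI": counts})

    track_a = build("a", mutant=False)
    track_b = build("b", mutant=True)
    truth = pd.DataFrame(
        [("chrI", s * template_bp, (s + 1) * template_bp) for s in sorted(plant_slots)],
        columns=["chrom", "start", "end"],
    )
    info = {"percent_monos_a": pm["a"], "percent_monos_b": pm["b"], "genome": genome}
    return track_a, track_b, truth, info
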