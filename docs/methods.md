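# Methods

## Digestion model

A chromatin template is a linear DNA molecule of length *L* (default
4 kb) carrying non-overlapping 147-bp nucleosomes at 100% occupancy;
all other bases are linker/naked DNA. The per-base MNase cut
probability is 1 on linker DNA and `1/protection(x)` inside a
nucleosome, where protection rises from `min_protection` (default 50)
at the nucleosome edge to `max_protection` (default 1000) at the dyad
(base 73 of 147) and is mirrored about the dyad. Two interpolation
shapes are provided — `linear` (default) and `cosine` (a smooth ramp,
flat near edge and dyad). The published range fixes only the 50×–1000×
endpoints and the positional dependence, not the curve between them;
the linear ramp is the minimal choice and the cosine alternative
brackets plausible smoother curves.

Digestion of one template throws *n* candidate cuts: each candidate
picks a between-base site uniformly in `[1, L-1]` and is realized with
the cut probability of the base to its right (`attempted` model,
default). Realized sites are deduplicated; fragments are the intervals
between consecutive cuts, with template ends closing the first and last
fragment, so fragment lengths always sum to *L*. Whether "*n* cuts"
counts attempts or placements is not observable from a gel, so a
`realized` alternative draws all *n* cut sites directly from the
normalized cut-probability distribution; both are exposed through
`cut_count_mode`. A population (default 10,000 templates, the scale at
which Monte-Carlo error on %Monos is ≲0.5 percentage points) is
digested independently and the fragments pooled.

Equal digestion kinetics are assumed for all nucleosomal DNA:
no sequence preference (AT bias), no exonucleolytic trimming, no
sub-100% occupancy, and no time-course — the cut number *n* is the
only dial for digestion extent.

Size selection keeps fragments with `115 ≤ length ≤ 195` bp
(inclusive on both ends). The extent of digestion is
`%Monos = #mono fragments / #fragments with length ≥ 115 bp`; the
denominator bound is inclusive by default for consistency with the
numerator window (`strict_denominator=True` switches to > 115).
%Monos is 0, with a warning, when nothing reaches the denominator.

Selected fragments are tabulated as +1 coverage over every base they
span (full-fragment tabulation, the equivalent of a paired-end run; no
tag extension). Counts are standardized to a nominal 10⁶ selected
fragments — any fixed constant works since only ratios matter — and
divided by the mean over the normalization region (default
bases 2500–3500, naked DNA in the standard template so it is identical
across runs). Titration sweeps report only a central 1-kb window to
avoid template-edge effects.

The six-nucleosome demonstration template places the array so the
midpoint of the 142-bp central linker falls at coordinate 2000;
internal linkers are 15, 15, 142, 15, 15 bp with 30 bp of linker
immediately upstream of nucleosome 1, and the remaining template is
naked DNA with cut probability 1. The exact placement within the 4-kb
molecule is a convention; centering keeps the reporting window
(1500–2500) and the normalization region fixed relative to the array.

With ~72% of this template naked, the attempted-cut model reaches
%Monos ≈ 0.54 at n = 50 and requires n ≈ 1000 for near-complete
digestion (%Monos ≈ 0.99); analyses that probe the approach to
completeness therefore extend n beyond the 2–50 titration that maps
the partial-digestion regime.

## Gel densitometry and matched digests

Lane profiles are tabular (migration distance, intensity) exports.
A ladder band table (≥ 3 bands, distance strictly decreasing in size)
is interpolated linearly in log(size) to map size↔distance, with
end-segment extrapolation flagged. Lanes are resampled onto a 1-bp
fragment-size grid over 0–400 bp; by default intensity is treated as a
density along the migration axis and multiplied by |d(distance)/d(size)|
so band areas survive the change of variable (`preserve_area=False`
gives plain relative-front resampling). A digest is *complete* when
the peak intensity in the di-nucleosome range (250–350 bp) is below 5%
of the mono-range peak (115–195 bp) — an operational stand-in for "no
visible di-nucleosome band"; both the window and the threshold are
configurable. A pair of lanes is *matched* when both are complete and
their size profiles correlate at strictly r > 0.9.

The lane simulator used in tests and fixtures renders a fragment
multiset with log-linear mobility `d = a − b·ln(size)` and Gaussian
band spreading; intensity is mass-weighted (count × length), the
behavior of intercalating dyes. It exists to bridge the digestion
simulator to the matcher; it is not a gel-image quantifier.

## Track comparison

Coverage tracks are per-sequence arrays at a fixed bin width (default
10 bp); fragment intervals are averaged into bins per-base, and
bedGraph/wiggle input is binned by length-weighted averaging.
Standardization rescales a track to a fixed genome-wide total
(default 10⁶), the analogue of equalizing read counts.

Window Pearson correlations use a cumulative-sum formulation on
globally centred values (numerically equal to the naive per-window
formula to ≲1e-12); windows with near-zero variance in either track
are flagged NaN, excluded from histograms, and never called
dissimilar. "10-bp resolution" is interpreted as: signal binned at
10 bp; histogram windows tile non-overlapping at 1 kb; dissimilar-
region detection slides the 1-kb window at 10-bp steps. Marked windows
(r < 0.5) merge when they overlap or abut, region bounds are the union
of merged windows, and merged regions ≥ 1 kb are reported. The union
rule overhangs a true decorrelated interval by up to one window per
edge — a known, bounded over-call.

Genome-to-genome correlation is a single Pearson r over 100-bp bins.
Linker-class profiles classify each reference nucleosome's two
flanking gaps as normal (10–20 bp), long (21–221 bp) or other, keep
nucleosomes whose two linkers share a class, and average dyad-aligned
signal over ±flank; nucleosomes at sequence boundaries get an "other"
outer side and never enter either class.

## Binding enrichment

Probe-level log2 ratios are smoothed by a sliding-window average
(window 500 bp, step 250 bp — conventional values for this style of
ChIP smoothing, configurable): bin *k* at step resolution holds the
mean ratio of probes whose midpoints fall in `[k·step, k·step+window)`,
NaN where no probe falls. Per-region binding is the mean of non-NaN
bins overlapping the region; regions with no data are excluded and
counted. The null is 10,000 random regions of the dissimilar-region
mean size, placed uniformly with chromosomes weighted by placeable
length. Significance is a one-tailed Welch t-test (unequal variances,
observed > null), delegated to `scipy.stats.ttest_ind`; when both
groups are degenerate the result is flagged rather than computed.

## Synthetic data: what it emulates and what it does not

`synth_track_pair` emulates the statistical structure replicate
comparisons assume: a shared underlying occupancy signal (Gaussian
peaks every ~165 bp — the yeast nucleosome repeat — with jittered
spacing, lognormal heights with CV 0.5, σ = 40 bp, baseline 0.1) and
independent per-bin Poisson counts at `depth` (default 50 per 10-bp
bin). Planted regions replace track b's underlying signal with an
independent draw — a genuine structural difference. The default genome
is 2 × 500 kb: ≥ 900 non-overlapping 1-kb windows but seconds-scale
tests.

`digestion_track_pair` instead derives the underlying signal from the
digestion simulator: the genome is tiled with 4-kb nucleosome-array
layouts (15-bp linkers, 1–3 long linkers of 80–250 bp at random gaps,
layout-specific phases), each layout's coverage profile is simulated
at the requested cut number (2000 templates per layout), and the
"mutant" repositions nucleosomes by half a repeat (+81 bp) inside
planted slots. Comparing wild-type and mutant generated at equal cut
numbers is the *matched* design; at unequal numbers (e.g. n = 45,
~16% Monos, vs n = 1000, ~100%) the neighborhood bias differs between
the tracks at every long linker, and detection precision for the
planted changes collapses — the technical-artifact inflation the
matched protocol exists to prevent. The default depth here is 400
counts per 10-bp bin (ordinary deep yeast MNase-seq coverage): at
complete digestion mono-fragment coverage is nearly flat across
15-bp-linker arrays, so much shallower counting noise would swamp
window correlations even between true replicates.

Neither generator models mappability, GC bias, copy-number variation,
fragment-length variation between experiments, or alignment artifacts;
passing tests show the statistics behave correctly under the stated
sampling model, not that real libraries are free of those effects.
`synth_binding` tiles probes at fixed spacing with Gaussian noise and a
constant planted effect — no probe-affinity variation or spatial
autocorrelation beyond the planted regions.

## Numerical and design choices

- Coordinates are 0-based, half-open everywhere; wiggle input is
  converted on read.
- All randomness flows through `numpy.random.Generator`; every
  simulation is bit-reproducible given a seed.
- Pearson r of a zero-variance vector is NaN (flagged), never 0.
- The fragment-length test oracle is an exact inclusion–exclusion
  enumeration over candidate outcomes, cross-checked against literal
  exhaustive enumeration on tiny templates; the simulator is never
  tested against itself.
- Degenerate inputs (empty fragment sets, zero-total tracks, zero
  normalization regions, non-monotone ladders) raise informative
  errors rather than propagating NaN.
- Test and acceptance problem sizes — 10⁶ templates for the oracle
  check, 10,000 templates per titration point, 1-Mb synthetic genomes,
  200-run calibration loops — were chosen so each check resolves its
  effect several σ above Monte-Carlo noise while the whole suite runs
  in well under a minute of compute.

## Known limitations

- The protection curve between the 50× edge and 1000× dyad is a
  modeling choice (linear/cosine), not a measured profile.
- %Monos depends on the attempted-vs-realized cut convention at fixed
  n; conclusions should be stated against %Monos, which is observable,
  rather than n.
- The completeness check inherits the arbitrariness of "visible band";
  its 5% threshold is a convention, not a measurement.
- Dissimilar-region bounds over-call by up to one window per edge by
  construction of the union merging rule.
- The enrichment test treats per-region means as independent samples;
  strong spatial autocorrelation of binding beyond the smoothing
  window would make the effective sample size smaller than n.
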