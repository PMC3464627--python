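# mnasetools

Simulation and comparison toolkit for **standardized MNase-seq**
experiments.

MNase-seq maps nucleosome occupancy by digesting chromatin with
micrococcal nuclease, size-selecting mono-nucleosome DNA (~115–195 bp),
and sequencing it. The digest is not a fair sample of the genome: a
nucleosome enters the mono-nucleosome pool only when MNase cuts fall on
*both* sides of it within the size-selection window, so nucleosomes
flanked by long linkers are over-represented at partial digestion — a
*neighborhood effect* that decays only as digestion approaches
completeness. Comparisons between experiments digested to different
extents therefore confound technical sampling bias with real chromatin
change. This package is for chromatin researchers who want to (i)
quantify that bias by simulation, (ii) select *matched* digests from
gel densitometry, and (iii) compare MNase-seq coverage tracks
genome-wide with the statistics appropriate to matched samples.

## What it computes

- **Digestion simulator** (`templates`, `digestion`): chromatin
  templates carry 147-bp nucleosomes whose per-base cut probability is
  1 in linker DNA and `1/protection(x)` inside a nucleosome, with
  protection rising from 50× at the edge to 1000× at the dyad. *n*
  candidate cuts per template are placed uniformly and realized with
  the local probability; 10,000 templates form a population. The
  extent of digestion is
  `%Monos = #fragments in [115, 195] / #fragments ≥ 115 bp`,
  and aligned mono-fragment coverage is standardized and normalized to
  a fixed reference region.
- **Matched-digest selection** (`gel`): lane intensity profiles are
  calibrated against a size ladder (log-linear mobility), resampled to
  a 1-bp size grid over 0–400 bp, checked for a visible di-nucleosome
  band (250–350 bp), and paired by Pearson correlation; a *match* is
  two complete digests with r > 0.9.
- **Track comparison** (`tracks`): binned coverage tracks are
  standardized to equal totals; Pearson r is computed for 1-kb windows
  tiling (histograms, fraction r > 0.9) or sliding at 10 bp;
  *dissimilar chromatin regions* are merged runs of windows with
  r < 0.5 spanning ≥ 1 kb; dyad-aligned average profiles are stratified
  by flanking-linker class (normal 10–20 bp vs long 21–221 bp).
- **Binding enrichment** (`enrichment`): probe-level log2 ratios are
  smoothed by a 500/250-bp sliding-window average; mean binding in the
  dissimilar regions is tested against 10,000 size-matched random
  regions with a one-tailed Welch (heteroscedastic) t-test.
- **Synthetic data** (`synth`, `io`): generators for replicate track
  pairs with planted dissimilar regions, probe-level binding with a
  planted effect, and digestion-driven wild-type/mutant genomes for
  matched-versus-unmatched contrasts; readers/writers for bedGraph,
  wiggle, BED and chrom.sizes.

## Worked example

`examples/01_digestion_titration.py` digests 10,000 copies of the 4-kb
six-nucleosome template (15-bp linkers except a 142-bp central linker
and a 30-bp upstream linker) across a titration and prints the
neighborhood-bias ratio — mean normalized mono-fragment signal over the
two nucleosomes flanking the central linker relative to nucleosomes
with 15-bp linkers on both sides:

```
n_cuts  %monos  long-linker/normal-linker signal ratio
     5    9.7%  3.09
    10   17.8%  2.62
    20   30.6%  2.44
    50   53.8%  2.42
   150   59.8%  1.86
  1000   98.6%  1.02
```

At 10–30% Monos the long-linker-flanked nucleosomes yield ~2.4–3× the
signal of identically occupied nucleosomes with normal linkers; at
near-complete digestion (99% Monos) the bias is gone. The other
examples show matched-digest selection from simulated gel lanes
(`02`), recovery of planted dissimilar regions from a synthetic
replicate pair (`03`), and the calibration and power of the enrichment
test (`04`).

There is also a thin CLI mirroring the library
(`mnasetools simulate|match|compare|enrich|synth`); run any subcommand
with `--help`.

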