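"""Binding enrichment at dissimilar chromatin regions.

Tiles probe-level log2-ratio binding data across a 1-Mb genome with a
planted +2 effect inside 40 regions, smooths the probes into a
continuous profile (500-bp windows sliding by 250 bp), and compares
per-region mean binding against 10,000 size-matched random regions with
a one-tailed Welch t-test.  A null data set (no effect) shows the test
is calibrated.
"""

import numpy as np

from mnasetools import enrichment, synth

genome = synth.DEFAULT_GENOME
rng = np.random.default_rng(3)
regions = []
for name, length in genome:
    for s in rng.choice(length - 2000, 20, replace=False):
        regions.append((name, int(s), int(s) + 2000))

for label, effect in (("no effect (null)", 0.0), ("planted +2 log2 effect", 2.0)):
    probes = synth.synth_binding(genome, regions, effect=effect, noise_sd=0.5, seed=42)
    result = enrichment.enrichment_analysis(
        probes, regions, genome, n_random=10_000, rng=np.random.default_rng(7)
    )
    print(
        f"{label}: observed mean = {result.observed_mean:+.3f}, "
        f"null mean = {result.null_mean:+.3f}, t = {result.t:.2f}, p = {result.p:.3g}"
    )
print(
    "\nWith no effect the p-value is unremarkable; with a planted effect the\n"
    "enrichment of binding inside the regions is overwhelmingly significant."
)
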