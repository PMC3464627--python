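"""Digestion titration on the six-nucleosome template.

Simulates MNase digestion of 10,000 copies of the 4-kb template at
increasing cut numbers, reporting the extent of digestion (% Monos) and
the neighborhood-bias ratio: mean mono-fragment signal over the two
nucleosomes flanking the 142-bp central linker relative to nucleosomes
flanked by 15-bp linkers on both sides.  A ratio well above 1 at partial
digestion, decaying toward 1 as digestion completes, is the sampling
bias that confounds comparisons between differently digested samples.
"""

import numpy as np

from mnasetools import digestion, templates

template = templates.figure1_template()
rng = np.random.default_rng(0)

print("n_cuts  %monos  long-linker/normal-linker signal ratio")
for n_cuts in (5, 10, 20, 50, 150, 1000):
    result = digestion.simulate_population(
        template, n_cuts=n_cuts, n_templates=10_000, rng=rng
    )
    raw = digestion.tabulate_signal(result.selected, template)
    norm = digestion.normalize_signal(raw, max(len(result.selected), 1))
    means = digestion.nucleosome_mean_signal(norm, template)
    ratio = (means[2] + means[3]) / (means[1] + means[4])
    print(f"{n_cuts:6d}  {100 * result.percent_monos:5.1f}%  {ratio:.2f}")

print(
    "\nThe ratio >1 at low %Monos shows nucleosomes beside long linkers are\n"
    "over-sampled at partial digestion; near-complete digestion removes the bias."
)
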