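"""Validate the interaction score against boundary pairs and module linkage.

Check 1: producer--transporter (metabolic--non-metabolic) pairs should score
stochastically higher than ordinary metabolic pairs (one-sided KS test).
Check 2: high-scoring pairs should share module *terminal* compounds rather
than module-internal intermediates (one-sided Mann-Whitney, edge greater).
"""

from dataclasses import replace

import interflora as ifl
from interflora.workflow import score_dataset

spec = replace(ifl.preset("small", seed=4), n_boundary_pairs=40)
dataset = ifl.generate_dataset(spec)
scored = score_dataset(dataset).scored

ks = ifl.compare_boundary_scores(scored)
print(f"boundary vs metabolic scores: KS statistic {ks.statistic:.3f}, "
      f"one-sided p = {ks.p_value:.3g} (n = {ks.n_a} vs {ks.n_b})")
# small p: boundary pairs concentrate at high scores, as expected if high
# scores mark the interface between intracellular and extracellular metabolism

linkage = ifl.module_linkage_by_window(scored, dataset.pathway.modules, window_width=0.1)
mw = ifl.edge_vs_nonedge_test(linkage)
print(f"module edge- vs non-edge-compound pair scores: U = {mw.statistic:.1f}, "
      f"one-sided p = {mw.p_value:.3g}")
for (lo, hi), frac in zip(linkage.windows, linkage.edge_fraction):
    if frac == frac and lo >= 0.4:  # show the informative upper windows
        print(f"  score window [{lo:+.1f}, {hi:+.1f}): edge-compound fraction {frac:.2f}")
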