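"""Bootstrap accuracy and case-dropping stability of one network.

Edge confidence intervals come from case resampling; the CS coefficient
is the largest share of the sample that can be dropped while node
expected influence still correlates >= 0.7 with the full-sample values in
95% of subsamples (>= 0.5 is conventionally 'stable').
"""

import numpy as np

from rfnet import bootstrap_edges, build_ground_truth, casedrop_stability, sample_score_panel

truth = build_ground_truth("adversity")
panel = sample_score_panel(truth, {"CA+": 631, "CA-": 499}, seed=6)
X = panel.matrix(group="CA-", occasion="t1")

boot = bootstrap_edges(X, B=200, seed=6)  # use B=2000 for a production run
widths = boot.edge_ci[:, 1] - boot.edge_ci[:, 0]
print(f"median 95% CI width over {len(widths)} edges: {np.median(widths):.3f}")

stab = casedrop_stability(X, B=200, seed=7)
print(f"CS coefficient: {stab.cs_coefficient:.2f}")
print(
    "\nNarrow intervals and a CS at or above 0.5 mean edge estimates and"
    " the expected-influence ordering would survive substantial data loss."
)
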