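"""Direct and shortest pathways from each resilience factor to distress.

DP sums the direct RF-GD edges (more negative = stronger direct
distress-dampening associations); SP sums shortest-path lengths with edge
length 1/|w| (lower = stronger routes), classifying each RF's best route
as direct or indirect.
"""

from rfnet import build_ground_truth, sample_score_panel, select_network_ebic, shortest_pathways

truth = build_ground_truth("adversity")
panel = sample_score_panel(truth, {"CA+": 631, "CA-": 499}, seed=5)

for grp in ("CA+", "CA-"):
    net = select_network_ebic(panel, group=grp, occasion="t1")
    res = shortest_pathways(net)
    kinds = {c: res.classification.count(c) for c in ("direct", "indirect", "none")}
    print(f"{grp} t1: DP = {res.dp:+.2f}, SP = {res.sp:.1f}, routes: {kinds}")
print()
net = select_network_ebic(panel, group="CA+", occasion="t1")
print(shortest_pathways(net).table().to_string(index=False))
print(
    "\nEach row shows an RF's direct edge to distress and its optimal route;"
    " unreachable RFs are classified 'none' and carry the recorded penalty."
)
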