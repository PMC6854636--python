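"""Score an ordinal item panel into factor scores.

Items travel through thresholds -> polychoric correlations -> a
single-factor ULS fit per occasion -> occasion-pooled parameters ->
regression factor scores. Restricted-range scales are collapsed to a
binary protective indicator instead.
"""

from rfnet import build_ground_truth, sample_item_panel, score_item_panel

truth = build_ground_truth("adversity")
items = sample_item_panel(truth, {"CA+": 400, "CA-": 400}, seed=2)
print(f"item panel: {len(items.items)} items across {len(items.scales)} scales")

panel, models = score_item_panel(
    items,
    binarize={"aggression": "any-endorsement", "expressive_suppression": "any-endorsement"},
)
fit = models["friendship_support"]
print("friendship support loadings:", [round(x, 2) for x in fit.loadings])
print(panel.data[["subject_id", "group", "occasion", "friendship_support", "aggression"]].head())
print(
    "\nLoadings near the generating value (0.7) indicate the ordinal chain"
    " recovered the measurement model; 'aggression' is the 0/1 protective"
    " (no-endorsement) class."
)
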