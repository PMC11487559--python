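"""Evaluate how well a state score separates its planted group.

Scores a cohort where only Senescence carries a planted effect, then
computes (1) the ROC AUC of the Senescence score against the truth labels,
(2) the dominant-state distribution per truth group, and (3) a two-sided
rank-sum comparison of every state between senescent and other samples.
"""

import pandas as pd

import tcellstates as tcs

cfg = tcs.default_states_config(effect=0.0)
cfg["Senescence"] = tcs.StateConfig(7, 3.0)
bundle = tcs.generate_cohort(n_genes=8000, n_samples=40, states_config=cfg, seed=23)

result = tcs.score_samples(
    bundle.expression,
    bundle.marker_sets,
    bundle.reference,
    bundle.housekeeping,
    seed=1,
)

labels = bundle.truth == "Senescence"
auc = tcs.roc_auc(result.scores.loc["Senescence"].to_numpy(), labels.to_numpy())
print(f"Senescence score AUC vs truth: {auc:.3f}")
print("(1.0 = every senescent sample outscores every other sample)")
print()

groups = pd.Series(
    ["senescent" if v else "other" for v in labels], index=bundle.truth.index
)
dom = tcs.dominant_state_proportions(result, groups)
print("dominant-state proportions per group:")
print(dom.proportions.round(2).to_string())
print()

table = tcs.compare_groups(result, groups, correction="bh")
print("rank-sum comparison senescent vs other (BH-adjusted):")
print(table.round(4).to_string())
print("Senescence separates the groups decisively; the other states carry")
print("no planted effect, so any small q-value among them is a chance-level")
print("false positive.")
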