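"""Score a synthetic bulk cohort for the eight T cell states.

Builds a small self-consistent cohort (6000 genes, 16 samples, each sample
dominated by one planted state at log2 effect 3), runs the full scoring
pipeline, and prints the state × sample score table.  High values on the
diagonal pattern — each sample scoring highest for its planted state —
show the rank statistic recovering the planted biology.
"""

import tcellstates as tcs

bundle = tcs.generate_cohort(n_genes=6000, n_samples=16, seed=11)
result = tcs.score_samples(
    bundle.expression,
    bundle.marker_sets,
    bundle.reference,
    bundle.housekeeping,
    seed=1,
)

print("TCSS (rows: states, columns: samples), rounded:")
print(result.scores.round(3).to_string())
print()
match = (result.scores.idxmax(axis=0) == bundle.truth).mean()
print(f"samples whose top-scoring state matches the planted state: {match:.0%}")
print("Scores lie in [0, 1]; ~0.5 on the rank part means markers are")
print("indistinguishable from background, values near 1 mean the state's")
print("markers outrank nearly every background gene in that sample.")
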