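"""Build pseudo-bulk samples and a reference spectrum from labelled cells.

Simulates a labelled single-cell cohort (two subtypes with disjoint planted
marker programs), aggregates it into pseudo-bulk samples — per subtype with
c cells: max(1, floor(c/5)) replicates, each averaging a random 60% of the
cells — and averages cells per state into a reference spectrum.
"""

import tcellstates as tcs

cohort = tcs.generate_cell_cohort(
    n_genes=800,
    cells_per_subtype={"Tn": 25, "Temra": 40},
    subtype_effects={"Tn": (8, 3.0), "Temra": (8, 3.0)},
    seed=4,
)

matrix, labels = tcs.make_pseudobulk(cohort, seed=1)
print("pseudo-bulk samples per subtype:")
print(labels.value_counts().to_string())
print("(25 cells -> 5 replicates of 15 cells; 40 cells -> 8 of 24)")
print()

ref = tcs.build_reference(cohort, {"Tn": "Quiescence", "Temra": "Senescence"})
print("reference spectrum, first genes (mean TPM per state):")
print(ref.data.head(5).round(2).to_string())
print()
print("Each pseudo-bulk sample emulates a flow-purified bulk RNA-seq sample")
print("of one subtype; the spectrum columns are per-state average profiles.")
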