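# Methods

## The model

`tcellstates` quantifies eight T cell states — Quiescence, Regulating,
Proliferation, Helper, Cytotoxicity, Progenitor exhaustion, Terminal
exhaustion, Senescence — one sample at a time from a bulk or pseudo-bulk
transcriptome in TPM units. The score for a state in a sample is a
Mann–Whitney-U rank statistic: it asks how highly that state's marker genes
rank, within the sample, against an expression-stratified random background
of genes, and then discounts the result by how far each marker falls short
of a per-state reference expression level.

The pipeline for a gene × sample TPM matrix is:

1. **log2 transform.** Every value v becomes log2(v + 1).
2. **Housekeeping correction.** With HK̄_i the mean expression of the
   housekeeping genes in sample i, every value in sample i is multiplied by
   (mean_j HK̄_j) / HK̄_i. Afterwards all samples share the same mean
   housekeeping expression (the pre-correction global mean), which makes
   reference comparisons meaningful across samples with different global
   expression levels. The correction is idempotent and is applied on the
   log2 scale, after the transform.
3. **Background draw.** Genes are ordered by pooled mean corrected
   expression, split into `n_bins` = 50 contiguous bins from high to low,
   and `per_bin` = 100 genes are drawn uniformly without replacement per bin
   (5000 genes by default). One draw per run is shared across all states and
   samples; the draw is fully determined by the seed.
4. **Rank score (per state, per sample).** The scored universe is the
   background minus that state's markers, plus the state's markers present
   in the matrix (N = m background + n markers). Each sample's column is
   ranked ascending 1..N with mid-ranks for ties, and

       U = Σ R.marker − n(n+1)/2.

   Under the default `unit` normalization the intermediate score is
   U / (n·m): the probability that a random marker outranks a random
   background gene (ties counted ½), which lies in [0, 1]. A `printed`
   mode dividing U by N is retained behind a flag; it is not bounded by 1
   in general (U can reach n·m > N when n > N/m), which is why `unit` is
   the default for a score advertised as ranging from 0 to 1.
5. **Reference weighting.** Each marker's corrected expression sp_i is
   compared with the reference spectrum value ref_i for that state on the
   log2(TPM+1) scale: weight 1 if sp_i ≥ ref_i, else sp_i/ref_i. The final
   score is the rank score times the mean weight. This caps the influence
   of a single extremely over-expressed marker: a high score requires
   generally high expression across the set.

### Assumptions

- Input is TPM (or a comparably normalized within-sample abundance); the
  scorer never re-normalizes library sizes beyond the housekeeping step.
- Gene identifiers are matched by exact string comparison after whitespace
  trimming; marker sets, housekeeping list, reference and matrix must share
  one identifier namespace.
- The score is purely rank-based within a sample, so it is invariant to any
  strictly monotone transform of a sample's (post-correction) column; only
  the reference weights are scale-sensitive.

## Numerical and design choices

- **Binning statistic.** Genes are ordered for binning by the mean corrected
  expression pooled across all samples; a pooled ordering gives one shared
  background for all samples, which the shared rank matrix requires. Sorting
  is stable with ties broken by input gene order, so the binning is
  deterministic.
- **Background/marker disjointness.** The state's marker genes are removed
  from the background at score time and N is adjusted, so no gene is both
  evidence and null.
- **Ties.** Mid-ranks everywhere (the Mann–Whitney convention); ties are
  common after log transformation of zero-inflated data.
- **Reference scale.** The spectrum is stored in TPM and compared on the
  log2(TPM+1) scale, since sp_i comes from the corrected log-scale matrix;
  the reference itself receives no housekeeping correction. ref_i = 0 gives
  weight 1 — a marker absent from the reference cannot penalize — and
  sp_i = ref_i = 0 falls in the sp ≥ ref branch.
- **Missing markers.** Markers absent from the input matrix are dropped from
  both the rank score and the weight mean; the effective count is recorded
  in the result. A state with fewer than 2 present markers is skipped with a
  warning (or errors under `strict=True`).
- **Small matrices.** If fewer than `n_bins × per_bin` genes are available
  after reserving the largest marker set, `per_bin` shrinks to
  ⌊(genes − reserve)/n_bins⌋ with a warning; below 5 genes per bin the draw
  is refused.
- **Degenerate inputs.** Negative expression, missing values, duplicate
  sample ids, samples with zero housekeeping mean, and marker sets smaller
  than 2 genes are all hard errors; duplicate gene rows are collapsed by
  summation with a warning.
- **Determinism.** All randomness (background draw, pseudo-bulk draws,
  synthetic generation) flows from explicit integer seeds via
  `numpy.random.default_rng`; identical inputs and seed give bitwise-
  identical results. The seed is recorded in every result object.
- **Group comparisons** use the two-sided Wilcoxon rank-sum test: exact null
  for combined n ≤ 20, normal approximation with continuity correction
  above. No multiple-testing correction is applied across the eight states
  by default; a Benjamini–Hochberg option exists.
- **Dominance ties.** Argmax ties in dominant-state calls are broken by the
  canonical state order and flagged per sample.

## Pseudo-bulk protocol

For a subtype with c labelled cells, `make_pseudobulk` emits
max(1, ⌊c/5⌋) replicates; each draws ⌈0.6·c⌉ cells without replacement and
averages them per gene on the linear scale (no re-normalization of column
sums — pre-normalize cells if strict TPM output is needed). The ceiling
guarantees at least one cell per draw; the floor with minimum 1 guarantees
at least one replicate. `build_reference` averages cells per state, via a
user-supplied subtype → state map, on the same linear scale. Subtypes with
fewer than 2 cells are skipped with a warning.

## What the synthetic generator emulates

`generate_cohort` builds a self-consistent bundle: per-gene baseline levels
drawn from Normal(1.0, 1.0) on the log2(TPM+1) scale (a log-normal-like TPM
dynamic range, which is what the 50-bin stratification assumes), samples
assigned one dominant state round-robin, that state's disjoint marker block
shifted up by a configurable log2 effect (default 3, i.e. 8-fold),
housekeeping genes at a solid moderate level with inter-sample jitter of
sd 0.01 so correction factors sit near 1 unless a per-sample library-scale
distortion is planted explicitly, and a reference spectrum built from the
generator's own state-mean profiles. Default marker-set sizes (7–16 genes
per state) sit inside the realistic 5–38 range of curated signatures.
Negative log2 values are clipped at 0 before converting back to TPM, which
adds mild, realistic zero inflation.

What it does **not** emulate: single-cell count noise (dropout, ZINB
overdispersion), correlated gene modules, batch structure beyond a scalar
library-size factor, or marker sets that overlap between states. Passing
tests on these fixtures therefore demonstrate the statistical machinery —
rank behaviour, normalization arithmetic, calibration under the null — not
performance on real cohorts, where marker co-expression and annotation
noise matter.

`generate_cell_cohort` produces labelled cells as subtype mean profiles plus
independent per-cell log2 noise, sufficient to exercise the pseudo-bulk
arithmetic and subtype recovery, again without a realistic count model.

## Problem sizes used in the checks

The bundled verification suite runs cohorts of 6,000–15,000 genes and 8–60
samples, 100 randomized cohorts for the score-range sweep, 20 seeds for
dominant-state recovery and background-seed stability, 200 replicates for
null calibration (one state tested per replicate, 12 vs 12 samples), and
200–500 random instances for the brute-force oracle comparisons. These
sizes give stable statistics while keeping a full run to a few minutes on
one core.

## Known limitations

- Scores are comparable across samples only after the housekeeping
  correction; matrices from incompatible platforms should not be mixed.
- Per-cell scoring of raw scRNA-seq matrices is out of scope: zero
  inflation distorts within-cell ranks in ways the background draw does not
  model. Aggregate cells to pseudo-bulk first.
- The percentage weight depends on the reference spectrum's scale being
  comparable to the corrected matrix; a reference from a very different
  platform will shift absolute scores (though not within-dataset rankings).
- With user-defined (non-canonical) marker sets the [0, 1] guarantee and
  rank logic hold, but the canonical-state conveniences (dominance order)
  treat the sets in table order.
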