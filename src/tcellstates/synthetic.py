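"""Self-consistent synthetic fixtures: expression cohorts with planted state
effects, marker sets, housekeeping genes, reference spectra and labelled
single-cell cohorts.

The generator works on the log2(TPM+1) scale.  Per-gene baseline levels are
drawn from a normal distribution (location 1.0, scale 1.0 by default),
giving the skewed, log-normal-like TPM dynamic range that expression-
stratified background binning assumes.  Each sample is assigned one dominant
state and that state's marker genes are shifted up by a configurable log2
effect size; housekeeping genes get near-zero inter-sample variance so
correction factors stay close to 1 unless a per-sample library-scale
distortion is planted explicitly.  The reference spectrum is built from the
generator's own state-mean profiles, so a sample in state s expresses s's
markers at the reference level on average.

All randomness flows from a single integer seed; identical seeds give
bitwise-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    CANONICAL_STATES,
    ExpressionMatrix,
    HousekeepingList,
    MarkerGeneSets,
    ReferenceSpectrum,
    ValidationError,
    write_expression_matrix,
    write_gene_sets,
    write_housekeeping,
    write_reference_spectrum,
)
from .pseudobulk import CellCohort

__all__ = [
    "StateConfig",
    "CohortBundle",
    "default_states_config",
    "generate_cohort",
    "generate_cell_cohort",
    "write_bundle",
]

#: Marker-set sizes for the default configuration, one per canonical state,
#: spanning the realistic 5-38 range of curated T cell state signatures.
_DEFAULT_SET_SIZES = {
    "Quiescence": 14,
    "Regulating": 10,
    "Proliferation": 9,
    "Helper": 12,
    "Cytotoxicity": 16,
    "Progenitor exhaustion": 8,
    "Terminal exhaustion": 11,
    "Senescence": 7,
}


@dataclass
class StateConfig:
    """Marker count and planted log2 effect size for one state."""

    n_markers: int
    effect: float

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ValidationError("each state needs >= 2 markers")
        if self.effect < 0:
            raise ValidationError("effect sizes must be >= 0")


def default_states_config(effect: float = 3.0) -> dict[str, StateConfig]:
    """All eight canonical states with realistic set sizes and one shared
    log2 effect size (default 3, an 8-fold marker up-regulation)."""
    return {s: StateConfig(_DEFAULT_SET_SIZES[s], effect) for s in CANONICAL_STATES}


@dataclass
class CohortBundle:
    """Everything needed to run and check a scoring experiment."""

    expression: ExpressionMatrix
    marker_sets: MarkerGeneSets
    housekeeping: HousekeepingList
    reference: ReferenceSpectrum
    truth: pd.Series  # sample id -> planted dominant state
    seed: int
    config: dict[str, StateConfig] = field(repr=False)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(n)]


def generate_cohort(
    n_genes: int = 12000,
    n_samples: int = 48,
    states_config: dict[str, StateConfig] | None = None,
    hk_count: int = 500,
    noise_sd: float = 0.5,
    seed: int = 1,
    baseline_loc: float = 1.0,
    baseline_scale: float = 1.0,
    hk_jitter_sd: float = 0.01,
    library_scales: np.ndarray | None = None,
    background_budget: int = 5000,
) -> CohortBundle:
    """Generate a synthetic bulk cohort with planted state effects.

    Samples are assigned dominant states round-robin over the configured
    states; sample ``S0007`` with truth ``Cytotoxicity`` has every
    Cytotoxicity marker shifted up by that state's log2 effect.  Marker
    blocks and the housekeeping block are disjoint.

    Parameters
    ----------
    n_genes, n_samples
        Cohort dimensions.  ``n_genes`` must cover the default background
        draw (5000 genes) plus all marker and housekeeping genes.
    states_config
        Per-state marker count and log2 effect; defaults to all eight
        canonical states at effect 3.
    hk_count
        Number of housekeeping genes (inter-sample jitter ``hk_jitter_sd``).
    noise_sd
        Per-gene, per-sample log2 noise standard deviation.
    library_scales
        Optional per-sample multiplicative TPM distortions (length
        ``n_samples``) to exercise the housekeeping correction.
    background_budget
        Gene count reserved for the downstream background draw when checking
        feasibility (default 5000, the standard 50 × 100 draw); lower it
        together with the scorer's ``n_bins``/``per_bin`` for small fixtures.
    """
    config = states_config if states_config is not None else default_states_config()
    for state, cfg in config.items():
        if not isinstance(cfg, StateConfig):
            raise ValidationError(f"states_config[{state!r}] must be a StateConfig")
    total_markers = sum(c.n_markers for c in config.values())
    required = background_budget + total_markers + hk_count
    if n_genes < required:
        raise ValidationError(
            f"n_genes={n_genes} too small: need >= {required} "
            f"({background_budget} background + {total_markers} markers + "
            f"{hk_count} housekeeping)"
        )
    if library_scales is not None:
        library_scales = np.asarray(library_scales, dtype=float)
        if library_scales.shape != (n_samples,):
            raise ValidationError("library_scales must have length n_samples")
        if (library_scales <= 0).any():
            raise ValidationError("library_scales must be positive")

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    samples = [f"S{i:04d}" for i in range(n_samples)]

    mu = rng.normal(baseline_loc, baseline_scale, size=n_genes)

    # Disjoint gene blocks: markers per state first, then housekeeping.
    cursor = 0
    marker_idx: dict[str, np.ndarray] = {}
    for state, cfg in config.items():
        marker_idx[state] = np.arange(cursor, cursor + cfg.n_markers)
        cursor += cfg.n_markers
    hk_idx = np.arange(cursor, cursor + hk_count)
    # Housekeeping genes sit at a solid moderate level so their mean cannot
    # be dominated by zeros after clipping.
    mu[hk_idx] = rng.normal(3.0, 0.5, size=hk_count)

    states = list(config)
    truth = pd.Series(
        [states[i % len(states)] for i in range(n_samples)],
        index=samples,
        name="state",
    )

    log2x = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    log2x[hk_idx, :] = mu[hk_idx, None] + rng.normal(
        0.0, hk_jitter_sd, size=(hk_count, n_samples)
    )
    for j, state in enumerate(truth):
        log2x[marker_idx[state], j] += config[state].effect

    tpm = np.exp2(np.clip(log2x, 0.0, None)) - 1.0
    if library_scales is not None:
        tpm = tpm * library_scales[None, :]
    expression = ExpressionMatrix(
        pd.DataFrame(tpm, index=genes, columns=samples), stage="tpm"
    )

    sets = MarkerGeneSets(
        {state: [genes[i] for i in idx] for state, idx in marker_idx.items()},
        strict=all(s in CANONICAL_STATES for s in states),
    )
    hk = HousekeepingList([genes[i] for i in hk_idx])

    # Reference spectrum from the generator's own state means: baseline
    # everywhere, each state's own markers raised by its effect.
    ref_cols = {}
    for state in states:
        prof = mu.copy()
        prof[marker_idx[state]] += config[state].effect
        ref_cols[state] = np.exp2(np.clip(prof, 0.0, None)) - 1.0
    reference = ReferenceSpectrum(pd.DataFrame(ref_cols, index=genes))

    return CohortBundle(
        expression=expression,
        marker_sets=sets,
        housekeeping=hk,
        reference=reference,
        truth=truth,
        seed=seed,
        config=config,
    )


def generate_cell_cohort(
    n_genes: int = 3000,
    cells_per_subtype: dict[str, int] | None = None,
    subtype_effects: dict[str, tuple[int, float]] | None = None,
    noise_sd: float = 0.5,
    seed: int = 1,
    baseline_loc: float = 1.0,
    baseline_scale: float = 1.0,
) -> CellCohort:
    """Generate a labelled single-cell cohort for the pseudo-bulk protocol.

    Each subtype gets a mean profile (baseline plus its planted marker
    shift); each cell is that profile plus cell-level log2 noise.

    Parameters
    ----------
    cells_per_subtype
        Subtype name → number of cells (each >= 2); default two subtypes of
        10 cells.
    subtype_effects
        Subtype name → (n_marker_genes, log2 effect).  Marker blocks are
        disjoint across subtypes.  Subtypes without an entry get no shift.
    """
    if cells_per_subtype is None:
        cells_per_subtype = {"TypeA": 10, "TypeB": 10}
    if subtype_effects is None:
        subtype_effects = {st: (10, 2.0) for st in cells_per_subtype}
    for st, n in cells_per_subtype.items():
        if n < 2:
            raise ValidationError(f"subtype {st!r} needs >= 2 cells, got {n}")
    total_markers = sum(nm for nm, _ in subtype_effects.values())
    if n_genes < total_markers + 100:
        raise ValidationError(
            f"n_genes={n_genes} too small for {total_markers} marker genes"
        )

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    mu = rng.normal(baseline_loc, baseline_scale, size=n_genes)

    cursor = 0
    profiles: dict[str, np.ndarray] = {}
    for st in cells_per_subtype:
        prof = mu.copy()
        if st in subtype_effects:
            nm, eff = subtype_effects[st]
            prof[cursor : cursor + nm] += eff
            cursor += nm
        profiles[st] = prof

    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for st, n_cells in cells_per_subtype.items():
        for k in range(n_cells):
            cell = f"{st}_c{k:04d}"
            log2c = profiles[st] + rng.normal(0.0, noise_sd, size=n_genes)
            columns[cell] = np.exp2(np.clip(log2c, 0.0, None)) - 1.0
            labels[cell] = st
    data = pd.DataFrame(columns, index=genes)
    return CellCohort(data=data, labels=pd.Series(labels, name="subtype"))


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort bundle as the standard text formats.

    Returns a name → path mapping for the five files written: expression TSV,
    marker-set GMT, housekeeping list, reference-spectrum TSV and truth TSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "markers": out / "markers.gmt",
        "housekeeping": out / "housekeeping.txt",
        "reference": out / "reference.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression_matrix(bundle.expression, paths["expression"])
    write_gene_sets(bundle.marker_sets, paths["markers"])
    write_housekeeping(bundle.housekeeping, paths["housekeeping"])
    write_reference_spectrum(bundle.reference, paths["reference"])
    bundle.truth.to_csv(paths["truth"], sep="\t", header=False)
    return paths
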