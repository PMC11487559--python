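"""The TCSS core: stratified background sampling, per-sample ranking, the
Mann–Whitney-U statistic, reference-percentage weighting and the final score.

For one T cell state and one sample, the score asks: how highly do the
state's marker genes rank among a fixed, expression-stratified background of
genes within that sample?  Formally, with n marker ranks R_1..R_n among
N = n + m genes (m background genes),

    U = sum(R_i) - n(n+1)/2

is the Mann–Whitney U statistic of markers versus background.  Under the
default ``"unit"`` normalization the intermediate score is U / (n*m): the
probability that a randomly chosen marker outranks a randomly chosen
background gene (ties counted half), which lies in [0, 1].  The ``"printed"``
normalization divides U by N instead.

The final TCSS multiplies this rank score by the mean of per-marker
"percentage" weights derived from a reference spectrum: weight 1 when the
sample expresses the marker at or above the reference level, sp/ref when
below.  This caps the contribution of individually over-expressed markers so
a high score requires generally high expression across the whole set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import (
    ExpressionMatrix,
    HousekeepingList,
    MarkerGeneSets,
    ReferenceSpectrum,
    TCSSResult,
    ValidationError,
)
from .preprocess import housekeeping_correct, log2_transform

__all__ = [
    "BackgroundSample",
    "select_background",
    "rank_sample",
    "tcss_prime",
    "reference_percentage",
    "tcss_final",
    "score_samples",
]

DEFAULT_N_BINS = 50
DEFAULT_PER_BIN = 100
MIN_PER_BIN = 5


@dataclass
class BackgroundSample:
    """An expression-stratified random draw of background genes.

    Genes are ordered by pooled (mean across samples) expression, split into
    ``n_bins`` contiguous bins from high to low, and ``per_bin`` genes are
    drawn uniformly without replacement from each bin.  Stratification keeps
    the background's expression distribution representative of the whole
    matrix, so marker ranks are compared against a realistic null.
    """

    genes: list[str]
    n_bins: int
    per_bin: int
    seed: int
    ordering_statistic: pd.Series = field(repr=False)
    warnings: list[str] = field(default_factory=list)


def select_background(
    m: ExpressionMatrix,
    n_bins: int = DEFAULT_N_BINS,
    per_bin: int = DEFAULT_PER_BIN,
    seed: int = 1,
    reserve: int = 0,
) -> BackgroundSample:
    """Draw a stratified background gene sample from a corrected matrix.

    Parameters
    ----------
    m
        Corrected (or log2) expression matrix.
    n_bins, per_bin
        Stratification parameters; the defaults draw 50 × 100 = 5000 genes.
    seed
        Seed for the uniform within-bin draws; a fixed seed gives an
        identical gene set on every call.
    reserve
        Number of genes to treat as unavailable when deciding whether the
        requested draw fits (callers reserve the largest marker set so the
        background plus any marker set never exceeds the gene universe).
        If the matrix is too small, ``per_bin`` is shrunk to
        ``floor((n_genes - reserve) / n_bins)`` with a warning; shrinking
        below 5 genes per bin is an error.
    """
    if m.n_genes < n_bins:
        raise ValidationError(
            f"matrix has {m.n_genes} genes but {n_bins} bins were requested"
        )
    notes: list[str] = []
    available = m.n_genes - reserve
    max_per_bin = available // n_bins
    if per_bin > max_per_bin:
        if max_per_bin < MIN_PER_BIN:
            raise ValidationError(
                f"cannot draw a background: only {available} genes available "
                f"for {n_bins} bins (per-bin draw would be {max_per_bin} < "
                f"{MIN_PER_BIN})"
            )
        notes.append(
            f"per_bin shrunk from {per_bin} to {max_per_bin} "
            f"({m.n_genes} genes, {reserve} reserved)"
        )
        warnings.warn(notes[-1])
        per_bin = max_per_bin

    pooled = m.data.mean(axis=1)
    # Stable sort, high to low; ties broken by input gene order so the
    # binning is deterministic regardless of float ties.
    order = np.argsort(-pooled.to_numpy(), kind="stable")
    sorted_genes = m.data.index.to_numpy()[order]
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for bin_genes in np.array_split(sorted_genes, n_bins):
        take = min(per_bin, len(bin_genes))
        chosen.extend(rng.choice(bin_genes, size=take, replace=False))
    return BackgroundSample(
        genes=[str(g) for g in chosen],
        n_bins=n_bins,
        per_bin=per_bin,
        seed=seed,
        ordering_statistic=pooled,
        warnings=notes,
    )


def rank_sample(column: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..N of one sample's expression values.

    The highest expression receives rank N; tied values receive the average
    of their rank span (mid-ranks, the Mann–Whitney convention).
    """
    return rankdata(np.asarray(column), method="average")


def tcss_prime(
    marker_ranks: np.ndarray,
    n_markers: int,
    n_background: int,
    mode: str = "unit",
) -> float:
    """Rank-based intermediate score from the markers' ranks in one sample.

    ``mode="unit"`` divides U by n_markers * n_background, the standard
    Mann–Whitney normalization, giving the marker-vs-background win
    probability in [0, 1].  ``mode="printed"`` divides U by
    N = n_markers + n_background.
    """
    marker_ranks = np.asarray(marker_ranks, dtype=float)
    if n_markers < 2:
        raise ValidationError(f"need >= 2 markers to score, got {n_markers}")
    if marker_ranks.shape[-1] != n_markers:
        raise ValidationError("marker_ranks length does not match n_markers")
    u = marker_ranks.sum(axis=-1) - n_markers * (n_markers + 1) / 2.0
    if mode == "unit":
        return u / (n_markers * n_background)
    if mode == "printed":
        return u / (n_markers + n_background)
    raise ValidationError(f"unknown mode {mode!r}; expected 'unit' or 'printed'")


def reference_percentage(sample_expr: np.ndarray, ref_expr: np.ndarray) -> np.ndarray:
    """Per-marker weights from sample vs reference expression (same scale).

    weight_i = 1 if sp_i >= ref_i else sp_i / ref_i.  A reference value of 0
    yields weight 1 (an sp of 0 then satisfies sp >= ref, and a marker absent
    from the reference cannot penalize the score).  All weights lie in [0, 1].
    """
    sp = np.asarray(sample_expr, dtype=float)
    ref = np.asarray(ref_expr, dtype=float)
    if sp.shape != ref.shape:
        raise ValidationError("sample and reference vectors differ in length")
    if (sp < 0).any() or (ref < 0).any():
        raise ValidationError("reference_percentage requires non-negative inputs")
    with np.errstate(over="ignore"):
        ratio = np.divide(sp, ref, out=np.ones_like(sp), where=ref > 0)
    return np.where(sp >= ref, 1.0, ratio)


def tcss_final(tcss_prime_value: float, weights: np.ndarray) -> float:
    """Final score: the rank score scaled by the mean percentage weight."""
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValidationError("weights are empty")
    return float(tcss_prime_value) * float(weights.mean())


def score_samples(
    m: ExpressionMatrix,
    sets: MarkerGeneSets,
    ref: ReferenceSpectrum,
    hk: HousekeepingList,
    seed: int = 1,
    mode: str = "unit",
    strict: bool = False,
    n_bins: int = DEFAULT_N_BINS,
    per_bin: int = DEFAULT_PER_BIN,
    min_hk: int = 50,
) -> TCSSResult:
    """Score every state for every sample of a TPM matrix.

    Pipeline: log2(TPM+1) → housekeeping correction → one stratified
    background draw (shared across all states and samples) → per state:
    restrict to (background minus that state's markers) plus the markers
    present in the matrix, rank each sample's column, compute the rank score,
    apply reference-percentage weights, and record the final TCSS.

    The reference spectrum, stored on the TPM scale, is compared on the
    log2(TPM+1) scale so sample and reference values share units; the
    reference receives no housekeeping correction.

    Parameters
    ----------
    m
        TPM-stage gene × sample matrix.
    sets, ref, hk
        Marker gene sets, reference spectrum, housekeeping list.
    seed
        Background-draw seed (recorded in the result).
    mode
        ``"unit"`` (default, scores in [0, 1]) or ``"printed"``.
    strict
        If True, a state with fewer than 2 markers present in the matrix is
        an error; otherwise it is skipped with a warning.
    """
    if mode not in ("unit", "printed"):
        raise ValidationError(f"unknown mode {mode!r}")
    if m.stage != "tpm":
        raise ValidationError(f"score_samples expects stage='tpm', got {m.stage!r}")

    corrected = housekeeping_correct(log2_transform(m), hk, min_hk=min_hk)
    gene_index = corrected.data.index

    max_set = max(len(sets[s]) for s in sets)
    background = select_background(
        corrected, n_bins=n_bins, per_bin=per_bin, seed=seed, reserve=max_set
    )
    notes = list(background.warnings)
    ref_log = ref.log2()

    rows: dict[str, np.ndarray] = {}
    effective: dict[str, int] = {}
    for state in sets:
        marker_set = set(sets[state])
        present = [g for g in sets[state] if g in gene_index]
        if len(present) < len(sets[state]):
            notes.append(
                f"{state}: {len(sets[state]) - len(present)} marker(s) "
                "absent from the matrix"
            )
        if len(present) < 2:
            msg = (
                f"state {state!r} has {len(present)} marker(s) present in the "
                "matrix; at least 2 are required"
            )
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg + "; state skipped")
            notes.append(msg + "; state skipped")
            continue
        if state not in ref.data.columns:
            raise ValidationError(
                f"reference spectrum has no column for state {state!r}"
            )

        bg_genes = [g for g in background.genes if g not in marker_set]
        n_mk, n_bg = len(present), len(bg_genes)
        x = corrected.data.loc[bg_genes + present].to_numpy()
        ranks = rankdata(x, method="average", axis=0)
        marker_ranks = ranks[n_bg:, :]  # (n_mk, n_samples)
        prime = tcss_prime(marker_ranks.T, n_mk, n_bg, mode=mode)

        ref_vec = np.array(
            [ref_log.at[g, state] if g in ref_log.index else 0.0 for g in present]
        )
        sp = corrected.data.loc[present].to_numpy()  # (n_mk, n_samples)
        w = reference_percentage(sp, np.repeat(ref_vec[:, None], sp.shape[1], axis=1))
        rows[state] = prime * w.mean(axis=0)
        effective[state] = n_mk

    if not rows:
        raise ValidationError("no state could be scored (all skipped)")
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=m.samples)
    return TCSSResult(
        scores=scores,
        effective_markers=effective,
        seed=seed,
        mode=mode,
        warnings=notes,
    )
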