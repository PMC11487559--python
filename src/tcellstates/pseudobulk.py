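"""Pseudo-bulk sample generation and reference-spectrum construction from
labelled single-cell expression matrices.

A pseudo-bulk sample emulates a purified bulk RNA-seq sample of one T cell
subtype: a random 60% of that subtype's cells are drawn without replacement
and their expression values averaged.  The number of replicates per subtype
is one fifth of its cell count (at least one), so better-sampled subtypes
contribute proportionally more pseudo-bulk samples.

Averaging is on the linear expression scale with no re-normalization of
column sums; callers who need strict TPM output should normalize cells
beforehand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ReferenceSpectrum, ValidationError

__all__ = [
    "CellCohort",
    "n_pseudobulk_reps",
    "pseudobulk_draw_size",
    "make_pseudobulk",
    "build_reference",
    "read_cell_labels",
    "write_cell_labels",
]


@dataclass
class CellCohort:
    """A gene × cell expression matrix with one subtype label per cell."""

    data: pd.DataFrame  # genes × cells, non-negative, TPM-like
    labels: pd.Series  # cell id -> subtype name

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("cell expression values must be non-negative")
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        cells = set(map(str, self.data.columns))
        labelled = set(self.labels.index)
        missing = cells - labelled
        if missing:
            raise ValidationError(
                f"{len(missing)} cell(s) have no subtype label "
                f"(e.g. {sorted(missing)[0]!r})"
            )
        # labels for cells not in the matrix are tolerated but unused
        self.labels = self.labels.loc[[str(c) for c in self.data.columns]]

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.labels.unique())

    def cells_of(self, subtype: str) -> list[str]:
        return list(self.labels.index[self.labels == subtype])


def n_pseudobulk_reps(n_cells: int, reps_divisor: int = 5) -> int:
    """Replicates for a subtype with ``n_cells`` cells: max(1, floor(c/5))."""
    return max(1, n_cells // reps_divisor)


def pseudobulk_draw_size(n_cells: int, fraction: float = 0.6) -> int:
    """Cells per replicate: ceil(fraction * c), guaranteeing >= 1 cell."""
    return math.ceil(fraction * n_cells)


def make_pseudobulk(
    cohort: CellCohort,
    fraction: float = 0.6,
    reps_divisor: int = 5,
    seed: int = 1,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate pseudo-bulk samples from a labelled cell cohort.

    For each subtype with c cells, ``max(1, floor(c / reps_divisor))``
    replicates are produced; each draws ``ceil(fraction * c)`` cells without
    replacement and emits the per-gene arithmetic mean as one sample named
    ``<subtype>_<rep>``.

    Returns
    -------
    (matrix, labels)
        The pseudo-bulk expression matrix (stage ``"tpm"``) and a Series
        mapping each pseudo-bulk sample name to its subtype.
    """
    if not (0 < fraction <= 1):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    sample_labels: dict[str, str] = {}
    values = cohort.data.to_numpy()
    col_of = {str(c): i for i, c in enumerate(cohort.data.columns)}
    for subtype in cohort.subtypes:
        cells = cohort.cells_of(subtype)
        if len(cells) < 2:
            warnings.warn(
                f"subtype {subtype!r} has {len(cells)} cell(s); skipped"
            )
            continue
        idx = np.array([col_of[c] for c in cells])
        size = pseudobulk_draw_size(len(cells), fraction)
        for rep in range(n_pseudobulk_reps(len(cells), reps_divisor)):
            draw = rng.choice(idx, size=size, replace=False)
            name = f"{subtype}_{rep + 1}"
            columns[name] = values[:, draw].mean(axis=1)
            sample_labels[name] = subtype
    if not columns:
        raise ValidationError("no subtype had >= 2 cells; nothing to generate")
    matrix = pd.DataFrame(columns, index=cohort.data.index)
    return (
        ExpressionMatrix(matrix, stage="tpm"),
        pd.Series(sample_labels, name="subtype"),
    )


def build_reference(cohort: CellCohort, state_map: dict[str, str]) -> ReferenceSpectrum:
    """Average cell expression per state to form a reference spectrum.

    ``state_map`` maps each subtype name to the T cell state it represents
    (e.g. naive T cells to Quiescence, terminally differentiated
    effector-memory cells to Senescence).  For each target state, the
    per-gene arithmetic mean over all mapped cells becomes that state's
    reference column, on the same (TPM-like) scale as the input cells.
    """
    target_states = list(dict.fromkeys(state_map.values()))
    columns: dict[str, np.ndarray] = {}
    for state in target_states:
        subtypes = [st for st, s in state_map.items() if s == state]
        cells: list[str] = []
        for st in subtypes:
            cells.extend(cohort.cells_of(st))
        if not cells:
            raise ValidationError(f"no cells mapped to state {state!r}")
        columns[state] = cohort.data[cells].to_numpy().mean(axis=1)
    return ReferenceSpectrum(pd.DataFrame(columns, index=cohort.data.index))


def read_cell_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (cell_id <TAB> subtype), no header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected exactly 2 tab-separated columns")
    return pd.Series(df[1].values, index=df[0].values, name="subtype")


def write_cell_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({0: labels.index, 1: labels.values}).to_csv(
        path, sep="\t", header=False, index=False
    )
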