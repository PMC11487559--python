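"""Domain types and file I/O for expression matrices, gene sets, housekeeping
lists and reference spectra.

All tabular formats are plain text: expression matrices and reference spectra
are TSV/CSV with a header row of sample (or state) identifiers and gene
identifiers in the first column; gene sets are GMT or JSON; housekeeping lists
are one gene per line with ``#`` comments.

Gene identifiers are matched by exact string comparison after whitespace
trimming.  No alias or cross-namespace resolution is attempted: supplying
marker sets, housekeeping genes and expression data in a consistent identifier
namespace (symbols throughout, or Ensembl throughout) is the caller's
responsibility.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_STATES",
    "ValidationError",
    "ExpressionMatrix",
    "MarkerGeneSets",
    "HousekeepingList",
    "ReferenceSpectrum",
    "TCSSResult",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_housekeeping",
    "write_housekeeping",
    "read_reference_spectrum",
    "write_reference_spectrum",
]

#: The eight T cell states, in canonical order.  This order breaks argmax ties
#: in dominant-state calls and fixes row order in score tables.
CANONICAL_STATES: tuple[str, ...] = (
    "Quiescence",
    "Regulating",
    "Proliferation",
    "Helper",
    "Cytotoxicity",
    "Progenitor exhaustion",
    "Terminal exhaustion",
    "Senescence",
)


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for name in names:
        if not name:
            raise ValidationError(f"empty {what} identifier")
        if name in seen:
            raise ValidationError(f"duplicate {what} identifier: {name!r}")
        seen.add(name)


@dataclass
class ExpressionMatrix:
    """A gene × sample expression matrix with a processing-stage tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with one column per sample.
    stage
        ``"tpm"`` for raw TPM input, ``"log2"`` after the log2(TPM+1)
        transform, ``"corrected"`` after housekeeping correction.  All three
        stages are non-negative.
    """

    data: pd.DataFrame
    stage: str = "tpm"

    _STAGES = ("tpm", "log2", "corrected")

    def __post_init__(self) -> None:
        if self.stage not in self._STAGES:
            raise ValidationError(
                f"unknown stage {self.stage!r}; expected one of {self._STAGES}"
            )
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValidationError("expression matrix needs >= 1 gene and >= 1 sample")
        _check_unique([str(g) for g in self.data.index], "gene")
        _check_unique([str(s) for s in self.data.columns], "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix must be numeric")
        if np.isnan(values).any():
            raise ValidationError("expression matrix contains missing values")
        if (values < 0).any():
            gene, sample = self._first_negative()
            raise ValidationError(
                f"negative expression value at gene {gene!r}, sample {sample!r} "
                f"(stage={self.stage} requires values >= 0)"
            )

    def _first_negative(self) -> tuple[str, str]:
        mask = self.data.to_numpy() < 0
        i, j = np.argwhere(mask)[0]
        return str(self.data.index[i]), str(self.data.columns[j])

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class MarkerGeneSets:
    """Named state → marker gene list mapping.

    State names are validated against :data:`CANONICAL_STATES`.  With
    ``strict=True`` (default) an unknown state name is an error; with
    ``strict=False`` it is kept with a warning, which allows user-defined
    signatures to flow through the same scoring machinery.
    """

    entries: dict[str, list[str]]
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("marker gene sets are empty")
        cleaned: dict[str, list[str]] = {}
        for state, genes in self.entries.items():
            state = state.strip()
            if state not in CANONICAL_STATES:
                if self.strict:
                    raise ValidationError(
                        f"unknown state name {state!r}; canonical names are "
                        f"{list(CANONICAL_STATES)} (pass strict=False to allow)"
                    )
                warnings.warn(f"non-canonical state name kept: {state!r}")
            unique = list(dict.fromkeys(g.strip() for g in genes if g.strip()))
            if len(unique) < len([g for g in genes if g.strip()]):
                warnings.warn(f"duplicate marker genes removed in state {state!r}")
            if len(unique) < 2:
                raise ValidationError(
                    f"state {state!r} has {len(unique)} marker gene(s); "
                    "scoring requires at least 2"
                )
            cleaned[state] = unique
        self.entries = cleaned

    @property
    def states(self) -> list[str]:
        return list(self.entries)

    def n_markers(self, state: str) -> int:
        return len(self.entries[state])

    def __getitem__(self, state: str) -> list[str]:
        return self.entries[state]

    def __contains__(self, state: str) -> bool:
        return state in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class HousekeepingList:
    """A set of housekeeping genes used for cross-sample correction."""

    genes: list[str]

    def __post_init__(self) -> None:
        cleaned = list(dict.fromkeys(g.strip() for g in self.genes if g.strip()))
        if not cleaned:
            raise ValidationError("housekeeping list is empty")
        if len(cleaned) < len([g for g in self.genes if g.strip()]):
            warnings.warn("duplicate housekeeping genes removed")
        self.genes = cleaned

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class ReferenceSpectrum:
    """Gene × state reference expression on the TPM scale.

    The spectrum caps each marker's contribution to the final score through
    the percentage weight: a marker whose sample expression falls below its
    reference value contributes proportionally less.  A log2(TPM+1) view is
    computed on demand for scale-consistent comparison with corrected
    expression values.
    """

    data: pd.DataFrame  # genes × states, TPM scale
    _log2_cache: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValidationError("reference spectrum needs >= 1 gene and >= 1 state")
        _check_unique([str(g) for g in self.data.index], "gene")
        _check_unique([str(s) for s in self.data.columns], "state")
        values = self.data.to_numpy()
        if np.isnan(values).any():
            raise ValidationError("reference spectrum contains missing values")
        if (values < 0).any():
            raise ValidationError("reference spectrum contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def states(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def log2(self) -> pd.DataFrame:
        """log2(TPM + 1) view of the spectrum (cached)."""
        if self._log2_cache is None:
            self._log2_cache = np.log2(self.data + 1.0)
        return self._log2_cache

    def require_state(self, state: str) -> pd.Series:
        if state not in self.data.columns:
            raise ValidationError(
                f"reference spectrum has no column for state {state!r}"
            )
        return self.data[state]


@dataclass
class TCSSResult:
    """State × sample score matrix with scoring provenance.

    Attributes
    ----------
    scores
        DataFrame with one row per scored state (canonical order) and one
        column per sample.  Under ``mode="unit"`` every value lies in [0, 1].
    effective_markers
        Per state, the number of marker genes actually found in the input
        matrix and used for scoring.
    seed
        Background-sampling seed.
    mode
        ``"unit"`` or ``"printed"`` normalization.
    warnings
        Messages accumulated during scoring (skipped states, shrunk draws,
        absent markers).
    """

    scores: pd.DataFrame
    effective_markers: dict[str, int]
    seed: int
    mode: str
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode == "unit":
            values = self.scores.to_numpy()
            if values.size and ((values < 0) | (values > 1)).any():
                raise ValidationError("unit-mode scores must lie in [0, 1]")

    @property
    def states(self) -> list[str]:
        return [str(s) for s in self.scores.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.scores.columns]

    def save(self, path: str | Path, delimiter: str = "\t") -> None:
        """Write the score table plus a JSON provenance sidecar.

        The sidecar (``<path>.json``) records seed, mode, effective marker
        counts and accumulated warnings so a score table is auditable on its
        own.
        """
        path = Path(path)
        self.scores.to_csv(path, sep=delimiter, float_format="%.17g")
        sidecar = {
            "seed": self.seed,
            "mode": self.mode,
            "effective_markers": self.effective_markers,
            "warnings": self.warnings,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: Path, delimiter: str) -> pd.DataFrame:
    header = path.read_text().splitlines()
    if not header:
        raise ValidationError(f"{path}: empty file")
    sample_ids = [c.strip() for c in header[0].split(delimiter)[1:]]
    _check_unique(sample_ids, "column")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = sample_ids
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    # numpy's string parsing is correctly rounded, so "%.17g" output
    # round-trips to the exact same float64
    return df.astype(np.float64)


def read_expression_matrix(
    path: str | Path, delimiter: str | None = None
) -> ExpressionMatrix:
    """Read a TPM gene × sample matrix from TSV (default) or CSV.

    Duplicate gene rows are collapsed by summation (duplicates in TPM tables
    usually arise from transcript-to-gene collapse, and summation preserves
    abundance); a warning reports how many rows were merged.  Missing values
    and non-numeric cells are rejected with the offending row/column named.
    """
    path = Path(path)
    df = _read_table(path, _infer_delimiter(path, delimiter))
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        df = df.groupby(level=0, sort=False).sum()
        warnings.warn(
            f"{path}: {n_dup} duplicate gene row(s) collapsed by summation"
        )
    return ExpressionMatrix(df, stage="tpm")


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    m.data.to_csv(path, sep=_infer_delimiter(path, delimiter), float_format="%.17g")


def read_gene_sets(path: str | Path, strict: bool = True) -> MarkerGeneSets:
    """Read marker gene sets from a GMT file or a JSON ``{state: [genes]}``.

    GMT lines are ``name <TAB> description <TAB> gene1 <TAB> ...``; the
    description field is ignored.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
        if not isinstance(entries, dict):
            raise ValidationError(f"{path}: JSON gene sets must be an object")
        return MarkerGeneSets({str(k): list(v) for k, v in entries.items()}, strict=strict)
    entries = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        entries[fields[0]] = fields[2:]
    return MarkerGeneSets(entries, strict=strict)


def write_gene_sets(sets: MarkerGeneSets, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(sets.entries, indent=2) + "\n")
        return
    lines = [
        "\t".join([state, "na", *genes]) for state, genes in sets.entries.items()
    ]
    path.write_text("\n".join(lines) + "\n")


def read_housekeeping(path: str | Path) -> HousekeepingList:
    """Read a housekeeping gene list: one gene per line, ``#`` comments."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return HousekeepingList(genes)


def write_housekeeping(hk: HousekeepingList, path: str | Path) -> None:
    Path(path).write_text("\n".join(hk.genes) + "\n")


def read_reference_spectrum(
    path: str | Path, delimiter: str | None = None
) -> ReferenceSpectrum:
    """Read a gene × state reference spectrum (TPM scale) from TSV/CSV."""
    path = Path(path)
    df = _read_table(path, _infer_delimiter(path, delimiter))
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene rows in reference spectrum")
    return ReferenceSpectrum(df)


def write_reference_spectrum(
    ref: ReferenceSpectrum, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    ref.data.to_csv(path, sep=_infer_delimiter(path, delimiter), float_format="%.17g")
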