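"""Pre-scoring normalization: log2(TPM+1) and housekeeping-gene correction.

The correction rescales each sample so that all samples share the same mean
housekeeping-gene expression, making rank comparisons and reference-spectrum
comparisons meaningful across samples with different global expression
levels.  It is applied on the log2 scale, after the log transform.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .core_io import ExpressionMatrix, HousekeepingList, ValidationError

__all__ = ["log2_transform", "housekeeping_correct"]

logger = logging.getLogger(__name__)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every TPM value v with log2(v + 1).

    Raises
    ------
    ValidationError
        If ``m`` is not at stage ``"tpm"``.
    """
    if m.stage != "tpm":
        raise ValidationError(f"log2_transform expects stage='tpm', got {m.stage!r}")
    return ExpressionMatrix(np.log2(m.data + 1.0), stage="log2")


def housekeeping_correct(
    m: ExpressionMatrix,
    hk: HousekeepingList,
    min_hk: int = 50,
) -> ExpressionMatrix:
    """Rescale each sample to equalize mean housekeeping expression.

    For sample i with housekeeping mean HK̄_i, every value in that sample's
    column is multiplied by (mean over samples of HK̄) / HK̄_i.  After the
    correction every sample's housekeeping mean equals the pre-correction
    global mean, and applying the correction a second time is the identity.

    Parameters
    ----------
    m
        log2-stage matrix (an already-corrected matrix is also accepted:
        the correction is idempotent, so a second pass is the identity).
    hk
        Housekeeping gene list; only genes present in ``m`` are used.  Absent
        genes are ignored with a warning giving the count.
    min_hk
        Minimum number of housekeeping genes that must be present; a
        correction based on a handful of genes is refused.

    Raises
    ------
    ValidationError
        Wrong stage, fewer than ``min_hk`` housekeeping genes present, or a
        sample whose housekeeping mean is zero (the scale factor would be
        infinite).
    """
    if m.stage not in ("log2", "corrected"):
        raise ValidationError(
            f"housekeeping_correct expects stage='log2' or 'corrected', "
            f"got {m.stage!r}"
        )
    present = [g for g in hk.genes if g in m.data.index]
    n_absent = len(hk.genes) - len(present)
    if n_absent:
        warnings.warn(
            f"{n_absent} housekeeping gene(s) absent from the matrix ignored"
        )
    if len(present) < min_hk:
        raise ValidationError(
            f"only {len(present)} housekeeping gene(s) present in the matrix; "
            f"need at least {min_hk}"
        )
    hk_means = m.data.loc[present].mean(axis=0)
    zero = hk_means[hk_means <= 0]
    if len(zero):
        raise ValidationError(
            f"sample {zero.index[0]!r} has zero mean housekeeping expression"
        )
    factors = hk_means.mean() / hk_means
    logger.info(
        "housekeeping correction: %d genes, factors %s",
        len(present),
        ", ".join(f"{s}={f:.6g}" for s, f in factors.items()),
    )
    return ExpressionMatrix(m.data * factors, stage="corrected")
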