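"""Normalization and standardization shared by signature building and deconvolution.

Quantile normalization forces every sample (column) to share one empirical
distribution: the across-sample mean of order statistics.  Within-column rank
order is preserved; tied values receive the mean of the target quantiles they
span, which keeps the transform deterministic and symmetric.  z-scoring uses
the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .io_formats import ExpressionMatrix, SignatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["quantile_normalize", "zscore", "align_genes"]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Map every column onto the mean-of-order-statistics distribution.

    A single-column matrix is returned unchanged (with a warning): there is
    nothing to normalize against.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization of a single sample is the identity")
        return ExpressionMatrix(matrix.data.copy())
    values = matrix.values.astype(float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = _map_to_target(values[:, j], target)
    frame = matrix.data.copy()
    frame.iloc[:, :] = out
    return ExpressionMatrix(frame)


def _map_to_target(column: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Assign target order statistics by rank; ties get the mean of the
    target values their run spans."""
    order = np.argsort(column, kind="mergesort")
    ranked = column[order]
    assigned = target.copy()
    # average target over runs of tied input values
    i = 0
    n = len(ranked)
    while i < n:
        j = i + 1
        while j < n and ranked[j] == ranked[i]:
            j += 1
        if j - i > 1:
            assigned[i:j] = target[i:j].mean()
        i = j
    out = np.empty_like(column, dtype=float)
    out[order] = assigned
    return out


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd, n-1 denominator).

    Raises on vectors shorter than 2 or with no variance, where the
    standardization is undefined.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("zscore needs at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zscore undefined for a constant vector")
    return (values - values.mean()) / sd


def align_genes(
    signature: SignatureMatrix, mixture: ExpressionMatrix
) -> tuple[SignatureMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in signature order.

    The overlap must be at least as large as the number of classes or the
    linear system M = S F becomes underdetermined.
    """
    mixture_genes = set(mixture.gene_ids)
    shared = [g for g in signature.gene_ids if g in mixture_genes]
    if not shared:
        raise ValueError("signature and mixture share no genes")
    r = len(signature.class_labels)
    if len(shared) < r:
        raise ValueError(
            f"only {len(shared)} shared genes for {r} classes: system underdetermined"
        )
    logger.info(
        "gene overlap: %d of %d signature genes present in mixtures",
        len(shared),
        len(signature.gene_ids),
    )
    sig = SignatureMatrix(signature.data.loc[shared].copy(), dict(signature.meta))
    mix = ExpressionMatrix(mixture.data.loc[shared].copy())
    return sig, mix
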