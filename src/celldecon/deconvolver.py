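"""Proportion estimation by linear-kernel nu-support-vector regression.

Each mixture column m is modeled as m ~ S f: the signature genes are the
training points, the r signature columns their features, and the fitted
hyperplane normal w (length r) is the raw proportion estimate.  nu-SVR is
used because nu bounds the fraction of support vectors — the genes that
actually pin down the fit — making the regression robust to genes whose
expression in the mixture departs from the linear mixing model.

Per sample the model is fitted at every nu in the grid (default
{0.25, 0.5, 0.75}); the fit minimizing the RMSE between the standardized
mixture and S x w over the signature genes wins (ties: smallest nu).  The
winning raw coefficients are post-processed into proportions: negatives are
clipped to zero and the rest normalized to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .io_formats import ExpressionMatrix, ProportionTable, SignatureMatrix
from .preprocess import align_genes, quantile_normalize, zscore

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionConfig",
    "FitResult",
    "fit_single_nu",
    "select_nu",
    "clip_and_normalize",
    "deconvolve",
]


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Solver settings.

    nu_grid: candidate nu values, each in (0, 1].
    cost: SVR penalty constant C (fixed, exposed for transparency).
    tol: solver stopping tolerance.
    zscore_scope: how the signature matrix is standardized — "global"
        (one mean/sd over all entries, preserving relative magnitudes
        across columns) or "per-column" (each class column separately).
        Mixture columns are always standardized over their signature-gene
        entries.
    """

    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    cost: float = 1.0
    tol: float = 1e-6
    zscore_scope: str = "global"

    def __post_init__(self) -> None:
        if not self.nu_grid:
            raise ValueError("nu_grid must be non-empty")
        if any(not (0 < nu <= 1) for nu in self.nu_grid):
            raise ValueError("every nu must lie in (0, 1]")
        if self.zscore_scope not in ("global", "per-column"):
            raise ValueError(f"unknown zscore scope {self.zscore_scope!r}")
        if self.cost <= 0 or self.tol <= 0:
            raise ValueError("cost and tol must be positive")


@dataclass
class FitResult:
    """Outcome of nu selection for one mixture sample."""

    raw_coefficients: np.ndarray  # length r, signed
    proportions: np.ndarray  # clipped, sums to 1
    chosen_nu: float
    reconstruction_rmse: float
    reconstruction_correlation: float
    intercept: float = 0.0
    per_nu_rmse: dict[float, float] = field(default_factory=dict)


def _fit(
    s_std: np.ndarray, m_std: np.ndarray, nu: float, cost: float, tol: float
) -> tuple[np.ndarray, float]:
    s_std = np.asarray(s_std, dtype=float)
    m_std = np.asarray(m_std, dtype=float).ravel()
    if s_std.shape[0] != m_std.size:
        raise ValueError("signature and mixture gene counts differ")
    if s_std.shape[0] < s_std.shape[1]:
        raise ValueError("fewer genes than classes: underdetermined")
    model = NuSVR(kernel="linear", nu=nu, C=cost, tol=tol)
    model.fit(s_std, m_std)
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def fit_single_nu(
    s_std: np.ndarray,
    m_std: np.ndarray,
    nu: float,
    cost: float = 1.0,
    tol: float = 1e-6,
) -> np.ndarray:
    """Raw coefficient vector (length r) of a linear-kernel nu-SVR of the
    standardized mixture on the rows of the standardized signature."""
    return _fit(s_std, m_std, nu, cost, tol)[0]


def clip_and_normalize(raw_coefficients: np.ndarray) -> np.ndarray:
    """Zero out negative coefficients and rescale the rest to sum to 1."""
    raw = np.asarray(raw_coefficients, dtype=float)
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        raise ValueError("all coefficients non-positive: proportions undefined")
    return clipped / total


def select_nu(
    s_std: np.ndarray,
    m_std: np.ndarray,
    config: DeconvolutionConfig = DeconvolutionConfig(),
) -> FitResult:
    """Fit at every nu on the grid and keep the lowest-RMSE model.

    RMSE is measured between the standardized mixture and the fitted model
    S x w + b over the signature genes, using the raw (pre-clipping)
    coefficients; ties go to the smallest nu.  The winning coefficients are
    then clipped and normalized into proportions.
    """
    m_std = np.asarray(m_std, dtype=float).ravel()
    per_nu_rmse: dict[float, float] = {}
    best: tuple[float, float, np.ndarray, float] | None = None  # (rmse, nu, coef, b)
    errors: dict[float, str] = {}
    for nu in sorted(config.nu_grid):
        try:
            coef, intercept = _fit(s_std, m_std, nu, config.cost, config.tol)
        except Exception as exc:  # propagate only if every nu fails
            errors[nu] = str(exc)
            continue
        reconstruction = np.asarray(s_std) @ coef + intercept
        rmse = float(np.sqrt(np.mean((m_std - reconstruction) ** 2)))
        per_nu_rmse[nu] = rmse
        if best is None or rmse < best[0]:
            best = (rmse, nu, coef, intercept)
    if best is None:
        raise RuntimeError(f"nu-SVR failed for every nu on the grid: {errors}")
    rmse, nu, coef, intercept = best
    reconstruction = np.asarray(s_std) @ coef + intercept
    if np.std(reconstruction) == 0 or np.std(m_std) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(m_std, reconstruction)[0, 1])
    return FitResult(
        raw_coefficients=coef,
        proportions=clip_and_normalize(coef),
        chosen_nu=nu,
        reconstruction_rmse=rmse,
        reconstruction_correlation=corr,
        intercept=intercept,
        per_nu_rmse=per_nu_rmse,
    )


def _standardize_signature(values: np.ndarray, scope: str) -> np.ndarray:
    if scope == "global":
        flat = zscore(values.ravel())
        return flat.reshape(values.shape)
    return np.column_stack([zscore(values[:, k]) for k in range(values.shape[1])])


def deconvolve(
    mixtures: ExpressionMatrix,
    signature: SignatureMatrix,
    config: DeconvolutionConfig = DeconvolutionConfig(),
) -> ProportionTable:
    """Estimate cell-type fractions for every mixture column.

    Pipeline per the linear mixing model: quantile-normalize the mixture
    set, restrict to the genes shared with the signature, standardize both
    sides, then solve each sample independently by nu-SVR with model
    selection over the nu grid.
    """
    mixtures = quantile_normalize(mixtures)
    signature, mixtures = align_genes(signature, mixtures)
    s_std = _standardize_signature(signature.values, config.zscore_scope)
    fractions = {}
    diagnostics = {}
    for sample in mixtures.sample_ids:
        column = mixtures.data[sample].to_numpy()
        try:
            m_std = zscore(column)
            fit = select_nu(s_std, m_std, config)
        except Exception as exc:
            raise RuntimeError(f"deconvolution failed for sample {sample!r}: {exc}") from exc
        fractions[sample] = fit.proportions
        diagnostics[sample] = {
            "chosen_nu": fit.chosen_nu,
            "reconstruction_rmse": fit.reconstruction_rmse,
            "reconstruction_correlation": fit.reconstruction_correlation,
        }
    fraction_frame = pd.DataFrame.from_dict(
        fractions, orient="index", columns=signature.class_labels
    )
    diag_frame = pd.DataFrame.from_dict(diagnostics, orient="index")
    return ProportionTable(fraction_frame, diag_frame)
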