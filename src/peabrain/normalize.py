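"""Expression normalization: rank-based inverse normal transform, covariate
residualization, and per-gene mean abundance."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rank_inverse_normal", "residualize", "mean_abundance",
           "filter_expressed"]


def rank_inverse_normal(x) -> np.ndarray:
    """Map values to normal quantiles of their tie-averaged ranks:
    ``Phi^-1((rank - 0.5) / n)``.

    Monotone in the input and equivariant under permutation.  All-equal
    input has undefined ranks for normalization and raises.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if len(x) < 2:
        raise ValueError("need at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if np.all(x == x[0]):
        raise ValueError("all values equal; rank transform undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def filter_expressed(expr: pd.DataFrame, min_fraction: float = 0.5,
                     threshold: float = 0.0) -> pd.DataFrame:
    """Keep genes with expression above ``threshold`` in at least
    ``min_fraction`` of samples (the non-zero-in-half-of-samples filter)."""
    frac = (expr.values > threshold).mean(axis=1)
    return expr.loc[frac >= min_fraction]


def _drop_collinear(design: np.ndarray) -> np.ndarray:
    """Drop columns that are linearly dependent on earlier ones (QR-based)."""
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-8 * max(1.0, diag.max())
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} collinear design column(s)")
    return design[:, keep]


def residualize(expr: pd.DataFrame, covariates=None,
                pc_variance_target: float = 0.55) -> pd.DataFrame:
    """Residualize each gene on covariates plus top expression PCs, then
    rank-inverse-normal transform per gene.

    PCs are computed on the covariate-residualized expression matrix and the
    smallest number of leading components whose cumulative explained variance
    reaches ``pc_variance_target`` is added to the design.  A target of 0
    disables the PC block (covariate-only residualization).  An intercept is
    always included.
    """
    if not 0 <= pc_variance_target <= 1:
        raise ValueError("pc_variance_target must be in [0, 1]")
    values = expr.values.astype(float)
    n_genes, n_samples = values.shape
    design = [np.ones((n_samples, 1))]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n_samples:
            raise ValueError("covariate rows do not align with samples")
        design.append(cov)
    X = _drop_collinear(np.hstack(design))

    def _resid(Y, X):
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        return Y - (X @ beta).T

    resid0 = _resid(values, X)
    # PCs of the covariate-residualized matrix (samples as observations)
    centred = resid0 - resid0.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centred.T, full_matrices=False)
    var = s ** 2
    if pc_variance_target == 0:
        n_pc = 0
    elif var.sum() > 0:
        explained = np.cumsum(var) / var.sum()
        n_pc = int(np.searchsorted(explained, pc_variance_target - 1e-12) + 1)
        n_pc = min(n_pc, len(s))
    else:
        n_pc = 0
    if n_pc > 0:
        pcs = u[:, :n_pc] * s[:n_pc]
        X = _drop_collinear(np.hstack([X, pcs]))
    resid = _resid(values, X)
    out = np.vstack([rank_inverse_normal(row) for row in resid])
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def mean_abundance(expr: pd.DataFrame) -> pd.Series:
    """Average expression per gene across samples, then rank-inverse-normal
    transform across genes (the Stage-1 training target)."""
    if expr.shape[1] < 1:
        raise ValueError("need at least one sample")
    means = expr.values.astype(float).mean(axis=1)
    return pd.Series(rank_inverse_normal(means), index=expr.index,
                     name="mean_abundance")
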