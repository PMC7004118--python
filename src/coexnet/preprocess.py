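"""Expression QC chain: log transform, quantile normalization, covariate
residualization.

The stages are applied in the fixed order log -> quantile -> residualize.
Covariate correction uses per-gene ordinary least squares: each gene is
regressed on the (one-hot encoded) covariate design and replaced by its
residuals plus the gene's grand mean, which removes all linear covariate
signal while preserving per-gene means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import ExpressionMatrix, ValidationError

logger = logging.getLogger("coexnet")


@dataclass
class CovariateTable:
    """Per-sample covariates: categorical (batch, center, ...) and numeric (age)."""

    sample_ids: list[str]
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != len(self.covariates):
            raise ValidationError("covariate rows do not match sample ids")
        for col in self.covariates.columns:
            s = self.covariates[col]
            if not pd.api.types.is_numeric_dtype(s):
                singles = s.value_counts()
                for level in singles.index[singles == 1]:
                    logger.warning("covariate %r level %r has a single sample", col, level)

    def design_matrix(self) -> np.ndarray:
        """Intercept + one-hot categoricals (first level dropped) + numerics."""
        parts = [np.ones((len(self.sample_ids), 1))]
        for col in self.covariates.columns:
            s = self.covariates[col]
            if pd.api.types.is_numeric_dtype(s):
                parts.append(s.to_numpy(float)[:, None])
            else:
                dummies = pd.get_dummies(s.astype(str), drop_first=True)
                if dummies.shape[1]:
                    parts.append(dummies.to_numpy(float))
        return np.hstack(parts)


def log_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """v -> log2(v + 1) on RPKM-like nonnegative values."""
    if x.stage_tag != "raw":
        raise ValidationError(f"log_transform expects stage_tag raw, got {x.stage_tag}")
    if (x.values < 0).any():
        raise ValidationError("negative values: input is not RPKM-like")
    return x.with_values(np.log2(x.values + 1.0), "logged")


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the across-sample mean of order statistics.

    Ties within a column receive the mean of the reference values at the
    tied ranks, so the map is well defined and idempotent.
    """
    if x.stage_tag not in ("logged", "normalized"):
        raise ValidationError(f"quantile_normalize expects logged values, got {x.stage_tag}")
    v = x.values
    order = np.argsort(v, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(v, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(v)
    n = v.shape[0]
    for j in range(v.shape[1]):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # average reference values over runs of tied input values
        start = 0
        for end in range(1, n + 1):
            if end == n or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = assigned[start:end].mean()
                start = end
        out[order[:, j], j] = assigned
    return x.with_values(out, "normalized")


def residualize(x: ExpressionMatrix, cov: CovariateTable) -> ExpressionMatrix:
    """Per-gene OLS residuals on the covariate design plus the gene grand mean.

    Collinear design columns are dropped with a warning (rank-revealing QR).
    """
    if x.stage_tag != "normalized":
        raise ValidationError(f"residualize expects stage_tag normalized, got {x.stage_tag}")
    if cov.sample_ids != x.sample_ids:
        raise ValidationError("covariate sample ids do not match expression matrix")
    X = cov.design_matrix()
    X = _drop_collinear(X)
    Y = x.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T + x.values.mean(axis=1, keepdims=True)
    return x.with_values(out, "residualized")


def drop_zero_variance(x: ExpressionMatrix, tol: float = 1e-12) -> ExpressionMatrix:
    """Remove genes with (numerically) zero variance; correlation is undefined
    for them, so they are excluded before the correlation screen."""
    sd = x.values.std(axis=1)
    keep = sd > tol
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance genes before screening", n_dropped)
    genes = [g for g, k in zip(x.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(x.sample_ids), x.values[keep], x.stage_tag,
                            dict(x.provenance))


def _drop_collinear(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * max(diag[0], 1.0)).sum())
    if rank < X.shape[1]:
        logger.warning("dropped %d collinear design columns", X.shape[1] - rank)
        keep = sorted(piv[:rank])
        return X[:, keep]
    return X
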