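"""Surrogate variable analysis for technical batch structure.

Estimates latent covariates from the methylation matrix while protecting
the study design (intercept, case status, age at measurement) from
absorption, so the surrogate variables capture technical structure rather
than the exposure itself. Two pieces:

* :func:`estimate_n_sv` — permutation (parallel-analysis) estimate of how
  many surrogate variables the residual space supports: each probe's
  residuals are permuted independently to build a null spectrum, and the
  count of leading singular values exceeding the null quantile is returned.
* :func:`compute_svs` — two-step iteratively reweighted SVA: residualise on
  the protected design, take leading right-singular vectors, reweight probes
  by the posterior probability of being associated with the surrogate
  structure but not with the protected variables, and repeat.

Missing beta-values are mean-imputed per probe *for this step only*; the
scan itself stays complete-case per probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SurrogateVariableSet", "estimate_n_sv", "compute_svs"]


@dataclass
class SurrogateVariableSet:
    n_sv: int
    data: pd.DataFrame  # samples x sv1..svK; empty with 0 columns when n_sv == 0
    method: str = "irw-sva"
    seed: int | None = None

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def _impute_row_means(matrix: pd.DataFrame) -> np.ndarray:
    y = matrix.to_numpy(dtype=float, copy=True)
    if np.isnan(y).any():
        row_mean = np.nanmean(y, axis=1)
        idx = np.where(np.isnan(y))
        y[idx] = row_mean[idx[0]]
    return y


def _design_array(design: pd.DataFrame | np.ndarray) -> np.ndarray:
    x = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return x


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    # y: probes x samples, x: samples x k
    q, _ = np.linalg.qr(x)
    return y - (y @ q) @ q.T


def estimate_n_sv(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    n_permutations: int = 20,
    seed: int = 0,
    quantile: float = 0.95,
) -> int:
    """Parallel-analysis estimate of the number of surrogate variables.

    Singular values of the design-residualised matrix are compared, rank by
    rank, against the spectrum of row-permuted residuals; the estimate is
    the number of *leading consecutive* ranks whose observed singular value
    exceeds the permutation quantile.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = _design_array(design)
    n = matrix.shape[1]
    if x.shape[1] >= n:
        raise ValueError("design has at least as many columns as samples")
    y = _impute_row_means(matrix)
    r = _residualize(y, x)
    observed = np.linalg.svd(r, compute_uv=False)

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, observed.size))
    for b in range(n_permutations):
        null[b] = np.linalg.svd(rng.permuted(r, axis=1), compute_uv=False)
    thresholds = np.quantile(null, quantile, axis=0)

    n_sv = 0
    max_rank = min(r.shape) - x.shape[1]
    for k in range(max(max_rank, 0)):
        if observed[k] > thresholds[k]:
            n_sv += 1
        else:
            break
    return n_sv


def _f_pvalues(y: np.ndarray, x_full: np.ndarray, x_reduced: np.ndarray) -> np.ndarray:
    """Per-probe nested-model F-test p-values (vectorised)."""
    n = y.shape[1]
    k1, k0 = x_full.shape[1], x_reduced.shape[1]
    if k1 == k0:  # nothing to test: nested models coincide
        return np.ones(y.shape[0])
    rss1 = (_residualize(y, x_full) ** 2).sum(axis=1)
    rss0 = (_residualize(y, x_reduced) ** 2).sum(axis=1)
    df1, df2 = k1 - k0, n - k1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df1) / (rss1 / df2)
    f = np.where(rss1 <= 0, np.inf, f)
    return stats.f.sf(np.clip(f, 0, None), df1, df2)


def _lfdr(p: np.ndarray) -> np.ndarray:
    """Local false-discovery rate from a p-value vector.

    Probit-transform, kernel density estimate of the mixture, Storey-type
    pi0 at lambda = 0.5. Clipped to [0, 1].
    """
    p = np.clip(np.asarray(p, float), 1e-15, 1 - 1e-15)
    x = stats.norm.ppf(p)
    pi0 = min(1.0, 2.0 * float(np.mean(p > 0.5)))
    if np.allclose(x, x[0]) or float(np.var(x)) < 1e-12:
        return np.full_like(p, min(1.0, pi0))
    try:
        kde = stats.gaussian_kde(x)
    except np.linalg.LinAlgError:
        return np.full_like(p, min(1.0, pi0))
    f = np.maximum(kde(x), 1e-12)
    lfdr = pi0 * stats.norm.pdf(x) / f
    return np.clip(lfdr, 0.0, 1.0)


def compute_svs(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    n_sv: int,
    max_iterations: int = 5,
    protected: list[str] | None = None,
) -> SurrogateVariableSet:
    """Iteratively reweighted SVA.

    Parameters
    ----------
    matrix : probes x samples beta matrix (missing cells mean-imputed here).
    design : samples x k protected design (intercept, case status, age, ...).
    n_sv : number of surrogate variables to return (>= 1).
    max_iterations : reweighting iterations.
    protected : names of the design columns whose signal the SVs must not
        absorb; defaults to every non-intercept column.

    Returns
    -------
    SurrogateVariableSet with zero-mean, mutually orthogonal columns.
    """
    if n_sv < 1:
        raise ValueError("n_sv must be >= 1")
    x = _design_array(design)
    n, k = x.shape
    if n_sv >= n - k:
        raise ValueError(f"n_sv={n_sv} >= rank of residual space ({n - k})")

    y = _impute_row_means(matrix)
    resid = _residualize(y, x)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    svs = vt[:n_sv].T

    if isinstance(design, pd.DataFrame):
        cols = list(design.columns)
        if protected is None:
            protected = [c for c in cols if c.lower() not in ("intercept", "const")]
        keep_reduced = [i for i, c in enumerate(cols) if c not in protected]
    else:
        keep_reduced = [0]
    x_reduced = x[:, keep_reduced] if keep_reduced else np.ones((n, 1))

    yc = y - y.mean(axis=1, keepdims=True)
    for _ in range(max_iterations):
        x_sv = np.column_stack([x, svs])
        x_red_sv = np.column_stack([x_reduced, svs])
        # associated with the surrogate structure ...
        p_gam = _f_pvalues(y, x_sv, x)
        # ... but not with the protected variables
        p_b = _f_pvalues(y, x_sv, x_red_sv)
        weights = (1.0 - _lfdr(p_gam)) * _lfdr(p_b)
        _, _, vt = np.linalg.svd(yc * weights[:, None], full_matrices=False)
        svs = vt[:n_sv].T

    # enforce the output contract: zero-mean, orthogonal, deterministic sign
    svs = svs - svs.mean(axis=0, keepdims=True)
    q, rr = np.linalg.qr(svs)
    svs = q * np.sign(np.diag(rr))[None, :]
    flip = np.sign(svs[np.argmax(np.abs(svs), axis=0), np.arange(n_sv)])
    flip[flip == 0] = 1.0
    svs = svs * flip[None, :]

    index = matrix.columns if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(n)
    data = pd.DataFrame(svs, index=index, columns=[f"sv{i + 1}" for i in range(n_sv)])
    return SurrogateVariableSet(n_sv=n_sv, data=data)
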