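"""Projection PCA: fit on a modern reference panel, place low-coverage
samples onto the fitted axes by least squares over their observed sites.

The fit standardizes dosages per site (centre by the mean dosage, scale
by ``sqrt(p(1-p))`` with ``p`` the dosage-based allele frequency) and
eigendecomposes the individual x individual covariance. Low-coverage or
pseudo-haploid samples are then projected with the restricted-loading
normal equations, using only their non-missing sites, so that
missingness biases the placement as little as possible. An optional
shrinkage correction rescales projected scores by per-PC factors
calibrated with leave-one-out projection of the reference individuals,
countering the well-known shrinkage of out-of-sample projections toward
the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix, HaploidMatrix, VariantTable

__all__ = ["PcaModel", "fit_pca", "project_lsq", "loo_shrink_factors"]


@dataclass
class PcaModel:
    site_means: np.ndarray       # per-site mean dosage
    site_scales: np.ndarray      # per-site sqrt(p(1-p)) scale
    loadings: np.ndarray         # sites x k, orthonormal columns
    eigenvalues: np.ndarray      # k, non-increasing
    pct_variance: np.ndarray     # k, percent of total variance
    shrink_factors: np.ndarray | None = None   # per-PC projection rescale

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def _standardize(values: np.ndarray, means: np.ndarray,
                 scales: np.ndarray) -> np.ndarray:
    x = (values - means) / scales
    return x


def fit_pca(modern: GenotypeMatrix, variants: VariantTable | None, k: int):
    """Fit a PCA on a (filtered, LD-pruned) modern diploid panel.

    Missing dosages are mean-imputed per site before standardization.
    Returns ``(PcaModel, scores)`` where ``scores`` is individuals x k.
    The sign of each component is fixed so its largest-magnitude loading
    is positive, making results deterministic.
    """
    values = modern.dosages.astype(float)
    miss = modern.dosages == MISSING
    if miss.all(axis=0).any():
        raise ValueError("all-missing sites present; filter before fitting")
    col_mean = np.where(miss, np.nan, values).copy()
    col_mean = np.nanmean(col_mean, axis=0)
    values = np.where(miss, col_mean, values)
    p_hat = col_mean / 2.0
    scale = np.sqrt(np.maximum(p_hat * (1.0 - p_hat), 0.0))
    if (scale == 0).any():
        raise ValueError("monomorphic sites present; filter before fitting")
    x = _standardize(values, col_mean, scale)
    n_ind = x.shape[0]
    if k > min(x.shape) - 1:
        raise ValueError(f"k={k} exceeds the rank bound {min(x.shape) - 1}")
    # SVD of the standardized matrix: scores = U S, loadings = V.
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float(np.sum(s ** 2))
    loadings = vt[:k].T
    eigenvalues = (s[:k] ** 2) / n_ind
    # sign convention: largest-|loading| entry positive per component
    for c in range(k):
        jmax = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[jmax, c] < 0:
            loadings[:, c] = -loadings[:, c]
            u[:, c] = -u[:, c]
    scores = u[:, :k] * s[:k]
    pct = (s[:k] ** 2) / total_var * 100.0
    model = PcaModel(col_mean, scale, loadings, eigenvalues, pct)
    return model, scores


def _sample_dosage(values: np.ndarray, haploid: bool) -> np.ndarray:
    """Map calls to the diploid dosage scale (haploid 0/1 -> 0/2)."""
    out = values.astype(float)
    if haploid:
        out = out * 2.0
    out[values == MISSING] = np.nan
    return out


def project_lsq(sample, model: PcaModel, shrink: bool = False) -> np.ndarray:
    """Project one sample (or a matrix of samples) onto fitted components.

    Solves the least-squares problem restricted to the sample's
    non-missing sites: ``argmin_beta || x_obs - L_obs beta ||``. A
    complete-data modern individual projects exactly onto its fit-time
    score. Accepts a 1-D dosage/call array, a :class:`HaploidMatrix`, or
    a :class:`GenotypeMatrix`; returns scores of shape (k,) or (n, k).
    With ``shrink=True`` the model's calibrated per-PC factors are
    applied (see :func:`loo_shrink_factors`).
    """
    haploid = isinstance(sample, HaploidMatrix)
    if isinstance(sample, (HaploidMatrix, GenotypeMatrix)):
        values = sample.values
    else:
        values = np.asarray(sample)
    single = values.ndim == 1
    if single:
        values = values[None, :]
    dosage = _sample_dosage(values, haploid)
    out = np.empty((dosage.shape[0], model.k))
    for i in range(dosage.shape[0]):
        obs = ~np.isnan(dosage[i])
        if not obs.any():
            raise ValueError("sample has no observed sites")
        x = (dosage[i, obs] - model.site_means[obs]) / model.site_scales[obs]
        l_obs = model.loadings[obs]
        beta, *_ = np.linalg.lstsq(l_obs, x, rcond=None)
        out[i] = beta
    if shrink:
        if model.shrink_factors is None:
            raise ValueError("model has no shrink factors; run loo_shrink_factors")
        out = out * model.shrink_factors
    return out[0] if single else out


def loo_shrink_factors(modern: GenotypeMatrix, model: PcaModel, k: int,
                       max_individuals: int = 50, seed: int = 0) -> np.ndarray:
    """Calibrate per-PC shrinkage factors by leave-one-out projection.

    Each held-out reference individual is projected onto a PCA refit
    without it; the factor for PC c is the ratio of the in-fit score
    spread to the projected score spread, so multiplying projected
    scores by it puts projected samples on the same scale as the
    reference scores (factors are >= 1 in expectation). The factors are
    stored on ``model`` and returned.
    """
    rng = np.random.default_rng(seed)
    n = modern.n_individuals
    take = np.arange(n)
    if n > max_individuals:
        take = np.sort(rng.choice(n, size=max_individuals, replace=False))
    _, full_scores = fit_pca(modern, None, k)
    proj = np.empty((len(take), k))
    for row, i in enumerate(take):
        rest = np.ones(n, dtype=bool)
        rest[i] = False
        sub = modern.subset_individuals(rest)
        sub_model, sub_scores = fit_pca(sub, None, k)
        # align the refit components to the full fit (sign via loadings)
        sign = np.sign(np.sum(sub_model.loadings * model.loadings, axis=0))
        sign[sign == 0] = 1.0
        beta = project_lsq(modern.dosages[i], sub_model)
        proj[row] = beta * sign
    fit_sd = full_scores[take].std(axis=0, ddof=1)
    proj_sd = proj.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(proj_sd > 0, fit_sd / proj_sd, 1.0)
    model.shrink_factors = factors
    return factors
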