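"""Cross-validated Mahalanobis (crossnobis) RDMs and their summary statistics.

The dissimilarity between the activity patterns of two digit conditions a, b
is estimated as the cross-validated squared Mahalanobis distance

    d(a, b) = mean over run pairs (m != n) of  delta_m' S^-1 delta_n / V

where ``delta_r = beta_r(a) - beta_r(b)`` is the pattern difference in run r,
``S`` is the (shrunk) voxel-by-voxel noise covariance estimated from GLM
residuals, and ``V`` the voxel count.  Because the two factors come from
independent runs the estimator is unbiased: its expectation is zero when the
two conditions evoke identical patterns, and individual estimates may be
negative.  Distances are divided by the voxel count so that values are
comparable across regions of different size; units are arbitrary (a.u.).

Summary statistics follow the standard representational-similarity workflow
for hand digits: the mean dissimilarity over the ten unique digit pairs
(strength of digit individuation), the typicality (Spearman correlation of a
measured RDM with a canonical two-hander reference RDM; a proxy for how
normally organised the hand representation is) and the split-half
consistency (Spearman correlation between RDMs computed separately from odd
and even runs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats

__all__ = [
    "RDM",
    "NoiseModel",
    "estimate_noise",
    "crossnobis",
    "mean_dissimilarity",
    "typicality",
    "split_half_consistency",
    "pair_labels",
]

DIGITS = ("D1", "D2", "D3", "D4", "D5")


def pair_labels(conditions=DIGITS) -> list[str]:
    """Unique condition pairs in canonical vectorization order.

    For five digits: (D1D2, D1D3, D1D4, D1D5, D2D3, D2D4, D2D5, D3D4,
    D3D5, D4D5) — row-major upper triangle.
    """
    n = len(conditions)
    return [f"{conditions[i]}{conditions[j]}" for i in range(n) for j in range(i + 1, n)]


@dataclass
class RDM:
    """Representational dissimilarity matrix with metadata.

    ``matrix`` is symmetric with a zero diagonal; entries may be negative
    because the crossnobis estimator is unbiased rather than nonnegative.
    """

    matrix: np.ndarray
    conditions: tuple = DIGITS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        self.matrix = m

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    @property
    def vector(self) -> np.ndarray:
        """Unique off-diagonal entries in canonical pair order."""
        iu = np.triu_indices(self.n_conditions, k=1)
        return self.matrix[iu]

    @classmethod
    def from_vector(cls, vec, conditions=DIGITS, meta=None) -> "RDM":
        vec = np.asarray(vec, dtype=float)
        n = len(conditions)
        if vec.shape != (n * (n - 1) // 2,):
            raise ValueError("vector length does not match condition count")
        m = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        m[iu] = vec
        m += m.T
        return cls(m, conditions=tuple(conditions), meta=meta or {})


@dataclass
class NoiseModel:
    """Voxel noise covariance used for multivariate noise normalization."""

    cov: np.ndarray
    shrinkage: float
    dof: int

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("covariance must be square")
        self.cov = c

    @property
    def n_voxels(self) -> int:
        return self.cov.shape[0]

    def whitener(self) -> np.ndarray:
        """Matrix ``W`` with ``W W' = cov^-1`` (inverse Cholesky factor)."""
        L = scipy.linalg.cholesky(self.cov, lower=True)
        W = scipy.linalg.solve_triangular(L, np.eye(self.n_voxels), lower=True).T
        return W


def _shrinkage_intensity(residuals: np.ndarray, sample_cov: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the diagonal target.

    Ledoit–Wolf-style plug-in estimate: the ratio of the summed sampling
    variances of the off-diagonal covariance entries to their summed squared
    magnitudes, clipped to [0, 1].
    """
    t, v = residuals.shape
    if t < 2:
        return 1.0
    x = residuals - residuals.mean(axis=0)
    # var(s_ij) ~ sum_t (x_ti x_tj - mean)^2 * t / (t-1)^3
    s_unnorm = x.T @ x / t
    w2 = (x**2).T @ (x**2) / t
    var_s = (w2 - s_unnorm**2) * t / (t - 1) ** 3 * t
    off = ~np.eye(v, dtype=bool)
    denom = np.sum(s_unnorm[off] ** 2)
    if denom <= 0:
        return 1.0
    lam = np.sum(var_s[off]) / denom
    return float(np.clip(lam, 0.0, 1.0))


def estimate_noise(residuals, dof: int, shrinkage: float | None = None) -> NoiseModel:
    """Estimate a shrunk voxel noise covariance from GLM residuals.

    Parameters
    ----------
    residuals
        Timepoints-by-voxels residual matrix, or a list of per-run residual
        matrices (pooled by stacking).
    dof
        Total error degrees of freedom used to normalize the sample
        covariance (summed over runs when residuals are pooled).
    shrinkage
        Shrinkage intensity in [0, 1] toward the diagonal of the sample
        covariance; if ``None`` an analytic Ledoit–Wolf-style intensity is
        computed from the residuals.

    Degenerate inputs are floored: near-zero voxel variances are raised to a
    small fraction of the mean variance, and all-zero residuals yield the
    identity covariance (no normalization), with a warning in both cases.
    """
    if isinstance(residuals, (list, tuple)):
        residuals = np.vstack(residuals)
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[0] < 2:
        raise ValueError("residuals must be a matrix with >= 2 rows")
    if dof < 1:
        raise ValueError("dof must be >= 1")

    v = residuals.shape[1]
    sample = residuals.T @ residuals / dof
    diag = np.diag(sample).copy()
    mean_var = float(np.mean(diag))
    if mean_var < 1e-12:
        warnings.warn("residuals have (near-)zero variance; using identity noise covariance")
        return NoiseModel(cov=np.eye(v), shrinkage=1.0, dof=dof)
    floor = 1e-6 * mean_var
    low = diag < floor
    if np.any(low):
        warnings.warn(f"{int(low.sum())} voxel(s) with near-zero residual variance floored")
        diag[low] = floor
        np.fill_diagonal(sample, diag)

    lam = _shrinkage_intensity(residuals, sample) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    cov = (1.0 - lam) * sample + lam * np.diag(diag)
    return NoiseModel(cov=cov, shrinkage=lam, dof=dof)


def _pair_contrasts(n_conditions: int) -> np.ndarray:
    """Pairs-by-conditions contrast matrix in canonical pair order."""
    pairs = [(i, j) for i in range(n_conditions) for j in range(i + 1, n_conditions)]
    c = np.zeros((len(pairs), n_conditions))
    for k, (i, j) in enumerate(pairs):
        c[k, i] = 1.0
        c[k, j] = -1.0
    return c


def crossnobis(run_betas, noise: NoiseModel, conditions=DIGITS, meta=None) -> RDM:
    """Cross-validated squared Mahalanobis distances between conditions.

    Parameters
    ----------
    run_betas
        List (length = number of runs, >= 2) of conditions-by-voxels beta
        matrices with a consistent condition order.
    noise
        Noise covariance for multivariate noise normalization
        (pre-whitening); voxel count must match the betas.

    Returns
    -------
    RDM
        Distances averaged over all unordered pairs of distinct runs and
        normalized by the voxel count.
    """
    if len(run_betas) < 2:
        raise ValueError("cross-validation impossible: need at least 2 runs")
    betas = [np.asarray(b, dtype=float) for b in run_betas]
    shape = betas[0].shape
    if any(b.shape != shape for b in betas):
        raise ValueError("all runs must have identical condition x voxel shape")
    n_cond, n_vox = shape
    if n_cond != len(conditions):
        raise ValueError("condition count does not match condition labels")
    if noise.n_voxels != n_vox:
        raise ValueError("noise model voxel count does not match betas")

    contrasts = _pair_contrasts(n_cond)
    w = noise.whitener()  # V x V, W W' = cov^-1
    # whitened pair differences per run: pairs x voxels
    deltas = np.stack([contrasts @ b @ w for b in betas])
    m = len(betas)
    total = deltas.sum(axis=0)
    # sum over ordered pairs m != n of <delta_m, delta_n> equals
    # |sum_r delta_r|^2 - sum_r |delta_r|^2, rowwise.
    cross = (total**2).sum(axis=1) - (deltas**2).sum(axis=(0, 2))
    dist = cross / (m * (m - 1)) / n_vox
    return RDM.from_vector(dist, conditions=conditions, meta=meta)


def mean_dissimilarity(rdm: RDM) -> float:
    """Mean of the unique off-diagonal dissimilarities (10 digit pairs)."""
    return float(np.mean(rdm.vector))


def typicality(rdm: RDM, canonical: RDM) -> float:
    """Spearman correlation between a measured RDM and the canonical RDM.

    Ties are handled with midranks; to keep mathematically tied
    dissimilarities tied despite floating-point rounding, values are
    quantized to ten decimals (relative to the largest magnitude) before
    ranking.  If either RDM vector is constant the rank correlation is
    undefined and NaN is returned with a warning.
    """
    a, b = rdm.vector, canonical.vector
    if a.shape != b.shape:
        raise ValueError("RDMs must cover the same condition pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("typicality undefined for a constant RDM; returning NaN")
        return float("nan")

    def _quantize(v):
        s = np.max(np.abs(v))
        return np.round(v / s, 10) if s > 0 else v

    rho, _ = scipy.stats.spearmanr(_quantize(a), _quantize(b))
    return float(rho)


def split_half_consistency(run_betas, noise: NoiseModel, conditions=DIGITS) -> float:
    """Spearman correlation between odd-run and even-run crossnobis RDMs.

    Runs are split by 1-based index: runs 1, 3, ... versus runs 2, 4, ....
    Each half must retain at least two runs for cross-validation.
    """
    odd = [b for i, b in enumerate(run_betas) if i % 2 == 0]
    even = [b for i, b in enumerate(run_betas) if i % 2 == 1]
    if len(odd) < 2 or len(even) < 2:
        raise ValueError("need at least 2 runs in each half for a split-half RDM")
    rdm_odd = crossnobis(odd, noise, conditions=conditions)
    rdm_even = crossnobis(even, noise, conditions=conditions)
    rho, _ = scipy.stats.spearmanr(rdm_odd.vector, rdm_even.vector)
    return float(rho)
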