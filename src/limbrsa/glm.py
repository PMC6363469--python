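"""Block-design GLM estimation: design matrices, high-pass filtering, betas.

Each run is modelled independently: one regressor per digit condition,
obtained by convolving the block timecourse (boxcar) with a double-gamma
hemodynamic response function, against an implicit rest baseline.  Slow
scanner drift is removed with a discrete-cosine high-pass basis (cutoff
100 s by default) included as confound regressors, which makes filtering
exactly linear and composable with the GLM.  Estimation is ordinary least
squares, optionally with user-supplied per-timepoint weights applied as
diagonal weighting (down-weighting noisy volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal
import scipy.stats

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "double_gamma_hrf",
    "dct_highpass_basis",
    "build_design",
    "highpass_filter",
    "fit_glm",
    "mean_activity",
]


def double_gamma_hrf(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Difference of two gamma densities: a positive response peaking ~5-6 s
    after stimulus and an undershoot around 16 s scaled by 1/ratio (the
    conventional parameterization).  Normalized to unit peak.
    """
    t = np.asarray(t, dtype=float)
    h = scipy.stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    h = h - scipy.stats.gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp) / ratio
    peak = np.max(np.abs(h)) if np.any(h) else 1.0
    return h / peak if peak > 0 else h


@dataclass
class DesignMatrix:
    """Time-by-regressor design for one run."""

    matrix: np.ndarray
    labels: list[str]
    tr_s: float
    run: int = 0
    condition_labels: list[str] = field(default_factory=list)

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def columns(self, labels) -> np.ndarray:
        idx = [self.labels.index(lab) for lab in labels]
        return self.matrix[:, idx]


@dataclass
class GLMResult:
    """Per-run GLM estimates: betas, residuals, degrees of freedom."""

    betas: np.ndarray  # regressor x voxel
    labels: list[str]
    residuals: np.ndarray  # time x voxel
    dof: int
    condition_labels: list[str] = field(default_factory=list)

    def condition_betas(self) -> np.ndarray:
        idx = [self.labels.index(lab) for lab in self.condition_labels]
        return self.betas[idx]


def dct_highpass_basis(n_timepoints: int, tr_s: float, cutoff_s: float = 100.0) -> np.ndarray:
    """Discrete-cosine basis spanning fluctuations slower than ``cutoff_s``.

    Returns the DCT-II regressors with period longer than the cutoff
    (excluding the constant), i.e. orders ``k = 1 .. floor(2*T*TR/cutoff)``.
    """
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff must exceed twice the TR")
    k_max = int(np.floor(2.0 * n_timepoints * tr_s / cutoff_s))
    t = np.arange(n_timepoints)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_timepoints)) for k in range(1, k_max + 1)]
    ) if k_max >= 1 else np.empty((n_timepoints, 0))
    return basis


def build_design(
    block_schedule,
    tr_s: float,
    n_timepoints: int | None = None,
    hrf_params: dict | None = None,
    highpass_cutoff_s: float | None = 100.0,
    oversample: int = 15,
    run: int = 0,
) -> DesignMatrix:
    """Build a convolved block design matrix.

    Parameters
    ----------
    block_schedule
        Iterable of ``(condition_label, onset_s, duration_s)`` triples.
        Overlapping blocks of the *same* condition are rejected.
    tr_s
        Repetition time in seconds.
    n_timepoints
        Number of volumes; inferred from the last block end if omitted.
    hrf_params
        Keyword overrides for :func:`double_gamma_hrf`.
    highpass_cutoff_s
        If not ``None``, discrete-cosine drift regressors with this cutoff
        plus a constant are appended as confounds.

    An empty schedule yields a design containing only the constant and
    drift columns.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    schedule = [(str(c), float(o), float(d)) for c, o, d in block_schedule]
    for c, o, d in schedule:
        if d <= 0 or o < 0:
            raise ValueError("blocks need onset >= 0 and duration > 0")
    by_cond: dict[str, list[tuple[float, float]]] = {}
    for c, o, d in schedule:
        by_cond.setdefault(c, []).append((o, d))
    for c, blocks in by_cond.items():
        blocks = sorted(blocks)
        for (o1, d1), (o2, _) in zip(blocks, blocks[1:]):
            if o2 < o1 + d1:
                raise ValueError(f"overlapping blocks for condition {c!r}")

    if n_timepoints is None:
        end = max((o + d for _, o, d in schedule), default=0.0)
        n_timepoints = int(np.ceil(end / tr_s)) + int(np.ceil(20.0 / tr_s))

    conditions = sorted(by_cond)
    dt = tr_s / oversample
    n_fine = n_timepoints * oversample
    hrf = double_gamma_hrf(np.arange(0.0, 32.0 + dt, dt), **(hrf_params or {}))

    cols = []
    for c in conditions:
        boxcar = np.zeros(n_fine)
        for o, d in by_cond[c]:
            i0 = int(round(o / dt))
            i1 = min(int(round((o + d) / dt)), n_fine)
            boxcar[i0:i1] = 1.0
        conv = scipy.signal.fftconvolve(boxcar, hrf)[:n_fine] * dt
        cols.append(conv[::oversample][:n_timepoints])

    labels = list(conditions)
    mat = np.column_stack(cols) if cols else np.empty((n_timepoints, 0))

    confounds = [np.ones(n_timepoints)]
    conf_labels = ["constant"]
    if highpass_cutoff_s is not None:
        t_lin = np.linspace(-0.5, 0.5, n_timepoints)
        confounds.append(t_lin)
        conf_labels.append("drift_linear")
        drift = dct_highpass_basis(n_timepoints, tr_s, highpass_cutoff_s)
        for k in range(drift.shape[1]):
            confounds.append(drift[:, k])
            conf_labels.append(f"drift_{k + 1}")
    mat = np.column_stack([mat] + [np.column_stack(confounds)]) if cols else np.column_stack(confounds)
    return DesignMatrix(
        matrix=mat,
        labels=labels + conf_labels,
        tr_s=tr_s,
        run=run,
        condition_labels=labels,
    )


def highpass_filter(series, tr_s: float, cutoff_s: float = 100.0) -> np.ndarray:
    """Remove the mean and fluctuations slower than ``cutoff_s``.

    Implemented by residualizing against the constant, a linear trend and
    the discrete-cosine basis of :func:`dct_highpass_basis`, so that
    filtering then fitting is equivalent to fitting with the basis included
    as confounds.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    one_d = series.ndim == 1
    y = series[:, None] if one_d else series
    n = y.shape[0]
    basis = np.column_stack(
        [np.ones(n), np.linspace(-0.5, 0.5, n), dct_highpass_basis(n, tr_s, cutoff_s)]
    )
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    out = y - basis @ coef
    return out[:, 0] if one_d else out


def _collinear_columns(x: np.ndarray, labels) -> list[str]:
    """Names of columns involved in the rank deficiency (via pivoted QR)."""
    _, r, piv = scipy.linalg.qr(x, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [labels[i] for i in sorted(piv[rank:])]


def fit_glm(series, design: DesignMatrix, weights=None) -> GLMResult:
    """Estimate betas and residuals for one run by (weighted) least squares.

    ``weights`` is an optional per-timepoint vector of nonnegative weights
    applied as diagonal weighting — the down-weighting interface for noisy
    volumes.  With ``weights=None`` this is ordinary least squares.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError("series and design have different numbers of timepoints")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = _collinear_columns(x, design.labels)
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (x.shape[0],) or np.any(w < 0):
            raise ValueError("weights must be a nonnegative per-timepoint vector")
        sw = np.sqrt(w)
        betas, *_ = np.linalg.lstsq(x * sw[:, None], y * sw[:, None], rcond=None)
    else:
        betas, *_ = np.linalg.lstsq(x, y, rcond=None)
    residuals = y - x @ betas
    dof = x.shape[0] - rank
    return GLMResult(
        betas=betas,
        labels=list(design.labels),
        residuals=residuals,
        dof=dof,
        condition_labels=list(design.condition_labels),
    )


def mean_activity(betas: np.ndarray, labels, digit_labels) -> float:
    """Mean beta (condition versus implicit rest baseline) over digit
    conditions and voxels — the univariate task-activity summary."""
    digit_labels = list(digit_labels)
    if not digit_labels:
        raise ValueError("need at least one digit condition label")
    labels = list(labels)
    idx = [labels.index(lab) for lab in digit_labels]
    return float(np.mean(np.asarray(betas, dtype=float)[idx]))
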