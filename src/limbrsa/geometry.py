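"""Low-dimensional visualisation geometry: classical MDS and Procrustes.

RDMs are projected to two dimensions with classical (Torgerson) MDS for
visual inspection of the digit arrangement, and participant projections are
aligned with rigid Procrustes (rotation/reflection, optional scaling off by
default) before averaging, because the MDS solution is defined only up to an
orthogonal transform.  No statistics are computed from the projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from limbrsa.rdm import RDM

__all__ = ["DigitProjection", "classical_mds", "procrustes_align", "mds_stress"]


@dataclass
class DigitProjection:
    """Aligned per-participant projections with group mean and dispersion."""

    aligned: list  # list of points x dims arrays
    mean: np.ndarray  # points x dims
    dispersion: np.ndarray  # points x dims standard error across participants
    meta: dict = field(default_factory=dict)


def classical_mds(rdm: RDM | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical MDS embedding of an RDM.

    Squares the dissimilarities, double-centers to a Gram matrix and takes
    the top eigenvectors; axes with non-positive eigenvalues are dropped
    (returned as zero columns).  An all-zero RDM maps every condition to
    the origin.
    """
    d = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("RDM must be square")
    if not np.allclose(d, d.T, atol=1e-8) or not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValueError("RDM must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:dims]
    coords = np.zeros((n, dims))
    for k, idx in enumerate(order):
        if evals[idx] > 1e-12:
            coords[:, k] = evecs[:, idx] * np.sqrt(evals[idx])
    return coords


def mds_stress(rdm: RDM | np.ndarray, coords: np.ndarray) -> float:
    """Sum of squared discrepancies between RDM entries and embedded
    pairwise distances, as a fraction of the total squared dissimilarity."""
    d = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    fitted = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(d.shape[0], k=1)
    total = float(np.sum(d[iu] ** 2))
    if total == 0:
        return 0.0
    return float(np.sum((d[iu] - fitted[iu]) ** 2) / total)


def _orthogonal_align(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate/reflect centered ``source`` onto centered ``target``."""
    r, _ = scipy.linalg.orthogonal_procrustes(source, target)
    return source @ r


def procrustes_align(projections, scaling: bool = False, meta=None) -> DigitProjection:
    """Align a set of per-participant MDS projections.

    Each configuration is centered at the origin, then aligned to the first
    participant with an orthogonal (rotation/reflection) transform, followed
    by one refinement pass aligning every configuration to the running mean.
    With ``scaling=False`` (default) within-configuration inter-point
    distances are untouched.  Returns the aligned configurations, their
    mean, and the per-point, per-axis standard error across participants.
    """
    configs = [np.asarray(p, dtype=float) for p in projections]
    if len(configs) < 2:
        raise ValueError("need at least two projections to align")
    shape = configs[0].shape
    if any(c.shape != shape for c in configs):
        raise ValueError("all projections must have the same points x dims shape")

    centered = [c - c.mean(axis=0) for c in configs]
    if scaling:
        ref_norm = np.linalg.norm(centered[0])
        centered = [
            c * (ref_norm / np.linalg.norm(c)) if np.linalg.norm(c) > 0 else c
            for c in centered
        ]
    aligned = [centered[0]] + [_orthogonal_align(c, centered[0]) for c in centered[1:]]
    mean = np.mean(aligned, axis=0)
    aligned = [_orthogonal_align(c, mean) for c in aligned]
    mean = np.mean(aligned, axis=0)
    se = np.std(aligned, axis=0, ddof=1) / np.sqrt(len(aligned))
    return DigitProjection(aligned=aligned, mean=mean, dispersion=se, meta=meta or {})
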