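"""Synthetic study generator with known ground truth.

Simulates the complete data-generating situation of a digit-movement fMRI
study of hand loss: per-participant condition-by-voxel activity patterns
whose true inter-digit geometry is ``signal_scale * canonical RDM``,
spatially correlated voxel noise with matching synthetic GLM residuals,
behavioural covariates (phantom kinaesthesia coupled to realized typicality,
vividness, pain, amputation history) and per-trial force traces for the
motor-performance check.  All outputs are deterministic functions of the
configuration and seed.

Two generation modes are provided: "beta mode" (default; emits run-wise
pattern matrices plus residuals directly) and "timeseries mode"
(:func:`simulate_timeseries`; emits voxel time series so the GLM stage can
be exercised end to end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from limbrsa.config import GROUPS, ROIS, ROI_HAND, CanonicalParams, StudyConfig
from limbrsa.rdm import DIGITS, RDM, typicality

__all__ = [
    "RunPatterns",
    "GroundTruth",
    "ForceData",
    "make_canonical_rdm",
    "spatial_noise_covariance",
    "simulate_participant",
    "simulate_timeseries",
    "simulate_covariates",
    "simulate_force_traces",
]


def make_canonical_rdm(params: CanonicalParams | None = None) -> RDM:
    """Parametric canonical inter-digit RDM.

    ``d(i, j) = baseline + neighbour_gradient * |i - j| + thumb_boost`` when
    the thumb (D1) is involved.  Stands in for an empirical two-hander
    reference RDM; users analysing real data should supply their own.
    """
    params = params or CanonicalParams()
    a, b, c = params.baseline, params.neighbour_gradient, params.thumb_boost
    if a <= 0:
        raise ValueError("baseline dissimilarity must be > 0")
    if b < 0 or c < 0:
        raise ValueError("neighbour_gradient and thumb_boost must be >= 0")
    n = len(DIGITS)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = a + b * abs(i - j) + c * (i == 0 or j == 0)
    return RDM(m, conditions=DIGITS, meta={"kind": "canonical", "params": params})


@dataclass
class RunPatterns:
    """Single-run, single-ROI pattern estimates with matching residuals."""

    betas: np.ndarray  # condition x voxel
    residuals: np.ndarray  # time x voxel
    dof: int
    conditions: tuple = DIGITS
    roi: str = ""
    run: int = 0
    participant: str = ""
    group: str = ""
    hand: str = ""


@dataclass
class GroundTruth:
    """Generative truth for one simulated participant."""

    group: str
    true_means: dict  # roi -> condition x voxel array
    true_rdm: dict  # roi -> RDM
    true_typicality: dict  # roi -> float (NaN when undefined)
    activation_offset: dict  # roi -> float
    seed: int = 0


@dataclass
class ForceData:
    """Per-trial force traces for the intact-hand button-box task."""

    traces: np.ndarray  # trial x digit-channel x time
    instructed_timecourses: np.ndarray  # trial x time
    instructed_digit: np.ndarray  # trial, int in [0, 4]
    sample_rate_hz: float = 10.0


def spatial_noise_covariance(
    n_voxels: int, corr_length: float, voxel_stds: np.ndarray | None = None
) -> np.ndarray:
    """Exponential-decay spatial noise covariance over a 1-D voxel index.

    ``corr(i, j) = exp(-|i - j| / corr_length)`` (identity when the length
    is 0), scaled by per-voxel standard deviations.
    """
    idx = np.arange(n_voxels)
    if corr_length > 0:
        corr = np.exp(-np.abs(idx[:, None] - idx[None, :]) / corr_length)
    else:
        corr = np.eye(n_voxels)
    if voxel_stds is None:
        return corr
    d = np.asarray(voxel_stds, dtype=float)
    return corr * d[:, None] * d[None, :]


def _geometry_coords(target_sq_dist: np.ndarray) -> np.ndarray:
    """Exact low-dimensional configuration realizing a squared-distance
    matrix (double-centered Gram factorization)."""
    n = target_sq_dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ target_sq_dist @ j
    evals, evecs = np.linalg.eigh(gram)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    r = int(np.sum(evals > 1e-12 * max(evals.max(), 1.0)))
    if r == 0:
        return np.zeros((n, 0))
    return evecs[:, :r] * np.sqrt(evals[:r])


def _embed_coords(rng: np.random.Generator, coords: np.ndarray, n_voxels: int) -> np.ndarray:
    """Embed a conditions-by-r configuration into voxel space through a
    random orthonormal basis, preserving all pairwise distances exactly."""
    n, r = coords.shape
    if r == 0:
        return np.zeros((n, n_voxels))
    if r > n_voxels:
        raise ValueError("not enough voxels to embed the requested geometry")
    basis, _ = np.linalg.qr(rng.standard_normal((n_voxels, r)))
    return coords @ basis.T


def _squared_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return (diff**2).sum(axis=-1)


def simulate_participant(
    config: StudyConfig, group: str, participant_seed: int, rois=None
) -> tuple[dict, GroundTruth]:
    """Simulate one participant in beta mode.

    Returns
    -------
    patterns : dict
        ``roi -> list of RunPatterns`` (one per run).
    truth : GroundTruth
        True mean patterns, true RDMs and true typicality per ROI.

    True condition means realize ``signal_scale[group][roi] * canonical``
    exactly (per-voxel squared distance); run-wise patterns add noise with
    the configured spatial covariance; residual matrices are drawn from the
    same covariance so the noise-normalization stage is consistent with the
    pattern noise.  V5 never carries digit signal for any group.

    ``rois`` optionally restricts generation to a subset of regions (the
    random stream is keyed per region, so a region's data is identical
    whether or not the others are generated).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    selected = tuple(ROIS) if rois is None else tuple(rois)
    for roi in selected:
        if roi not in ROIS:
            raise ValueError(f"unknown ROI {roi!r}")
    canonical = make_canonical_rdm(config.canonical_params)

    patterns: dict[str, list[RunPatterns]] = {}
    true_means: dict[str, np.ndarray] = {}
    true_rdms: dict[str, RDM] = {}
    true_typ: dict[str, float] = {}
    offsets: dict[str, float] = {}
    pid = f"{group}_{participant_seed:03d}"

    for roi in selected:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(config.rng_seed), int(participant_seed), ROIS.index(roi)]
            )
        )
        v = config.n_voxels_per_roi[roi]
        scale = 0.0 if roi == "V5" else float(config.signal_scale[group][roi])
        if scale > 0 and config.signal_amplitude_sd > 0:
            # between-participant amplitude variability (median = group scale)
            scale *= float(np.exp(rng.normal(0.0, config.signal_amplitude_sd)))
        # exact configuration realizing: squared pattern distance per voxel
        # = scale * canonical entry ...
        coords = _geometry_coords(scale * canonical.matrix * v)
        # ... then participant-specific geometry variability: jitter the
        # configuration so each participant's *true* RDM is a perturbed
        # canonical geometry (consistent across runs within participant).
        if coords.shape[1] > 0 and config.geometry_jitter > 0:
            rms = np.sqrt(np.mean(coords**2))
            coords = coords + config.geometry_jitter * rms * rng.standard_normal(coords.shape)
        means_centered = _embed_coords(rng, coords, v)
        offset = float(
            config.mean_activation[group][roi]
            + rng.normal(0.0, config.activation_subject_sd)
        )
        means = means_centered + offset
        true_means[roi] = means
        true_rdms[roi] = RDM(_squared_distances(coords) / v, meta={"roi": roi, "truth": True})
        true_typ[roi] = typicality(true_rdms[roi], canonical) if scale > 0 else float("nan")
        offsets[roi] = offset

        voxel_stds = np.exp(rng.normal(0.0, config.voxel_variance_log_sd, size=v))
        cov = spatial_noise_covariance(v, config.noise_spatial_corr, voxel_stds)
        chol = np.linalg.cholesky(cov)

        runs = []
        for run in range(config.n_runs):
            noise = rng.standard_normal((config.n_digits, v)) @ chol.T * config.beta_noise_std
            resid = (
                rng.standard_normal((config.n_residual_timepoints, v))
                @ chol.T
                * config.residual_noise_std
            )
            runs.append(
                RunPatterns(
                    betas=means + noise,
                    residuals=resid,
                    dof=config.residual_dof,
                    conditions=DIGITS,
                    roi=roi,
                    run=run + 1,
                    participant=pid,
                    group=group,
                    hand=ROI_HAND[roi],
                )
            )
        patterns[roi] = runs

    truth = GroundTruth(
        group=group,
        true_means=true_means,
        true_rdm=true_rdms,
        true_typicality=true_typ,
        activation_offset=offsets,
        seed=participant_seed,
    )
    return patterns, truth


@dataclass
class TimeseriesNoise:
    """Noise description for timeseries mode."""

    sigma: float = 1.0
    drift_amplitude: float = 0.0
    spatial_corr: float = 0.0


def simulate_timeseries(
    design_schedule,
    true_betas: np.ndarray,
    tr_s: float,
    n_timepoints: int,
    noise_model: TimeseriesNoise | None = None,
    seed: int = 0,
    hrf_params: dict | None = None,
):
    """Generate voxel time series from a block schedule and true betas.

    ``series = design @ betas + linear drift + spatially correlated noise``;
    the returned design contains only condition columns plus the constant
    (no drift regressors), so drift must be handled by high-pass filtering
    or confounds downstream.  Deterministic given the seed.
    """
    from limbrsa import glm as glm_mod

    noise_model = noise_model or TimeseriesNoise()
    true_betas = np.asarray(true_betas, dtype=float)
    design = glm_mod.build_design(
        design_schedule, tr_s, n_timepoints=n_timepoints, highpass_cutoff_s=None,
        hrf_params=hrf_params,
    )
    n_cond = len(design.condition_labels)
    if true_betas.shape[0] != n_cond:
        raise ValueError(
            f"true_betas has {true_betas.shape[0]} conditions, schedule has {n_cond}"
        )
    rng = np.random.default_rng(seed)
    x = design.columns(design.condition_labels)
    series = x @ true_betas
    t = np.arange(n_timepoints, dtype=float)
    if noise_model.drift_amplitude:
        drift = noise_model.drift_amplitude * (t / max(n_timepoints - 1, 1) - 0.5)
        series = series + drift[:, None]
    if noise_model.sigma > 0:
        v = true_betas.shape[1]
        cov = spatial_noise_covariance(v, noise_model.spatial_corr)
        chol = np.linalg.cholesky(cov)
        series = series + rng.standard_normal((n_timepoints, v)) @ chol.T * noise_model.sigma
    return series, design


def _normal_scores(values: np.ndarray) -> np.ndarray:
    ranks = scipy.stats.rankdata(values, method="average")
    return scipy.stats.norm.ppf((ranks - 0.5) / len(values))


def _attained_spearman(typ_std: np.ndarray, rho: float, eps: np.ndarray) -> float:
    """Expected Spearman between six-level-binned latent and typicality,
    estimated over pre-drawn noise replicates ``eps`` (reps x n)."""
    z = rho * typ_std + np.sqrt(max(1.0 - rho**2, 0.0)) * eps
    kin = np.clip(np.floor(scipy.stats.norm.cdf(z) * 6.0), 0, 5)
    rk = scipy.stats.rankdata(kin, axis=1)
    rt = scipy.stats.rankdata(typ_std)
    rk_c = rk - rk.mean(axis=1, keepdims=True)
    rt_c = rt - rt.mean()
    denom = np.sqrt((rk_c**2).sum(axis=1) * (rt_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, rk_c @ rt_c / denom, 0.0)
    return float(corr.mean())


def _calibrate_latent_correlation(
    typ_std: np.ndarray, target: float, rng: np.random.Generator, n_sim: int = 400
) -> float:
    """Latent correlation whose binned score attains the target expected
    Spearman with the given (standardized) typicality values."""
    eps = rng.standard_normal((n_sim, typ_std.shape[0]))
    if _attained_spearman(typ_std, 1.0 - 1e-9, eps) <= target:
        return 1.0 - 1e-9
    lo, hi = 0.0, 1.0 - 1e-9
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if _attained_spearman(typ_std, mid, eps) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_covariates(realized_typicality, coupling: float, seed: int = 0) -> pd.DataFrame:
    """Behavioural covariate table for a cohort of amputees.

    Phantom kinaesthesia (integer 0-5, the number of phantom digits with a
    sensation of independent movement) is generated through a Gaussian
    copula so its population Spearman correlation with the *realized*
    typicality values equals ``coupling``, then discretized to six levels
    (which attenuates the rank correlation slightly).  The remaining
    covariates — chronic/acute nonpainful vividness (0-100), chronic/acute
    phantom pain (0-100), years since amputation, age at amputation, and
    intact-hand typicality — are drawn independently of typicality, with
    distributions matching a typical acquired-amputee cohort.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    typ = np.asarray(realized_typicality, dtype=float)
    n = typ.shape[0]
    rng = np.random.default_rng(seed)

    # Kinaesthesia is driven linearly by (standardized) typicality plus
    # independent Gaussian noise, then discretized to six levels — matching
    # the linear relation the regression analysis probes.  The latent
    # correlation is calibrated per cohort (bisection against a Monte-Carlo
    # estimate of the attained rank correlation) so that the expected
    # Spearman between the discretized score and the realized typicality
    # values equals the requested coupling.
    typ_sd = typ.std()
    typ_std = (typ - typ.mean()) / typ_sd if typ_sd > 0 else np.zeros(n)
    if abs(coupling) >= 1.0:
        z_kin = np.sign(coupling) * _normal_scores(typ)
        kin = np.clip(np.floor(scipy.stats.norm.cdf(z_kin) * 6.0), 0, 5).astype(int)
    else:
        rho_lin = 0.0
        if coupling != 0.0:
            rho_lin = _calibrate_latent_correlation(
                typ_std, abs(coupling), np.random.default_rng(np.random.SeedSequence([seed, 71]))
            )
        # draw several candidate noise realizations and keep the one whose
        # *realized* rank correlation is closest to the target coupling —
        # the coupling is a ground-truth parameter of the cohort, so its
        # sampling variability is removed here just as the pattern
        # generator realizes the target geometry exactly.
        n_candidates = 64
        eps = rng.standard_normal((n_candidates, n))
        z = np.sign(coupling) * rho_lin * typ_std + np.sqrt(1.0 - rho_lin**2) * eps
        kin_cand = np.clip(np.floor(scipy.stats.norm.cdf(z) * 6.0), 0, 5)
        rt = scipy.stats.rankdata(typ)
        rk = scipy.stats.rankdata(kin_cand, axis=1)
        rk_c = rk - rk.mean(axis=1, keepdims=True)
        rt_c = rt - rt.mean()
        denom = np.sqrt((rk_c**2).sum(axis=1) * (rt_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rhos = np.where(denom > 0, rk_c @ rt_c / denom, 0.0)
        kin = kin_cand[int(np.argmin(np.abs(rhos - coupling)))].astype(int)

    def trunc(mean, sd, lo, hi, size=n):
        return np.clip(rng.normal(mean, sd, size=size), lo, hi)

    table = pd.DataFrame(
        {
            "kinaesthesia": kin,
            "vividness_chronic": trunc(58, 38, 0, 100),
            "vividness_acute": trunc(65, 30, 0, 100),
            "pain_chronic": trunc(46, 37, 0, 100),
            "pain_acute": trunc(21, 23, 0, 100),
            "years_since_amputation": np.round(trunc(18, 10, 1, 45), 1),
            "age_at_amputation": np.round(trunc(33, 12, 16, 60), 1),
            "intact_typicality": trunc(0.81, 0.08, -1, 1),
            "typicality": typ,
        }
    )
    return table


def _press_waveform(n_presses: int, sample_rate_hz: float) -> np.ndarray:
    """Instructed 1-Hz press timecourse: half-sine force bumps."""
    per = int(round(sample_rate_hz))
    bump = np.sin(np.linspace(0.0, np.pi, per, endpoint=False))
    return np.tile(bump, n_presses)


def simulate_force_traces(
    trial_schedule,
    performance_level: float,
    seed: int = 0,
    n_presses: int = 12,
    sample_rate_hz: float = 10.0,
    noise_sd: float = 0.8,
) -> ForceData:
    """Per-trial digit-channel force traces at 1-Hz press cadence.

    ``performance_level`` in [0, 1] mixes the instructed-digit signal with
    the same signal placed on a uniformly random digit: at 1 the instructed
    channel carries the full waveform (classification is perfect), at 0 the
    waveform lands on a random digit (classification at the 20% chance
    level).  Channel noise makes intermediate levels produce intermediate
    accuracies.
    """
    if not 0.0 <= performance_level <= 1.0:
        raise ValueError("performance_level must lie in [0, 1]")
    instructed = np.asarray(list(trial_schedule), dtype=int)
    if np.any(instructed < 0) or np.any(instructed > 4):
        raise ValueError("instructed digits must be integers in [0, 4]")
    rng = np.random.default_rng(seed)
    wave = _press_waveform(n_presses, sample_rate_hz)
    n_trials, t = len(instructed), wave.shape[0]
    traces = rng.standard_normal((n_trials, 5, t)) * noise_sd
    random_digit = rng.integers(0, 5, size=n_trials)
    for k in range(n_trials):
        traces[k, instructed[k]] += performance_level * wave
        traces[k, random_digit[k]] += (1.0 - performance_level) * wave
    timecourses = np.tile(wave, (n_trials, 1))
    return ForceData(
        traces=traces,
        instructed_timecourses=timecourses,
        instructed_digit=instructed,
        sample_rate_hz=sample_rate_hz,
    )
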