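"""Study configuration for the synthetic digit-representation experiment.

The default :class:`StudyConfig` encodes the experimental design used
throughout the package: three groups (acquired amputees, congenital
one-handers, two-handed controls), four fMRI runs per participant, 12-s
digit-movement blocks repeated three times per run at TR 1.5 s, and four
regions of interest — the primary somatosensory (SI) and motor (M1) hand
areas contralateral to the missing/nondominant hand, the same cortex probed
via ipsilateral movements of the intact hand, and visual area V5 as a control
region carrying no somatosensory digit information.

Group signal scales are calibration constants: they set how strongly each
group's true condition patterns realize the canonical inter-digit geometry,
and defaults are chosen so the default pipeline produces group summary
statistics in the range reported for comparable human cohorts (high
typicality for amputees and controls, strongly reduced typicality for
congenital one-handers, none in V5).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

GROUPS = ("amputee", "congenital", "control")
ROIS = ("SI_contra", "M1_contra", "SI_ipsi", "V5")

#: analysis hand associated with each region: the contralateral regions are
#: probed with missing/nondominant-hand movements, SI_ipsi with intact-hand
#: movements, V5 with both (averaged downstream).
ROI_HAND = {
    "SI_contra": "contralateral",
    "M1_contra": "contralateral",
    "SI_ipsi": "ipsilateral",
    "V5": "contralateral",
}


@dataclass(frozen=True)
class CanonicalParams:
    """Parameters of the parametric canonical inter-digit RDM.

    The canonical hand geometry is modelled as
    ``d(i, j) = a + b * |i - j| + c * [i == D1 or j == D1]``:
    a baseline dissimilarity ``a`` between any two digits, a neighbourhood
    gradient ``b`` (non-neighbouring digits are more dissimilar), and a
    thumb-distinctiveness boost ``c`` (the thumb is the most individuated
    digit). Defaults give a Euclidean-embeddable geometry qualitatively
    matching measured two-hander inter-digit structure.
    """

    baseline: float = 1.0
    neighbour_gradient: float = 0.5
    thumb_boost: float = 0.5


def _default_signal_scale() -> dict:
    # Calibrated so that the default pipeline lands near typicality ~0.75
    # for amputees and ~0.29 for congenital one-handers in contralateral SI,
    # weaker digit individuation in M1 and ipsilateral SI, and none in V5.
    return {
        "amputee": {"SI_contra": 0.008, "M1_contra": 0.002, "SI_ipsi": 0.0045, "V5": 0.0},
        "congenital": {"SI_contra": 0.001, "M1_contra": 0.0005, "SI_ipsi": 0.0012, "V5": 0.0},
        "control": {"SI_contra": 0.0105, "M1_contra": 0.0028, "SI_ipsi": 0.005, "V5": 0.0},
    }


def _default_mean_activation() -> dict:
    # Mean digit-versus-rest activation (a.u.); congenital SI activity is
    # reduced but above baseline.
    return {
        "amputee": {"SI_contra": 1.0, "M1_contra": 1.1, "SI_ipsi": 0.6, "V5": 0.2},
        "congenital": {"SI_contra": 0.55, "M1_contra": 0.85, "SI_ipsi": 0.6, "V5": 0.2},
        "control": {"SI_contra": 1.1, "M1_contra": 1.2, "SI_ipsi": 0.6, "V5": 0.2},
    }


def _default_n_per_group() -> dict:
    return {"amputee": 18, "congenital": 13, "control": 12}


def _default_n_voxels() -> dict:
    return {"SI_contra": 100, "M1_contra": 100, "SI_ipsi": 100, "V5": 80}


@dataclass
class StudyConfig:
    """Full parameterization of a simulated study.

    Parameters
    ----------
    n_per_group
        Participants per group.
    n_runs
        fMRI runs per participant (cross-validation folds).
    n_digits
        Digit conditions per hand (D1 thumb … D5 little finger).
    block_duration_s, repeats_per_run, tr_s
        Block-design timing: 12-s movement blocks, three repeats of each
        condition per run, TR 1.5 s.
    n_voxels_per_roi
        Voxel count of each region of interest.
    signal_scale
        Per-group, per-ROI nonnegative scaling of the canonical geometry:
        squared pattern distance per voxel between two digits equals
        ``signal_scale * canonical_rdm[i, j]`` in the noiseless limit.
    mean_activation
        Per-group, per-ROI mean digit-versus-rest beta (univariate activity).
    activation_subject_sd
        Between-participant SD of the activation offset.
    geometry_jitter
        Inter-individual geometry variability: SD of Gaussian jitter applied
        to each participant's true digit configuration, as a fraction of the
        configuration's RMS coordinate.  0 makes every participant's true
        geometry exactly canonical; larger values lower typicality while
        leaving within-participant (split-half) consistency intact.  Scales
        with the signal, so a zero-signal region remains truly null.
    signal_amplitude_sd
        Between-participant variability of overall signal strength: each
        participant's effective signal scale is the group scale times a
        lognormal factor with this log-SD.  0 gives every participant the
        group scale exactly.
    beta_noise_std
        SD of run-wise pattern noise per voxel (relative to unit residual SD).
    residual_noise_std
        SD of the synthetic GLM residuals per voxel.
    noise_spatial_corr
        Correlation length (in voxel index units) of the exponential-decay
        spatial noise correlation; 0 gives white noise.
    voxel_variance_log_sd
        Log-normal SD of per-voxel noise variances (voxel heteroscedasticity).
    n_residual_timepoints
        Rows of the per-run residual matrix emitted in beta mode.
    residual_dof
        Error degrees of freedom per run associated with those residuals.
    canonical_params
        Parameters of the canonical RDM generator.
    covariate_coupling
        Target Spearman correlation between phantom kinaesthesia and realized
        typicality across amputees (in [-1, 1]).
    rng_seed
        Master seed; all simulation randomness derives from it.
    """

    n_per_group: dict = field(default_factory=_default_n_per_group)
    n_runs: int = 4
    n_digits: int = 5
    block_duration_s: float = 12.0
    repeats_per_run: int = 3
    tr_s: float = 1.5
    n_voxels_per_roi: dict = field(default_factory=_default_n_voxels)
    signal_scale: dict = field(default_factory=_default_signal_scale)
    mean_activation: dict = field(default_factory=_default_mean_activation)
    activation_subject_sd: float = 0.25
    geometry_jitter: float = 0.15
    signal_amplitude_sd: float = 0.4
    beta_noise_std: float = 0.35
    residual_noise_std: float = 1.0
    noise_spatial_corr: float = 5.0
    voxel_variance_log_sd: float = 0.15
    n_residual_timepoints: int = 264
    residual_dof: int = 244
    canonical_params: CanonicalParams = field(default_factory=CanonicalParams)
    covariate_coupling: float = 0.7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.canonical_params, dict):
            self.canonical_params = CanonicalParams(**self.canonical_params)
        self.validate()

    def validate(self) -> None:
        if self.n_runs < 1 or self.n_digits < 1 or self.repeats_per_run < 1:
            raise ValueError("counts must be >= 1")
        if self.tr_s <= 0 or self.block_duration_s <= 0:
            raise ValueError("timing parameters must be positive")
        for group, n in self.n_per_group.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            if n < 1:
                raise ValueError("group sizes must be >= 1")
        for roi, v in self.n_voxels_per_roi.items():
            if roi not in ROIS:
                raise ValueError(f"unknown ROI {roi!r}")
            if v < 1:
                raise ValueError("voxel counts must be >= 1")
        for group, per_roi in self.signal_scale.items():
            for roi, s in per_roi.items():
                if s < 0:
                    raise ValueError(f"signal_scale[{group}][{roi}] must be >= 0")
        if not -1.0 <= self.covariate_coupling <= 1.0:
            raise ValueError("covariate_coupling must lie in [-1, 1]")
        if self.residual_dof < 2 or self.n_residual_timepoints < 2:
            raise ValueError("residual dimensions must be >= 2")

    @property
    def run_duration_s(self) -> float:
        """Total task time per run: (digit conditions of both hands + rest)
        x repeats x block duration."""
        n_blocks = (2 * self.n_digits + 1) * self.repeats_per_run
        return n_blocks * self.block_duration_s

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the full configuration, for provenance records."""
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
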