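"""End-to-end orchestration: simulate -> RDMs -> geometry -> inference.

:func:`run_study` executes the full analysis for a configured synthetic
study across the four regions (contralateral SI and M1, ipsilateral SI, V5):

1. per-participant crossnobis RDMs with noise normalization from pooled
   run residuals, plus univariate activity, mean dissimilarity, typicality
   against the canonical RDM, and odd/even split-half consistency;
2. the missing-hand group analysis — three Bonferroni-controlled group
   contrasts per measure, one-sample tests against zero, and the
   group-difference-calibrated Bayes factor for amputees versus controls;
3. the phantom-sensation analysis in amputees — forward stepwise regression
   of SI typicality on behavioural covariates with bootstrap replicability,
   post-hoc Spearman correlations, the partial correlation controlling for
   M1 typicality, and the low-vividness subgroup Mann-Whitney contrasts;
4. the ipsilateral/V5 control analysis with mixed-design group-by-area
   ANOVAs;
5. MDS projections Procrustes-aligned within each group.

Every stage is deterministic given the configuration seed, and provenance
(config hash, seed, package version) is recorded with the results.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from limbrsa import geometry, io, stats
from limbrsa.config import GROUPS, ROIS, ROI_HAND, StudyConfig
from limbrsa.rdm import (
    crossnobis,
    estimate_noise,
    mean_dissimilarity,
    split_half_consistency,
    typicality,
)
from limbrsa.synthetic import make_canonical_rdm, simulate_covariates, simulate_participant

__all__ = ["GroupResults", "run_study", "report"]

_GROUP_SEED_OFFSET = {"amputee": 0, "congenital": 1000, "control": 2000}

COVARIATE_PREDICTORS = [
    "kinaesthesia",
    "vividness_chronic",
    "vividness_acute",
    "pain_chronic",
    "pain_acute",
    "years_since_amputation",
    "age_at_amputation",
    "intact_typicality",
]


@dataclass
class GroupResults:
    """All tables and inferential outputs of one study run."""

    participant_measures: pd.DataFrame
    rdm_table: pd.DataFrame
    covariates: pd.DataFrame
    inferential: pd.DataFrame
    stepwise: stats.StepwiseModel
    bootstrap: stats.BootstrapSummary
    bayes: dict  # measure -> BayesResult
    projections: dict  # group -> DigitProjection (contralateral SI)
    provenance: dict = field(default_factory=dict)


def _analyze_participant(config, canonical, group, participant_seed):
    patterns, truth = simulate_participant(config, group, participant_seed)
    pid = f"{group}_{participant_seed:03d}"
    rows, rdms = [], []
    for roi in ROIS:
        runs = patterns[roi]
        noise = estimate_noise([rp.residuals for rp in runs], dof=sum(rp.dof for rp in runs))
        rdm = crossnobis(
            [rp.betas for rp in runs],
            noise,
            meta={"participant": pid, "group": group, "roi": roi, "hand": ROI_HAND[roi]},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            typ = typicality(rdm, canonical)
            split = split_half_consistency([rp.betas for rp in runs], noise)
        activity = float(np.mean([rp.betas for rp in runs]))
        rows.append(
            {
                "participant": pid,
                "group": group,
                "roi": roi,
                "hand": ROI_HAND[roi],
                "mean_activity": activity,
                "mean_dissimilarity": mean_dissimilarity(rdm),
                "typicality": typ,
                "split_half_rho": split,
            }
        )
        rdms.append(rdm)
    return rows, rdms, patterns


def _group_contrasts(measures: pd.DataFrame, roi: str, column: str) -> list[dict]:
    """Three Bonferroni-controlled between-group contrasts plus one-sample
    tests against zero, for one measure in one region."""
    sub = measures[measures["roi"] == roi]
    values = {g: sub.loc[sub["group"] == g, column].to_numpy() for g in GROUPS}
    pairs = [("amputee", "control"), ("amputee", "congenital"), ("congenital", "control")]
    out = []
    for a, b in pairs:
        res = stats.group_ttest(values[a], values[b], family_size=3)
        out.append(
            {
                "analysis": f"{column}:{roi}",
                "contrast": f"{a} vs {b}",
                "test": res.name,
                "statistic": res.statistic,
                "dof": res.dof,
                "p": res.p,
                "alpha_adjusted": res.alpha_adjusted,
            }
        )
    for g in GROUPS:
        res = stats.one_sample_ttest(values[g], 0.0)
        out.append(
            {
                "analysis": f"{column}:{roi}",
                "contrast": f"{g} vs 0",
                "test": res.name,
                "statistic": res.statistic,
                "dof": res.dof,
                "p": res.p,
                "alpha_adjusted": res.alpha_adjusted,
            }
        )
    return out


def _calibrated_bf(measures: pd.DataFrame, roi: str, column: str):
    """Bayes factor for the amputee-vs-control difference, with the prior
    width set by the congenital-vs-control difference in the same measure."""
    sub = measures[measures["roi"] == roi]
    amp = sub.loc[sub["group"] == "amputee", column].to_numpy()
    ctr = sub.loc[sub["group"] == "control", column].to_numpy()
    cong = sub.loc[sub["group"] == "congenital", column].to_numpy()
    prior_scale = float(abs(ctr.mean() - cong.mean()))
    # deficit-positive orientation: positive effect = amputees below controls
    effect = float(ctr.mean() - amp.mean())
    n1, n2 = len(ctr), len(amp)
    sp2 = ((n1 - 1) * ctr.var(ddof=1) + (n2 - 1) * amp.var(ddof=1)) / (n1 + n2 - 2)
    se = float(np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    return stats.calibrated_bayes_factor(
        effect_obs=effect,
        se_obs=se,
        dof_obs=n1 + n2 - 2,
        prior_scale=prior_scale,
        prior_dof=len(ctr) + len(cong) - 2,
        tail="positive",
    )


def run_study(config: StudyConfig, n_boot: int = 1000) -> GroupResults:
    """Run the complete analysis on a freshly simulated study."""
    canonical = make_canonical_rdm(config.canonical_params)
    all_rows, all_rdms = [], []
    patterns_by_pid = {}
    for group in GROUPS:
        for i in range(config.n_per_group[group]):
            seed = _GROUP_SEED_OFFSET[group] + i
            rows, rdms, patterns = _analyze_participant(config, canonical, group, seed)
            all_rows.extend(rows)
            all_rdms.extend(rdms)
            patterns_by_pid[rows[0]["participant"]] = patterns
    measures = pd.DataFrame(all_rows)
    rdm_table = io.rdm_long_table(all_rdms)

    # --- missing-hand and control-region group statistics -----------------
    inferential_rows: list[dict] = []
    for roi in ROIS:
        for column in ("mean_activity", "mean_dissimilarity", "typicality", "split_half_rho"):
            inferential_rows.extend(_group_contrasts(measures, roi, column))

    bayes = {
        "typicality": _calibrated_bf(measures, "SI_contra", "typicality"),
        "mean_dissimilarity": _calibrated_bf(measures, "SI_contra", "mean_dissimilarity"),
    }
    for measure, res in bayes.items():
        inferential_rows.append(
            {
                "analysis": f"{measure}:SI_contra",
                "contrast": "amputee vs control (calibrated BF)",
                "test": "bayes factor",
                "statistic": res.bf,
                "dof": res.dof_obs,
                "p": np.nan,
                "alpha_adjusted": np.nan,
            }
        )

    # --- phantom-sensation analysis in amputees ---------------------------
    amp = measures[(measures["group"] == "amputee") & (measures["roi"] == "SI_contra")]
    amp = amp.sort_values("participant")
    amp_typ = amp["typicality"].to_numpy()
    cov_seed_root = np.random.SeedSequence([int(config.rng_seed), 9001])
    covariates = simulate_covariates(
        amp_typ, config.covariate_coupling, seed=int(cov_seed_root.generate_state(1)[0] % (2**31))
    )
    covariates.insert(0, "participant", amp["participant"].to_numpy())

    X = covariates[COVARIATE_PREDICTORS].to_numpy()
    stepwise = stats.stepwise_forward(amp_typ, X, delta_r2=0.1, names=COVARIATE_PREDICTORS)
    boot_seed = int(np.random.SeedSequence([int(config.rng_seed), 9002]).generate_state(1)[0] % (2**31))
    bootstrap = stats.bootstrap_stepwise(
        amp_typ, X, B=n_boot, delta_r2=0.1, seed=boot_seed, names=COVARIATE_PREDICTORS
    )
    inferential_rows.append(
        {
            "analysis": "stepwise:typicality~covariates",
            "contrast": "+".join(stepwise.included) or "intercept-only",
            "test": "stepwise F",
            "statistic": stepwise.f_statistic,
            "dof": stepwise.n,
            "p": stepwise.f_p,
            "alpha_adjusted": np.nan,
        }
    )

    rho_kin = stats.spearman(covariates["kinaesthesia"].to_numpy(), amp_typ)
    inferential_rows.append(
        {
            "analysis": "correlation:typicality~kinaesthesia",
            "contrast": "amputees",
            "test": rho_kin.name,
            "statistic": rho_kin.statistic,
            "dof": rho_kin.dof,
            "p": rho_kin.p,
            "alpha_adjusted": 0.05 / 3,
        }
    )
    m1_typ = (
        measures[(measures["group"] == "amputee") & (measures["roi"] == "M1_contra")]
        .sort_values("participant")["typicality"]
        .to_numpy()
    )
    partial = stats.partial_correlation(amp_typ, covariates["kinaesthesia"].to_numpy(), m1_typ)
    inferential_rows.append(
        {
            "analysis": "partial:typicality~kinaesthesia|M1",
            "contrast": "amputees",
            "test": partial.name,
            "statistic": partial.extra["partial_r"],
            "dof": partial.dof,
            "p": partial.p,
            "alpha_adjusted": np.nan,
        }
    )

    # low-vividness amputee subgroup versus congenital/control typicality
    viv = covariates["vividness_chronic"].to_numpy()
    low_idx = np.where(viv < 10)[0]
    if low_idx.size < 3:
        low_idx = np.argsort(viv)[:3]
    low_typ = amp_typ[low_idx]
    for other in ("congenital", "control"):
        other_typ = measures[
            (measures["group"] == other) & (measures["roi"] == "SI_contra")
        ]["typicality"].to_numpy()
        mw = stats.mann_whitney(low_typ, other_typ)
        inferential_rows.append(
            {
                "analysis": "typicality:SI_contra",
                "contrast": f"low-vividness amputees vs {other}",
                "test": mw.name,
                "statistic": mw.statistic,
                "dof": mw.dof,
                "p": mw.p,
                "alpha_adjusted": np.nan,
            }
        )

    # --- ipsilateral / V5 control analysis --------------------------------
    for column in ("mean_dissimilarity", "typicality"):
        long = measures[measures["roi"].isin(["SI_ipsi", "V5"])][
            ["participant", "group", "roi", column]
        ].rename(columns={column: "value", "roi": "area"})
        res = stats.mixed_anova(long, dv="value", between="group", within="area", subject="participant")
        inferential_rows.append(
            {
                "analysis": f"{column}:SI_ipsi-vs-V5",
                "contrast": "group x area interaction",
                "test": "mixed ANOVA F",
                "statistic": res.statistic,
                "dof": res.dof,
                "p": res.p,
                "alpha_adjusted": np.nan,
            }
        )

    # --- geometry ----------------------------------------------------------
    projections = {}
    for group in GROUPS:
        group_rdms = [
            r for r in all_rdms if r.meta.get("group") == group and r.meta.get("roi") == "SI_contra"
        ]
        coords = [geometry.classical_mds(r, dims=2) for r in group_rdms]
        projections[group] = geometry.procrustes_align(coords, meta={"group": group, "roi": "SI_contra"})

    provenance = {
        "config_hash": config.content_hash(),
        "seed": int(config.rng_seed),
        "version": __import__("limbrsa").__version__,
        "n_boot": int(n_boot),
    }
    return GroupResults(
        participant_measures=measures,
        rdm_table=rdm_table,
        covariates=covariates,
        inferential=pd.DataFrame(inferential_rows),
        stepwise=stepwise,
        bootstrap=bootstrap,
        bayes=bayes,
        projections=projections,
        provenance=provenance,
    )


def report(results: GroupResults, out_dir: str | Path, plots: bool = True) -> list[Path]:
    """Write tidy result tables, MDS coordinates/plots and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    _write_csv(results.participant_measures, "participant_measures.csv")
    _write_csv(results.rdm_table, "rdms_long.csv")
    _write_csv(results.covariates, "amputee_covariates.csv")
    _write_csv(results.inferential, "inferential_tests.csv")

    boot = results.bootstrap
    boot_df = pd.DataFrame(
        {
            "predictor": list(boot.inclusion_proportion),
            "inclusion_proportion": list(boot.inclusion_proportion.values()),
        }
    )
    boot_df["adj_r2_median"] = boot.adj_r2_median
    boot_df["adj_r2_ci_low"], boot_df["adj_r2_ci_high"] = boot.adj_r2_ci
    _write_csv(boot_df, "bootstrap_stepwise.csv")

    coords_rows = []
    for group, proj in results.projections.items():
        for d, (x, y) in enumerate(proj.mean):
            coords_rows.append(
                {
                    "group": group,
                    "digit": f"D{d + 1}",
                    "x": x,
                    "y": y,
                    "se_x": proj.dispersion[d, 0],
                    "se_y": proj.dispersion[d, 1],
                }
            )
    _write_csv(pd.DataFrame(coords_rows), "mds_group_coordinates.csv")

    if plots and results.projections:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, len(results.projections), figsize=(4 * len(results.projections), 4))
            axes = np.atleast_1d(axes)
            for ax, (group, proj) in zip(axes, results.projections.items()):
                for d in range(proj.mean.shape[0]):
                    ax.errorbar(
                        proj.mean[d, 0], proj.mean[d, 1],
                        xerr=proj.dispersion[d, 0], yerr=proj.dispersion[d, 1],
                        fmt="o",
                    )
                    ax.annotate(f"D{d + 1}", proj.mean[d])
                ax.set_title(group)
                ax.set_aspect("equal")
            fig.tight_layout()
            path = out / "mds_projection.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
        except Exception as exc:  # plotting must never sink a run
            warnings.warn(f"plotting failed: {exc}")

    manifest = {
        "provenance": results.provenance,
        "files": [p.name for p in written],
        "stepwise_included": results.stepwise.included,
        "stepwise_adj_r2": results.stepwise.adj_r2,
        "bayes": {k: v.bf for k, v in results.bayes.items()},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    written.append(mpath)
    return written
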