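"""Simulation studies validating the pipeline's statistical behaviour.

Each experiment generates synthetic studies under stated conditions, runs the
relevant pipeline stage, and summarises parameter recovery or error
calibration.  These are the routines behind the package's reproducibility
checks; they are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from . import ewas, globalmeth as gm, pca_covariates as pca, preprocess as pp, riskmodels as rm
from . import synthdata as sd

TRUE_PER_SD_LOGOR = float(np.log(0.61))


def recovery_experiment(n_reps: int = 200, n_pairs: int = 500, n_probes: int = 300, seed: int = 0):
    """Per-SD effect recovery by conditional logistic regression.

    Simulates matched studies at a true per-SD log odds ratio of ln(0.61),
    estimates the effect on the continuous standardized mean-methylation
    exposure, and reports bias and 95% CI coverage across replicates.
    """
    ann = sd.generate_annotation(n_probes, seed=seed)
    coefs, covered = [], 0
    for r in range(n_reps):
        cfg = sd.SimConfig(
            n_pairs=n_pairs, n_probes=n_probes, seed=seed * 1000 + r, missing_rate=0.0
        )
        beta, sheet = sd.generate_pairs(cfg, ann)
        means = gm.sample_mean_methylation(beta)
        x = (means - means.mean()) / means.std(ddof=1)
        est = rm.clogit_pairs(rm.make_matched_pairs(sheet, x), adjust=("age",))
        coefs.append(est.coef)
        lo, hi = np.log(est.ci[0]), np.log(est.ci[1])
        covered += lo <= TRUE_PER_SD_LOGOR <= hi
    coefs = np.asarray(coefs)
    return {
        "true_logor": TRUE_PER_SD_LOGOR,
        "mean_logor": float(coefs.mean()),
        "bias": float(coefs.mean() - TRUE_PER_SD_LOGOR),
        "mean_or": float(np.exp(coefs.mean())),
        "ci_coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def type1_experiment(n_reps: int = 2000, n_pairs: int = 200, n_probes: int = 150, seed: int = 0):
    """Type-I error of the per-SD Wald test under the complete null.

    Uses the full exposure pipeline: quartiles on controls, quartile-median
    pseudo-continuous standardisation, age-adjusted conditional logistic
    regression.
    """
    ann = sd.generate_annotation(n_probes, seed=seed)
    rejections = 0
    for r in range(n_reps):
        cfg = sd.SimConfig(
            n_pairs=n_pairs,
            n_probes=n_probes,
            seed=seed * 10_000 + r,
            effect_logor_per_sd=0.0,
            missing_rate=0.0,
        )
        beta, sheet = sd.generate_pairs(cfg, ann)
        means = gm.sample_mean_methylation(beta)
        controls = sheet.index[sheet["status"] == "control"]
        labels, _ = gm.quartile_categorize(means, controls)
        expo = gm.pseudo_continuous(labels, means, controls)
        est = rm.clogit_pairs(rm.make_matched_pairs(sheet, expo), adjust=("age",))
        rejections += est.p_value < 0.05
    return {"type1_error": rejections / n_reps, "n_reps": n_reps}


def fwer_experiment(n_reps: int = 500, n_probes: int = 1000, n_pairs: int = 162, seed: int = 0, alpha: float = 0.05):
    """Family-wise error of the Bonferroni-controlled probe-wise scan.

    Complete-null studies; a replicate counts as a family-wise error when the
    scan flags at least one probe at the alpha/n threshold.
    """
    ann = sd.generate_annotation(n_probes, seed=seed)
    hits = 0
    for r in range(n_reps):
        cfg = sd.SimConfig(
            n_pairs=n_pairs,
            n_probes=n_probes,
            seed=seed * 10_000 + 5000 + r,
            effect_logor_per_sd=0.0,
            missing_rate=0.0,
        )
        beta, sheet = sd.generate_pairs(cfg, ann)
        res = ewas.ewas_scan(beta, sheet, alpha=alpha, technical=None)
        hits += res.n_significant > 0
    return {"fwer": hits / n_reps, "n_reps": n_reps}


def batch_experiment(n_sims: int = 100, n_pairs: int = 40, n_probes: int = 500, seed: int = 0):
    """Batch-correction efficacy: offset removal and post-ComBat chip screen.

    Reports (a) the mean percentage reduction of the systematic between-chip
    M-value difference, and (b) the fraction of simulations where the minimum
    chip p over the top three principal components exceeds 0.05 after
    adjustment.
    """
    ann = sd.generate_annotation(n_probes, seed=seed)
    reductions, passes = [], 0
    for s in range(n_sims):
        cfg = sd.SimConfig(
            n_pairs=n_pairs,
            n_probes=n_probes,
            seed=seed * 10_000 + 900 + s,
            missing_rate=0.0,
            batch_count=4,
            batch_sd=0.25,
            effect_logor_per_sd=0.0,
        )
        beta, sheet = sd.generate_pairs(cfg, ann)
        M = pp.beta_to_m(beta.clip(1e-6, 1 - 1e-6))
        # add a known systematic offset to one chip so the injected
        # between-batch mean difference is measurable against truth
        target = sheet["chip_id"] == sorted(sheet["chip_id"].unique())[0]
        M.loc[:, target.index[target]] += 1.0
        Madj = pp.combat_adjust(M, sheet["chip_id"])

        def chip_gap(mat):
            grp = mat.T.groupby(sheet["chip_id"]).mean()  # chips × probes
            first = grp.loc[sorted(grp.index)[0]]
            rest = grp.drop(index=sorted(grp.index)[0]).mean(axis=0)
            return float((first - rest).mean())

        before, after = chip_gap(M), chip_gap(Madj)
        reductions.append(100.0 * (1.0 - abs(after) / abs(before)))
        res = pca.pca_samples(Madj, k=3)
        min_p = pca.pc_covariate_assoc(res.scores, sheet).min_chip_p.min()
        passes += min_p > 0.05
    return {
        "mean_offset_reduction_pct": float(np.mean(reductions)),
        "chip_p_pass_rate": passes / n_sims,
        "n_sims": n_sims,
    }


def study_conditions_experiment(n_reps: int = 20, seed: int = 0):
    """Marginal study-level quantities under the default generator.

    Reports the case-control genome-wide mean-β difference (percentage
    points), the control SD of per-sample means, and the ROC AUC of mean
    methylation for case status (flipped so the hypomethylation signal scores
    above one half, matching how a protective exposure is reported).
    """
    diffs, sds, aucs, wilcoxon_ps = [], [], [], []
    for r in range(n_reps):
        ann = sd.generate_annotation(2000, seed=seed + r)
        cfg = sd.SimConfig(seed=seed * 1000 + r, missing_rate=0.0)
        beta, sheet = sd.generate_pairs(cfg, ann)
        means = gm.sample_mean_methylation(beta)
        case = sheet.index[sheet["status"] == "case"]
        ctrl = sheet.index[sheet["status"] == "control"]
        diffs.append(100.0 * (means[case].mean() - means[ctrl].mean()))
        sds.append(100.0 * means[ctrl].std(ddof=1))
        auc, _ = rm.roc_auc(means.to_numpy(), sheet["status"].to_numpy())
        aucs.append(max(auc, 1.0 - auc))
        pairs = rm.make_matched_pairs(sheet, means)
        _, p = rm.paired_wilcoxon(pairs["case_exposure"], pairs["control_exposure"])
        wilcoxon_ps.append(p)
    return {
        "mean_difference_pp": float(np.mean(diffs)),
        "control_sd_pp": float(np.mean(sds)),
        "auc": float(np.mean(aucs)),
        "median_wilcoxon_p": float(np.median(wilcoxon_ps)),
        "n_reps": n_reps,
    }
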