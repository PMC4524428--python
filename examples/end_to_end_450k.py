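"""End-to-end matched-pair analysis on a synthetic 450k-style study.

Generates a nested case-control study (162 pairs) with the package's default
study conditions, runs the QC chain (missingness filters, kNN imputation,
batch adjustment, type-II peak correction), removes white-cell
discriminating probes, builds the quartile / per-SD exposure, and fits the
matched risk models.
"""

from methrisk import celltype as ct
from methrisk import globalmeth as gm
from methrisk import preprocess as pp
from methrisk import riskmodels as rm
from methrisk import synthdata as sd

# --- generate the study -----------------------------------------------------
ann = sd.generate_annotation(n_probes=2000, seed=1)
cfg = sd.SimConfig(seed=2)  # 162 pairs, OR 0.61 per SD, ~0.2 pp hypomethylation
beta, sheet = sd.generate_pairs(cfg, ann)

# --- QC chain ---------------------------------------------------------------
beta, dropped_probes = pp.filter_probes_by_missingness(beta, 0.20)
beta, dropped_samples = pp.filter_samples_by_missingness(beta, 0.05)
beta, sheet = pp.drop_incomplete_pairs(beta, sheet)
beta = pp.knn_impute(beta, k=10)
M = pp.beta_to_m(beta.clip(1e-6, 1 - 1e-6))
M = pp.combat_adjust(M, sheet["chip_id"])
beta = pp.m_to_beta(M)
beta = pp.peak_correct_type2(beta, ann.loc[beta.index, "design_type"])
ledger = pp.exclusion_ledger(
    cfg.n_probes,
    2 * cfg.n_pairs,
    [("probe missingness >20%", len(dropped_probes), 0), ("sample missingness >5%", 0, len(dropped_samples))],
)
print(f"QC: {ledger.probes_remaining} probes x {ledger.samples_remaining} samples retained")

# --- white-cell discriminating probes ---------------------------------------
panel = sd.generate_reference_panel(ann.loc[beta.index], n_celltypes=7, n_discriminating=100, seed=3)
flt = ct.find_celltype_probes(panel)
beta = ct.remove_probes(beta, flt.union)
print(f"cell-type filter: removed {flt.n_unique} discriminating probes")

# --- exposure and risk models ------------------------------------------------
means = gm.sample_mean_methylation(beta)
controls = sheet.index[sheet["status"] == "control"]
labels, bounds = gm.quartile_categorize(means, controls)
expo = gm.pseudo_continuous(labels, means, controls)

pairs = rm.make_matched_pairs(sheet, expo)
per_sd = rm.clogit_pairs(pairs, adjust=("age",))
lo, hi = per_sd.ci
print(f"per-1-SD OR: {per_sd.odds_ratio:.2f} ({lo:.2f}-{hi:.2f}), p = {per_sd.p_value:.2g}")
# an OR below 1 means higher epigenome-wide methylation is protective

qpairs = rm.make_matched_pairs(sheet, means)
member = {
    status: {p: g.index[g["status"] == status][0] for p, g in sheet.groupby("pair_id")}
    for status in ("case", "control")
}
qpairs["case_quartile"] = [labels[member["case"][p]] for p in qpairs.index]
qpairs["control_quartile"] = [labels[member["control"][p]] for p in qpairs.index]
for q, est in rm.or_by_quartile(qpairs).items():
    lo, hi = est.ci
    print(f"  {q}: OR {est.odds_ratio:.2f}" + ("" if q == "Q1" else f" ({lo:.2f}-{hi:.2f})"))

w, p = rm.paired_wilcoxon(qpairs["case_exposure"], qpairs["control_exposure"])
print(f"paired Wilcoxon on mean methylation: p = {p:.2g}")
# hypomethylation is the risk signal, so score by negated mean methylation
auc, (alo, ahi) = rm.roc_auc((-means).to_numpy(), sheet["status"].to_numpy())
print(f"ROC AUC of hypomethylation for case status: {100 * auc:.0f}% ({100 * alo:.0f}-{100 * ahi:.0f}%)")

x = (means - means.mean()) / means.std(ddof=1)
spline = rm.spline_risk_distribution(x, sheet["status"], sheet["pair_id"], df=4)
print(
    f"individual-risk distribution (spline): 95% RR range "
    f"{spline.rr_lower:.2f}-{spline.rr_upper:.2f}"
)
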