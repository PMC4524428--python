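"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate a matched nested case-control study of blood DNA
methylation measured on a 450k-style array, plus pooled whole-genome
bisulphite sequencing (WGBS) libraries and a purified-white-cell reference
panel.  Every generator is deterministic for a fixed seed.

Generative model for the array data
-----------------------------------
Per-probe baseline methylation is drawn from a three-component mixture on the
natural-logit scale (unmethylated / intermediate / methylated modes), with
mixing weights that depend on the probe's CpG-island relation so islands are
mostly low-β and open-sea/gene-body probes mostly high-β.  Subject values add,
still on the logit scale,

* a per-subject *global methylation offset* — part shared within the pair,
  part individual — scaled by CpG-island relation (islands damped, open
  sea/shelf at full strength), the between-subject epigenome-wide variation
  that the mean-β exposure measures,
* a pair-shared per-probe random effect and independent per-probe subject
  noise (local variation; matched-pair correlation),
* a chip-batch × probe random offset,
* optionally, for cases, an explicit category-specific logit shift.

Case status within a pair is assigned from the conditional-logistic model
``P(member 1 is the case) = expit(b · (x1 − x2))`` where ``x`` is the
standardized per-sample mean β and ``b`` is the target log-odds per 1 SD, so
the injected per-SD effect is exactly the estimand of the downstream matched
analysis.  Because the global offset is damped at islands, the resulting case
hypomethylation concentrates in shelf/open-sea (hence gene-body) probes; at
the default effect size it produces a ≈0.2 percentage-point genome-wide
mean-β deficit in cases.  β values are obtained by the inverse-logit and
therefore always honour ``[0, 1]``; missingness is completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_sample_sheet

ISLAND_CATEGORIES = ("island", "shore", "shelf", "none")

#: Default island-relation weights, approximating array-wide proportions
#: (~31% island, 24% shore, 9% shelf, 36% open sea).
DEFAULT_ISLAND_WEIGHTS = {"island": 0.31, "shore": 0.24, "shelf": 0.09, "none": 0.36}

GENE_REGION_CATEGORIES = (
    "TSS1500",
    "TSS200",
    "5UTR",
    "1stExon",
    "body",
    "3UTR",
    "intergenic",
)

#: Default gene-region weights, approximating the array's feature mix.
DEFAULT_GENE_REGION_WEIGHTS = {
    "TSS1500": 0.146,
    "TSS200": 0.107,
    "5UTR": 0.090,
    "1stExon": 0.047,
    "body": 0.339,
    "3UTR": 0.060,
    "intergenic": 0.211,
}

# Mixture (unmethylated, intermediate, methylated) weights by island relation.
_MIX_WEIGHTS = {
    "island": (0.75, 0.15, 0.10),
    "shore": (0.45, 0.25, 0.30),
    "shelf": (0.15, 0.20, 0.65),
    "none": (0.10, 0.20, 0.70),
}
# Mode centres and jitter SDs on the natural-logit scale.
_MODE_MEANS = (-2.8, 0.0, 2.2)
_MODE_SDS = (0.5, 0.4, 0.5)

# How strongly a subject's global methylation offset acts per island
# relation: islands are tightly regulated (damped inter-individual
# variation), open sea and shelves vary most — concentrating any
# epigenome-wide effect in shelf/open-sea (and hence gene-body) probes.
_GLOBAL_SCALE = {"island": 0.3, "shore": 0.6, "shelf": 1.0, "none": 1.0}


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p):
    return np.log(p / (1.0 - p))


@dataclass
class SimConfig:
    """Study-design parameters for the matched-pair array generator.

    Defaults reflect the design being emulated: 162 analysed case-control
    pairs, a per-SD odds ratio of 0.61 for mean methylation, and a case
    hypomethylation shift concentrated in gene-body/shelf/open-sea probes
    calibrated to a ≈0.2 percentage-point genome-wide mean-β deficit.  The
    probe count is a desk-scale stand-in for the array (the statistics of
    per-sample means stabilise long before array scale).
    """

    n_pairs: int = 162
    n_probes: int = 2000
    effect_logor_per_sd: float = float(np.log(0.61))
    mean_shift_by_category: dict = field(default_factory=dict)
    batch_count: int = 8
    batch_sd: float = 0.10
    missing_rate: float = 0.005
    celltype_count: int = 7
    seed: int = 0
    # Within-pair correlation is not pinned down by the emulated design, so
    # the shared and individual variance scales are exposed as parameters.
    pair_sd: float = 0.15
    noise_sd: float = 0.15
    #: per-subject global methylation offset (logit scale): pair-shared and
    #: individual components; scaled per island relation below
    global_pair_sd: float = 0.008
    global_subject_sd: float = 0.055
    #: 'island_relation' or 'gene_region' — which annotation column the
    #: mean_shift_by_category keys refer to (island-relation shifts also
    #: accept gene-region keys; shifts for both columns are summed).
    shift_scope: str = "both"

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be ≥ 2")
        if self.n_probes < 100:
            raise ValueError("n_probes must be ≥ 100")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.batch_count < 1:
            raise ValueError("batch_count must be ≥ 1")


@dataclass
class ReferencePanel:
    """Purified-cell methylation reference with subject replicates.

    ``beta`` has shape ``(n_cell_types, n_replicates, n_probes)``; the first
    listed cell type may be a pooled baseline (e.g. ``PBMC``).
    """

    cell_types: list
    beta: np.ndarray
    probe_ids: pd.Index

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ValueError("reference panel needs ≥ 2 cell types")
        if np.any((self.beta < 0) | (self.beta > 1)):
            raise ValueError("reference profiles must lie in [0, 1]")

    @property
    def subject_replicates(self) -> int:
        return self.beta.shape[1]

    @property
    def profiles(self) -> pd.DataFrame:
        """Cell-type × probe mean-β profiles (replicate average)."""
        return pd.DataFrame(self.beta.mean(axis=1), index=self.cell_types, columns=self.probe_ids)

    def replicates(self, cell_type: str) -> np.ndarray:
        """Replicate × probe β values for one cell type."""
        return self.beta[self.cell_types.index(cell_type)]


# ---------------------------------------------------------------------------
# Probe annotation


def generate_annotation(
    n_probes: int,
    category_weights: dict | None = None,
    seed: int = 0,
    gene_region_weights: dict | None = None,
    snp_rate: float = 0.001,
    crossreactive_rate: float = 0.083,
    n_chromosomes: int = 22,
) -> pd.DataFrame:
    """Simulate a probe annotation table.

    Each probe gets exactly one island-relation category, one gene-region
    category, an Infinium design type (I/II), strictly increasing coordinates
    within its chromosome, and SNP / cross-reactive exclusion flags.
    """
    rng = np.random.default_rng(seed)
    weights = dict(DEFAULT_ISLAND_WEIGHTS if category_weights is None else category_weights)
    for cat in ISLAND_CATEGORIES:
        weights.setdefault(cat, 0.0)
    w = np.array([weights[c] for c in ISLAND_CATEGORIES], float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("category weights must be nonnegative with positive sum")
    gw_map = dict(DEFAULT_GENE_REGION_WEIGHTS if gene_region_weights is None else gene_region_weights)
    for cat in GENE_REGION_CATEGORIES:
        gw_map.setdefault(cat, 0.0)
    gw = np.array([gw_map[c] for c in GENE_REGION_CATEGORIES], float)
    if np.any(gw < 0) or gw.sum() <= 0:
        raise ValueError("gene-region weights must be nonnegative with positive sum")

    island = rng.choice(ISLAND_CATEGORIES, size=n_probes, p=w / w.sum())
    gene_region = rng.choice(GENE_REGION_CATEGORIES, size=n_probes, p=gw / gw.sum())
    design = np.where(rng.random(n_probes) < 0.28, "I", "II")
    chrom_idx = np.sort(rng.integers(1, n_chromosomes + 1, size=n_probes))
    gaps = rng.integers(100, 50_000, size=n_probes)
    pos = np.empty(n_probes, dtype=int)
    for c in np.unique(chrom_idx):
        mask = chrom_idx == c
        pos[mask] = 10_000 + np.cumsum(gaps[mask])
    ann = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom_idx],
            "pos": pos,
            "design_type": design,
            "island_relation": island,
            "gene_region": gene_region,
            "snp_probe": rng.random(n_probes) < snp_rate,
            "cross_reactive": rng.random(n_probes) < crossreactive_rate,
        },
        index=pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id"),
    )
    return ann


# ---------------------------------------------------------------------------
# Matched-pair β matrices


def _baseline_logits(annotation: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Per-probe mixture baseline on the logit scale."""
    n = len(annotation)
    comp = np.empty(n, dtype=int)
    for cat, mix in _MIX_WEIGHTS.items():
        mask = (annotation["island_relation"] == cat).to_numpy()
        if mask.any():
            comp[mask] = rng.choice(3, size=mask.sum(), p=mix)
    means = np.asarray(_MODE_MEANS)[comp]
    sds = np.asarray(_MODE_SDS)[comp]
    return rng.normal(means, sds)


def _case_shift_vector(cfg: SimConfig, annotation: pd.DataFrame) -> np.ndarray:
    shift = np.zeros(len(annotation))
    for cat, delta in cfg.mean_shift_by_category.items():
        if cat in ISLAND_CATEGORIES and cfg.shift_scope in ("island_relation", "both"):
            shift += np.where(annotation["island_relation"] == cat, delta, 0.0)
        elif cat in GENE_REGION_CATEGORIES and cfg.shift_scope in ("gene_region", "both"):
            shift += np.where(annotation["gene_region"] == cat, delta, 0.0)
        elif cat in ISLAND_CATEGORIES or cat in GENE_REGION_CATEGORIES:
            continue
        else:
            raise ValueError(f"unknown shift category {cat!r}")
    return shift


def generate_pairs(cfg: SimConfig, annotation: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a matched-pair β matrix and its sample sheet.

    Returns ``(beta, sheet)`` where ``beta`` is probes × samples and ``sheet``
    is indexed by sample ID with pair/status/age/follow-up/chip columns.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_probes = len(annotation)
    if n_probes != cfg.n_probes:
        raise ValueError("annotation size does not match cfg.n_probes")
    n_pairs = cfg.n_pairs
    n_samples = 2 * n_pairs

    base = _baseline_logits(annotation, rng)  # (P,)
    pair_eff = rng.normal(0.0, cfg.pair_sd, size=(n_probes, n_pairs))
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_probes, n_samples))

    # whole pairs share a chip (mirrors excluding pairs split across chips)
    batch_of_pair = rng.integers(0, cfg.batch_count, size=n_pairs)
    batch_offsets = rng.normal(0.0, cfg.batch_sd, size=(n_probes, cfg.batch_count))

    # subject-level global methylation offsets, damped at islands
    global_scale = annotation["island_relation"].map(_GLOBAL_SCALE).to_numpy(float)
    g_pair = rng.normal(0.0, cfg.global_pair_sd, size=n_pairs)
    g_subj = rng.normal(0.0, cfg.global_subject_sd, size=n_samples)

    logits = np.empty((n_probes, n_samples))
    for j in range(n_pairs):
        shared = base + pair_eff[:, j] + batch_offsets[:, batch_of_pair[j]]
        logits[:, 2 * j] = shared + noise[:, 2 * j] + global_scale * (g_pair[j] + g_subj[2 * j])
        logits[:, 2 * j + 1] = shared + noise[:, 2 * j + 1] + global_scale * (g_pair[j] + g_subj[2 * j + 1])

    # case assignment from the conditional-logistic model on standardized
    # per-sample mean β (pre-shift)
    beta0 = _expit(logits)
    means = beta0.mean(axis=0)
    sd = means.std(ddof=1)
    x = (means - means.mean()) / sd
    p_first = _expit(cfg.effect_logor_per_sd * (x[0::2] - x[1::2]))
    first_is_case = rng.random(n_pairs) < p_first

    case_col = np.where(first_is_case, 0, 1)
    status = np.full(n_samples, "control", dtype=object)
    status[2 * np.arange(n_pairs) + case_col] = "case"

    shift = _case_shift_vector(cfg, annotation)
    if np.any(shift != 0):
        case_mask = status == "case"
        logits[:, case_mask] += shift[:, None]
    beta = _expit(logits)

    if cfg.missing_rate > 0:
        miss = rng.random(beta.shape) < cfg.missing_rate
        beta[miss] = np.nan

    sample_ids = [f"S{j:04d}_{k}" for j in range(n_pairs) for k in ("a", "b")]
    beta_df = pd.DataFrame(beta, index=annotation.index, columns=sample_ids)

    pair_age = np.clip(rng.normal(52.0, 8.0, size=n_pairs), 35, 70)
    followup = np.clip(rng.normal(8.9, 3.0, size=n_samples), 0.5, 16.0)
    sheet = pd.DataFrame(
        {
            "pair_id": np.repeat([f"P{j:04d}" for j in range(n_pairs)], 2),
            "status": status,
            "age_at_draw": np.round(np.repeat(pair_age, 2), 1),
            "followup": np.round(followup, 2),
            "chip_id": np.repeat([f"chip{b:02d}" for b in batch_of_pair], 2),
            "position_on_chip": rng.integers(1, 13, size=n_samples),
            "menopausal_status": np.where(np.repeat(pair_age, 2) > 51, "post", "pre"),
            "bmi": np.round(rng.normal(25.5, 4.0, size=n_samples), 1),
            "folate": np.round(rng.lognormal(2.6, 0.4, size=n_samples), 1),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    # cases: time to diagnosis equals their follow-up (incident cases)
    sheet["time_to_diagnosis"] = np.where(sheet["status"] == "case", sheet["followup"], np.nan)
    validate_sample_sheet(sheet)
    return beta_df, sheet


# ---------------------------------------------------------------------------
# WGBS pools


def generate_wgbs_pools(
    n_sites: int,
    depth_mean: float = 50.0,
    case_shift: float = 0.0,
    seed: int = 0,
    dispersion: float = 20.0,
    label_case: str = "case_pool",
    label_control: str = "control_pool",
):
    """Generate matched case/control pooled-WGBS coverage tables.

    Per-site sequencing depth is negative-binomial (mean ``depth_mean``, mild
    overdispersion); methylated reads are binomial given the site's true
    methylation.  ``case_shift`` is added to the case pool's true methylation
    fraction at gene-body sites (clipped to ``[0, 1]``).

    Returns ``(case_pool, control_pool, sites)`` where ``sites`` carries the
    per-site annotation (chrom, pos, island_relation, gene_region, true
    methylation) needed to build feature interval sets.
    """
    from .io import WGBSPool

    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    ann = generate_annotation(max(n_sites, 100), seed=seed + 1)
    ann = ann.iloc[:n_sites]
    true_m = np.clip(_expit(_baseline_logits(ann, rng)), 0.01, 0.99)
    body = (ann["gene_region"] == "body").to_numpy()
    case_m = np.clip(true_m + np.where(body, case_shift, 0.0), 0.0, 1.0)

    p_nb = dispersion / (dispersion + depth_mean)
    pools = []
    for label, m in ((label_case, case_m), (label_control, true_m)):
        depth = rng.negative_binomial(dispersion, p_nb, size=n_sites)
        meth = rng.binomial(depth, m)
        keep = depth > 0
        sites = pd.DataFrame(
            {
                "chrom": ann["chrom"].to_numpy()[keep],
                "pos": ann["pos"].to_numpy()[keep],
                "meth_reads": meth[keep],
                "total_reads": depth[keep],
            }
        )
        pools.append(WGBSPool(label, sites))
    site_info = pd.DataFrame(
        {
            "chrom": ann["chrom"].to_numpy(),
            "pos": ann["pos"].to_numpy(),
            "island_relation": ann["island_relation"].to_numpy(),
            "gene_region": ann["gene_region"].to_numpy(),
            "true_methylation": true_m,
        }
    )
    return pools[0], pools[1], site_info


def feature_intervals_from_sites(sites: pd.DataFrame, by: str = "gene_region") -> dict:
    """Build per-category 1-based interval sets covering the listed sites."""
    features = {}
    for cat, grp in sites.groupby(by):
        features[cat] = pd.DataFrame(
            {"chrom": grp["chrom"].to_numpy(), "start": grp["pos"].to_numpy(), "end": grp["pos"].to_numpy()}
        )
    return features


# ---------------------------------------------------------------------------
# Reference panel


def generate_reference_panel(
    annotation: pd.DataFrame,
    n_celltypes: int = 7,
    n_discriminating: int = 500,
    seed: int = 0,
    n_replicates: int = 6,
    noise_sd: float = 0.01,
    delta: float = 0.2,
    include_baseline: bool = True,
) -> ReferencePanel:
    """Generate a purified-cell reference panel with planted markers.

    Exactly ``n_discriminating`` probes carry a cell-type-specific mean shift
    of ``±delta`` relative to the shared base profile (assigned round-robin
    across cell types); all other probes differ only by replicate noise of SD
    ``noise_sd``.  When ``include_baseline`` a pooled ``PBMC`` pseudo-type at
    the base profile is prepended.
    """
    n_probes = len(annotation)
    if n_discriminating > n_probes:
        raise ValueError("n_discriminating exceeds the number of probes")
    rng = np.random.default_rng(seed)
    base = np.clip(_expit(_baseline_logits(annotation, rng)), 0.05, 0.95)

    names = [f"celltype{i + 1}" for i in range(n_celltypes)]
    profiles = np.tile(base, (n_celltypes, 1))
    disc = rng.choice(n_probes, size=n_discriminating, replace=False)
    signs = np.where(base[disc] > 0.5, -1.0, 1.0)  # shift away from the boundary
    owner = np.arange(n_discriminating) % n_celltypes
    for i in range(n_celltypes):
        sel = disc[owner == i]
        profiles[i, sel] = np.clip(base[sel] + delta * signs[owner == i], 0.0, 1.0)

    if include_baseline:
        names = ["PBMC"] + names
        profiles = np.vstack([base, profiles])

    beta = profiles[:, None, :] + rng.normal(0.0, noise_sd, size=(len(names), n_replicates, n_probes))
    beta = np.clip(beta, 0.0, 1.0)
    panel = ReferencePanel(names, beta, annotation.index)
    panel.discriminating_probes = pd.Index(annotation.index[np.sort(disc)])  # planted truth, for checks
    return panel
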