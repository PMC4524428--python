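"""Per-sample epigenome-wide methylation statistics and exposure variables.

The risk exposure of the analysis is a per-sample summary of methylation —
the mean (or median) β over a probe set — categorised into quartiles on the
control distribution and converted to a quartile-median "pseudo-continuous"
variable standardised to per-1-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ISLAND_CATEGORIES = ("island", "shore", "shelf", "none")
PROMOTER_PARTS = ("TSS200", "TSS1500", "5UTR", "1stExon")
QUARTILES = ("Q1", "Q2", "Q3", "Q4")


def sample_mean_methylation(m: pd.DataFrame, subset=None) -> pd.Series:
    """Arithmetic mean β per sample over the (non-missing) probe subset."""
    sub = m if subset is None else m.loc[m.index.intersection(pd.Index(subset))]
    if sub.shape[0] == 0:
        raise ValueError("probe subset is empty")
    return sub.mean(axis=0, skipna=True)


def sample_median_methylation(m: pd.DataFrame, subset=None) -> pd.Series:
    """Median β per sample over the (non-missing) probe subset."""
    sub = m if subset is None else m.loc[m.index.intersection(pd.Index(subset))]
    if sub.shape[0] == 0:
        raise ValueError("probe subset is empty")
    return sub.median(axis=0, skipna=True)


@dataclass
class FeatureSubsets:
    """Probe lists per genomic feature category.

    Island-relation categories partition the probes; the ``promoter``
    gene-region category is the union of TSS200, TSS1500, 5′UTR and 1st exon.
    """

    island_relation: dict
    gene_region: dict
    flags: dict
    all_probes: pd.Index

    def counts(self) -> pd.Series:
        rows = {"all": len(self.all_probes)}
        rows.update({f"island:{k}": len(v) for k, v in self.island_relation.items()})
        rows.update({f"region:{k}": len(v) for k, v in self.gene_region.items()})
        rows.update({f"flag:{k}": len(v) for k, v in self.flags.items()})
        return pd.Series(rows)


def build_feature_subsets(annotation: pd.DataFrame) -> FeatureSubsets:
    """Partition probes by island relation and gene region, with flag lists."""
    unlabeled = annotation.index[~annotation["island_relation"].isin(ISLAND_CATEGORIES)]
    if len(unlabeled):
        raise ValueError(f"probe {unlabeled[0]!r} has no island-relation label")
    island = {c: annotation.index[annotation["island_relation"] == c] for c in ISLAND_CATEGORIES}
    gene = {
        c: annotation.index[annotation["gene_region"] == c]
        for c in annotation["gene_region"].unique()
    }
    promoter_mask = annotation["gene_region"].isin(PROMOTER_PARTS)
    gene["promoter"] = annotation.index[promoter_mask]
    flags = {
        "snp_probe": annotation.index[annotation.get("snp_probe", pd.Series(False, index=annotation.index)).astype(bool)],
        "cross_reactive": annotation.index[annotation.get("cross_reactive", pd.Series(False, index=annotation.index)).astype(bool)],
    }
    return FeatureSubsets(island, gene, flags, annotation.index)


def quartile_categorize(values: pd.Series, control_ids):
    """Label all samples by quartiles of the control distribution.

    Boundaries are the linear-interpolation sample quartiles of the control
    values; every sample (case or control) is labelled against those
    boundaries, with boundary ties broken toward the lower quartile.

    Returns ``(labels, boundaries)``.
    """
    controls = values.loc[control_ids]
    if len(controls) < 4:
        raise ValueError("need at least 4 controls to form quartiles")
    if controls.nunique() == 1:
        raise ValueError("degenerate control distribution (zero variance)")
    b1, b2, b3 = np.quantile(controls.to_numpy(float), [0.25, 0.5, 0.75])
    v = values.to_numpy(float)
    labels = np.select([v <= b1, v <= b2, v <= b3], ["Q1", "Q2", "Q3"], default="Q4")
    return pd.Series(labels, index=values.index, name="quartile"), (b1, b2, b3)


def pseudo_continuous(
    labels: pd.Series,
    values: pd.Series,
    control_ids,
    sd_scope: str = "controls",
) -> pd.Series:
    """Quartile-median pseudo-continuous exposure in per-1-SD units.

    Each sample's exposure is the median of its quartile's *control* values,
    then centred and standardised by the mean and SD of the per-sample
    summary distribution.  ``sd_scope='controls'`` (default) uses control
    samples only so the exposure scale is defined without reference to
    outcome; ``'all'`` uses every sample.
    """
    controls = values.loc[control_ids]
    medians = {}
    for q in QUARTILES:
        in_q = controls.loc[labels.loc[control_ids] == q]
        if in_q.empty:
            raise ValueError(f"quartile {q} has no control samples")
        medians[q] = float(in_q.median())
    ref = controls if sd_scope == "controls" else values
    mu, sd = float(ref.mean()), float(ref.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance in the reference distribution")
    exposure = labels.map(medians).astype(float)
    return (exposure - mu) / sd
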