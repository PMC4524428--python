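"""Coverage-weighted summaries of pooled-WGBS methylation.

Raw average methylation across CpG sites depends on sequencing coverage, so
per-site methylation fractions are combined with coverage-dependent weights:
a site at or above the pool's median coverage gets full weight 1, and the
weight drops by 0.1 for each complete 10%-of-median decrement below the
median (0.9, 0.8, …), floored at 0.  The weighted mean over a site set is
``Σ mᵢ wᵢ / Σ wᵢ``.

The pool median coverage is computed once over all sites in the pool, before
any feature subsetting.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

from .io import WGBSPool


def coverage_weight(coverage, median_coverage, mode: str = "completed"):
    """Weight(s) for site coverage relative to the pool median.

    ``mode='completed'`` (default) counts complete 10%-of-median decrements
    below the median; ``mode='started'`` already penalises a started
    decrement.  Coverage equal to the median gets full weight.  Exact
    rational arithmetic is used so decrement boundaries are never blurred by
    floating point.
    """
    if median_coverage <= 0:
        raise ValueError("median coverage must be positive")
    scalar = np.isscalar(coverage)
    cov = np.atleast_1d(np.asarray(coverage))
    if np.any(cov < 0):
        raise ValueError("negative coverage")
    med = Fraction(median_coverage).limit_denominator(10**6)
    weights = np.ones(len(cov), float)
    below = cov < float(med)
    for idx in np.nonzero(below)[0]:
        frac_below = (med - Fraction(int(cov[idx]))) / med  # fraction of median below it
        decs = frac_below / Fraction(1, 10)
        if mode == "completed":
            k = int(decs)  # floor
        elif mode == "started":
            k = int(decs) if decs == int(decs) else int(decs) + 1
        else:
            raise ValueError("mode must be 'completed' or 'started'")
        weights[idx] = max(0.0, 1.0 - 0.1 * k)
    return float(weights[0]) if scalar else weights


def weighted_mean(methylation, coverage, median_coverage, mode: str = "completed") -> float:
    """Coverage-weighted mean methylation over a set of sites."""
    m = np.asarray(methylation, float)
    w = np.atleast_1d(coverage_weight(coverage, median_coverage, mode=mode))
    if w.sum() == 0:
        raise ValueError("all site weights are zero")
    return float(np.sum(m * w) / np.sum(w))


def pool_median_coverage(pool: WGBSPool) -> float:
    """Median read depth over all sites in the pool."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    return float(np.median(pool.sites["total_reads"].to_numpy()))


def _sites_in_intervals(sites: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of pool sites contained in any 1-based inclusive interval."""
    mask = np.zeros(len(sites), dtype=bool)
    for chrom, ivals in intervals.groupby("chrom"):
        on_chrom = np.nonzero((sites["chrom"] == chrom).to_numpy())[0]
        if len(on_chrom) == 0:
            continue
        pos = sites["pos"].to_numpy()[on_chrom]
        order = np.argsort(pos)
        sorted_pos = pos[order]
        hit = np.zeros(len(pos), dtype=bool)
        # convert inclusive [start, end] to half-open [start, end+1) for searchsorted
        for start, end in zip(ivals["start"].to_numpy(), ivals["end"].to_numpy()):
            lo = np.searchsorted(sorted_pos, start, side="left")
            hi = np.searchsorted(sorted_pos, end + 1, side="left")
            hit[order[lo:hi]] = True
        mask[on_chrom] = hit
    return mask


def summarize_by_feature(pool: WGBSPool, features: dict, mode: str = "completed") -> pd.DataFrame:
    """Coverage-weighted mean methylation per genomic feature set.

    *features* maps labels to interval tables (``chrom``, ``start``, ``end``,
    1-based inclusive).  The weighting median is the pool-wide median
    coverage.  Features containing no sites are reported with ``n_sites=0``
    and an undefined (NaN) mean.
    """
    med = pool_median_coverage(pool)
    meth = pool.methylation
    cov = pool.sites["total_reads"].to_numpy()
    rows = []
    for label, intervals in features.items():
        mask = _sites_in_intervals(pool.sites, intervals)
        n_sites = int(mask.sum())
        if n_sites == 0:
            rows.append({"feature": label, "n_sites": 0, "weighted_mean": np.nan, "median_coverage": med})
            continue
        wm = weighted_mean(meth[mask], cov[mask], med, mode=mode)
        rows.append({"feature": label, "n_sites": n_sites, "weighted_mean": wm, "median_coverage": med})
    return pd.DataFrame(rows).set_index("feature")


def subset_to_array_sites(pool: WGBSPool, array_positions: pd.DataFrame) -> WGBSPool:
    """Restrict a pool to CpG sites at listed array coordinates.

    *array_positions* has columns ``chrom`` and ``pos``.
    """
    keys = pd.MultiIndex.from_frame(array_positions[["chrom", "pos"]])
    site_keys = pd.MultiIndex.from_frame(pool.sites[["chrom", "pos"]])
    keep = site_keys.isin(keys)
    return WGBSPool(pool.label, pool.sites.loc[keep].reset_index(drop=True), pool.pathology_subgroup)


def pool_contrast(case_pools, control_pools, features: dict, mode: str = "completed") -> pd.DataFrame:
    """Case-minus-control weighted-mean methylation per feature, in % points.

    Each pool contributes its own coverage-weighted feature means (with its
    own pool-wide median); pools within an arm are averaged unweighted.
    """
    def arm_means(pools):
        tables = [summarize_by_feature(p, features, mode=mode) for p in pools]
        return pd.concat([t["weighted_mean"] for t in tables], axis=1).mean(axis=1)

    case_mean = arm_means(case_pools)
    control_mean = arm_means(control_pools)
    out = pd.DataFrame(
        {
            "case_mean_pct": 100.0 * case_mean,
            "control_mean_pct": 100.0 * control_mean,
            "difference_pp": 100.0 * (case_mean - control_mean),
        }
    )
    out.index.name = "feature"
    return out
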