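"""QC and normalisation chain for 450k-style β matrices.

Stages mirror the pre-processing of a matched nested case-control array
study: an auditable probe/sample exclusion ledger, missingness filters,
k-nearest-neighbour imputation, empirical-Bayes location/scale batch
adjustment on M-values, and peak-based alignment of Infinium type-II probe
distributions to type I.

"Not detected" is operationalised as the missing-value fraction: detection
p-values need raw intensities, and the downstream arithmetic is identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.impute import KNNImputer

from .io import log_stage

_EPS = 1e-6


def beta_to_m(beta):
    """M = log2(β / (1 − β)); β must lie strictly inside (0, 1)."""
    beta = np.asarray(beta, float) if not isinstance(beta, (pd.DataFrame, pd.Series)) else beta
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    m = np.asarray(m, float) if not isinstance(m, (pd.DataFrame, pd.Series)) else m
    return 1.0 / (1.0 + 2.0 ** (-m))


# ---------------------------------------------------------------------------
# Exclusion ledger


@dataclass
class LedgerStep:
    label: str
    probes_removed: int
    samples_removed: int
    probes_remaining: int
    samples_remaining: int


@dataclass
class ExclusionLedger:
    """Sequential record of probe/sample exclusions.

    Remaining counts decrease by exactly the removed counts at every step, so
    the ledger always reconciles with the final matrix dimensions.
    """

    initial_probes: int
    initial_samples: int
    steps: list

    @property
    def probes_remaining(self) -> int:
        return self.steps[-1].probes_remaining if self.steps else self.initial_probes

    @property
    def samples_remaining(self) -> int:
        return self.steps[-1].samples_remaining if self.steps else self.initial_samples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def check_against(self, m: pd.DataFrame) -> None:
        """Raise if the ledger totals disagree with a matrix's shape."""
        if m.shape != (self.probes_remaining, self.samples_remaining):
            raise ValueError(
                f"ledger says {self.probes_remaining}×{self.samples_remaining}, "
                f"matrix is {m.shape[0]}×{m.shape[1]}"
            )


def exclusion_ledger(initial_probes: int, initial_samples: int, steps) -> ExclusionLedger:
    """Build a ledger from ``(label, probes_removed, samples_removed)`` steps."""
    probes, samples = initial_probes, initial_samples
    rows = []
    for label, p_rm, s_rm in steps:
        if p_rm < 0 or s_rm < 0:
            raise ValueError(f"step {label!r}: negative removal count")
        if p_rm > probes or s_rm > samples:
            raise ValueError(f"step {label!r}: removal exceeds remaining counts")
        probes -= p_rm
        samples -= s_rm
        rows.append(LedgerStep(label, p_rm, s_rm, probes, samples))
    return ExclusionLedger(initial_probes, initial_samples, rows)


# ---------------------------------------------------------------------------
# Missingness filters and pair completion


def filter_probes_by_missingness(m: pd.DataFrame, threshold: float = 0.20):
    """Drop probes with missing fraction strictly greater than *threshold*."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    frac = m.isna().mean(axis=1)
    removed = list(m.index[frac > threshold])
    out = m.drop(index=removed)
    log_stage("filter_probes_by_missingness", removed=len(removed), remaining=out.shape[0])
    return out, removed


def filter_samples_by_missingness(m: pd.DataFrame, threshold: float = 0.05):
    """Drop samples with missing fraction strictly greater than *threshold*."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    frac = m.isna().mean(axis=0)
    removed = list(m.columns[frac > threshold])
    out = m.drop(columns=removed)
    log_stage("filter_samples_by_missingness", removed=len(removed), remaining=out.shape[1])
    return out, removed


def drop_incomplete_pairs(m: pd.DataFrame, sheet: pd.DataFrame):
    """Keep only samples whose matched partner is still present in *m*."""
    present = sheet.loc[sheet.index.intersection(m.columns)]
    counts = present.groupby("pair_id")["status"].nunique()
    sizes = present.groupby("pair_id").size()
    complete = counts.index[(sizes == 2) & (counts == 2)]
    keep = present.index[present["pair_id"].isin(complete)]
    out_m = m[[c for c in m.columns if c in set(keep)]]
    out_sheet = sheet.loc[keep]
    log_stage("drop_incomplete_pairs", removed=m.shape[1] - out_m.shape[1], remaining=out_m.shape[1])
    return out_m, out_sheet


# ---------------------------------------------------------------------------
# kNN imputation


def knn_impute(m: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing β as the mean of the k nearest probes.

    Neighbours are probes (rows), with distances computed on shared samples
    (nan-aware Euclidean).  Observed values are left untouched.
    """
    if not m.isna().to_numpy().any():
        return m.copy()
    n_complete = int((~m.isna().any(axis=1)).sum())
    if n_complete < k:
        raise ValueError(f"only {n_complete} complete neighbour probes available, need k={k}")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    values = imputer.fit_transform(m.to_numpy(float))
    out = pd.DataFrame(values, index=m.index, columns=m.columns)
    log_stage("knn_impute", imputed=int(m.isna().to_numpy().sum()), k=k)
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment (location/scale model on M-values)


def combat_adjust(m_values: pd.DataFrame, batch, max_iter: int = 200, conv: float = 1e-4) -> pd.DataFrame:
    """Remove additive/multiplicative batch effects by parametric empirical Bayes.

    Implements the classic location/scale model: per-probe standardisation
    against the batch-design fit, normal prior on batch means and
    inverse-gamma prior on batch variances (hyperparameters by method of
    moments), posterior estimates found by the usual fixed-point iteration,
    then shrunken batch effects removed and the data rescaled.  After
    adjustment each probe is recentred so its pooled mean is preserved
    exactly.

    Parameters
    ----------
    m_values : probes × samples matrix on the M-value scale (no missing).
    batch : per-sample batch labels aligned with the columns.
    """
    batch = np.asarray(pd.Series(batch, index=m_values.columns) if not isinstance(batch, pd.Series) else batch.loc[m_values.columns])
    if m_values.isna().to_numpy().any():
        raise ValueError("batch adjustment requires a complete matrix; impute first")
    levels, inv = np.unique(batch, return_inverse=True)
    if len(levels) == 1:
        return m_values.copy()
    counts = np.bincount(inv)
    if counts.min() < 2:
        bad = levels[counts.argmin()]
        raise ValueError(f"batch {bad!r} has a single sample; cannot estimate its effect")

    Y = m_values.to_numpy(float)
    n_probes, n = Y.shape
    k = len(levels)
    n_i = counts.astype(float)

    batch_means = np.stack([Y[:, inv == b].mean(axis=1) for b in range(k)], axis=1)  # G × k
    alpha = batch_means @ (n_i / n)  # grand (pooled) mean per probe
    resid = Y - batch_means[:, inv]
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sigma = np.sqrt(var_pooled)

    Z = (Y - alpha[:, None]) / sigma[:, None]

    gamma_hat = np.stack([Z[:, inv == b].mean(axis=1) for b in range(k)], axis=1)
    delta_hat = np.stack([Z[:, inv == b].var(axis=1, ddof=1) for b in range(k)], axis=1)
    delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_bar = gamma_hat.mean(axis=0)
    t2 = gamma_hat.var(axis=0, ddof=1)
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    a_prior = (2 * d_var + d_mean**2) / d_var
    b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for b in range(k):
        Zb = Z[:, inv == b]
        nb = n_i[b]
        g_old = gamma_hat[:, b].copy()
        d_old = delta_hat[:, b].copy()
        for _ in range(max_iter):
            g_new = (t2[b] * nb * gamma_hat[:, b] + d_old * gamma_bar[b]) / (t2[b] * nb + d_old)
            ss = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * ss + b_prior[b]) / (nb / 2.0 + a_prior[b] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-8)),
                np.max(np.abs(d_new - d_old) / d_old),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        gamma_star[:, b] = g_old
        delta_star[:, b] = d_old

    Z_adj = (Z - gamma_star[:, inv]) / np.sqrt(delta_star[:, inv])
    Y_adj = Z_adj * sigma[:, None] + alpha[:, None]
    # preserve each probe's pooled mean exactly
    Y_adj += (alpha - Y_adj.mean(axis=1))[:, None]
    return pd.DataFrame(Y_adj, index=m_values.index, columns=m_values.columns)


# ---------------------------------------------------------------------------
# Peak-based type-II correction


class ModeDetectionError(RuntimeError):
    pass


def _density_modes(mvals: np.ndarray, bandwidth: float, min_sep: float):
    """Locate the unmethylated/methylated density modes of an M-value sample.

    Binned Gaussian kernel density (fixed absolute bandwidth); returns the two
    highest well-separated local maxima, sorted (lower, upper).
    """
    lo, hi = -10.0, 10.0
    step = 0.02
    grid = np.arange(lo, hi + step, step)
    hist, _ = np.histogram(np.clip(mvals, lo, hi), bins=np.append(grid - step / 2, grid[-1] + step / 2))
    dens = gaussian_filter1d(hist.astype(float), sigma=bandwidth / step)
    interior = np.arange(1, len(grid) - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    peaks = interior[is_max]
    if len(peaks) == 0:
        raise ModeDetectionError("no density mode found")
    order = peaks[np.argsort(dens[peaks])[::-1]]
    top = order[0]
    second = next((p for p in order[1:] if abs(grid[p] - grid[top]) >= min_sep), None)
    if second is None:
        raise ModeDetectionError("only one well-separated density mode found")
    lo_m, hi_m = sorted((grid[top], grid[second]))
    return lo_m, hi_m


def peak_correct_type2(
    m: pd.DataFrame,
    design_types,
    bandwidth: float = 0.5,
    min_sep: float = 2.0,
) -> pd.DataFrame:
    """Align Infinium type-II β distributions to type I, per sample.

    On the M-value scale the unmethylated and methylated modes are located
    separately for type I and type II probes; type II values are linearly
    rescaled so its two modes coincide with type I's.  Type I probes are
    returned unchanged.
    """
    design = pd.Series(design_types, index=m.index) if not isinstance(design_types, pd.Series) else design_types.loc[m.index]
    t1 = design == "I"
    t2 = design == "II"
    if not t1.any() or not t2.any():
        raise ValueError("both Infinium design types must be present")
    beta = m.to_numpy(float)
    clipped = np.clip(beta, _EPS, 1 - _EPS)
    M = np.log2(clipped / (1 - clipped))
    out = beta.copy()
    t1v = t1.to_numpy()
    t2v = t2.to_numpy()
    for j, sample in enumerate(m.columns):
        m1 = M[t1v, j]
        m2 = M[t2v, j]
        m1 = m1[np.isfinite(m1)]
        m2o = m2[np.isfinite(m2)]
        try:
            u1, hi1 = _density_modes(m1, bandwidth, min_sep)
            u2, hi2 = _density_modes(m2o, bandwidth, min_sep)
        except ModeDetectionError as exc:
            raise ModeDetectionError(f"sample {sample!r}: {exc}") from exc
        scale = (hi1 - u1) / (hi2 - u2)
        m2_corr = u1 + (m2 - u2) * scale
        with np.errstate(over="ignore"):
            out[t2v, j] = np.where(np.isfinite(m2_corr), 1.0 / (1.0 + 2.0 ** (-m2_corr)), np.nan)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def apply_type2_normalization(m: pd.DataFrame, design_types, normalizer=None, **kwargs) -> pd.DataFrame:
    """Normalisation hook: apply *normalizer* (default: peak correction).

    Any callable with the signature ``f(beta_matrix, design_types, **kwargs)``
    returning a β matrix may be substituted (e.g. a quantile-mixture method).
    """
    normalizer = peak_correct_type2 if normalizer is None else normalizer
    return normalizer(m, design_types, **kwargs)
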