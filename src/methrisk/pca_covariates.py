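"""Sample-space PCA of methylation profiles and covariate screening.

PCA is run on the samples (the transpose of the probe × sample M-value
matrix, probes centred), and each of the leading components is screened for
association with subject covariates and chip indicators — a batch-effect and
confounding diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × components
    variance_fractions: np.ndarray
    components: np.ndarray  # components × probes (loadings)


def pca_samples(m_values: pd.DataFrame, k: int = 3) -> PCAResult:
    """Principal components of the samples from a complete M-value matrix.

    Probes are centred; sample scores and the per-component fractions of
    total variance are returned for the top *k* components.
    """
    if m_values.isna().to_numpy().any():
        raise ValueError("matrix has missing values; run knn_impute first")
    X = m_values.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)  # centre each probe
    # SVD of the samples × probes matrix
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = min(k, len(s))
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=m_values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(scores, frac[:k], Vt[:k])


def _slope_p(score: np.ndarray, x: np.ndarray) -> float:
    mask = np.isfinite(x) & np.isfinite(score)
    if mask.sum() < 3 or np.nanstd(x[mask]) == 0:
        return np.nan
    return float(stats.linregress(x[mask], score[mask]).pvalue)


@dataclass
class PCAssociationTable:
    """Per-(PC, covariate) association p-values plus chip diagnostics."""

    p_values: pd.DataFrame  # rows: covariate (or covariate=level), cols: PCs
    min_chip_p: pd.Series  # per PC, minimum p over chip indicators
    variance_fractions: pd.Series


def pc_covariate_assoc(
    scores: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates=None,
    chip_col: str = "chip_id",
    variance_fractions=None,
) -> PCAssociationTable:
    """Screen principal-component scores against subject covariates and chips.

    Continuous covariates use the linear-regression slope p-value; categorical
    covariates are tested per non-reference level (indicator regression); the
    chip column contributes the minimum p over its per-chip indicators.
    Constant covariates are flagged with an undefined (NaN) p.
    """
    sheet = sheet.loc[scores.index]
    if covariates is None:
        covariates = [c for c in sheet.columns if c not in (chip_col, "pair_id")]
    rows = {}
    for cov in covariates:
        col = sheet[cov]
        if pd.api.types.is_numeric_dtype(col):
            rows[cov] = [_slope_p(scores[pc].to_numpy(float), col.to_numpy(float)) for pc in scores.columns]
        else:
            levels = pd.unique(col.dropna())
            if len(levels) < 2:
                rows[cov] = [np.nan] * scores.shape[1]
                continue
            ref = levels[0]
            for level in levels[1:]:
                indicator = (col == level).astype(float).to_numpy()
                rows[f"{cov}={level} (vs {ref})"] = [
                    _slope_p(scores[pc].to_numpy(float), indicator) for pc in scores.columns
                ]
    p_values = pd.DataFrame(rows, index=scores.columns).T

    min_chip = pd.Series(np.nan, index=scores.columns)
    if chip_col in sheet.columns and sheet[chip_col].nunique() > 1:
        chips = pd.unique(sheet[chip_col])
        for pc in scores.columns:
            ps = [
                _slope_p(scores[pc].to_numpy(float), (sheet[chip_col] == chip).astype(float).to_numpy())
                for chip in chips
            ]
            min_chip[pc] = np.nanmin(ps)
    if variance_fractions is None:
        var_frac = pd.Series(np.nan, index=scores.columns)
    else:
        var_frac = pd.Series(np.asarray(variance_fractions)[: scores.shape[1]], index=scores.columns)
    return PCAssociationTable(p_values, min_chip, var_frac)
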