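"""White-blood-cell composition handling.

Whole-blood methylation mixes signals from heterogeneous leukocyte types.
Two complementary strategies are provided: (a) identify probes that
discriminate purified cell types from a pooled baseline and drop them from
the analysis; (b) estimate per-sample cell proportions by constrained
projection on reference profiles (reference-based deconvolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthdata import ReferencePanel


@dataclass
class CellTypeFilterResult:
    """Probes flagged as cell-type discriminating.

    ``stats`` maps each cell type to a per-probe table with columns
    ``p_value``, ``delta_beta`` and ``flagged``; ``per_type`` holds the
    flagged probe lists and ``union`` their set union.
    """

    per_type: dict
    union: pd.Index
    stats: dict

    @property
    def n_unique(self) -> int:
        return len(self.union)


def _two_group_regression(group: np.ndarray, baseline: np.ndarray):
    """Per-probe simple linear regression of β on a group indicator.

    With a binary regressor this is the pooled-variance two-sample t-test;
    the vectorised closed form is used.  Arrays are replicate × probe.
    """
    n1, n0 = group.shape[0], baseline.shape[0]
    if n1 < 2 or n0 < 2:
        raise ValueError("need ≥ 2 replicates per group")
    m1, m0 = group.mean(axis=0), baseline.mean(axis=0)
    v1 = group.var(axis=0, ddof=1)
    v0 = baseline.var(axis=0, ddof=1)
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m0) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 1.0)
    return m1 - m0, p


def find_celltype_probes(
    panel: ReferencePanel,
    p_threshold: float = 1e-7,
    delta_threshold: float = 0.05,
    baseline: str | None = "PBMC",
) -> CellTypeFilterResult:
    """Flag probes discriminating each purified type from the baseline.

    A probe is flagged for a cell type when the two-group regression p-value
    is below ``p_threshold`` AND the absolute mean β difference exceeds
    ``delta_threshold``.  ``baseline=None`` uses the replicate-wise panel
    average as the comparison group.
    """
    if baseline is not None and baseline in panel.cell_types:
        base = panel.replicates(baseline)
        types = [t for t in panel.cell_types if t != baseline]
    else:
        base = panel.beta.mean(axis=0)
        types = list(panel.cell_types)

    per_type, stat_tables = {}, {}
    for t in types:
        delta, p = _two_group_regression(panel.replicates(t), base)
        flagged = (p < p_threshold) & (np.abs(delta) > delta_threshold)
        tab = pd.DataFrame({"p_value": p, "delta_beta": delta, "flagged": flagged}, index=panel.probe_ids)
        per_type[t] = panel.probe_ids[flagged]
        stat_tables[t] = tab
    union_mask = np.zeros(len(panel.probe_ids), dtype=bool)
    for probes in per_type.values():
        union_mask |= panel.probe_ids.isin(probes)
    return CellTypeFilterResult(per_type, panel.probe_ids[union_mask], stat_tables)


def remove_probes(m: pd.DataFrame, probes) -> pd.DataFrame:
    """Drop the listed probes from a β matrix (set difference on probes)."""
    out = m.drop(index=[p for p in probes if p in m.index])
    if out.shape[0] == 0:
        raise ValueError("probe removal would empty the matrix")
    return out


def estimate_cell_proportions(sample_beta, profiles: pd.DataFrame):
    """Estimate cell proportions by constrained least squares.

    Solves ``min ||P^T w − y||²`` subject to ``w ≥ 0`` and ``Σw ≤ 1``, where
    ``P`` holds cell-type × probe reference mean profiles restricted to
    discriminating probes and ``y`` is the sample's β vector on the same
    probes.

    Returns ``(proportions, residual_norm)``.
    """
    y = np.asarray(sample_beta, float)
    P = profiles.to_numpy(float)  # types × probes
    k, n = P.shape
    if n < k:
        raise ValueError("need at least as many probes as cell types")
    A = P.T  # probes × types
    if np.linalg.matrix_rank(A) < k:
        raise ValueError("reference profiles are rank deficient")
    w0, _ = optimize.nnls(A, y)
    if w0.sum() > 1:
        w0 = w0 / w0.sum()
    res = optimize.minimize(
        lambda w: 0.5 * np.sum((A @ w - y) ** 2),
        w0,
        jac=lambda w: A.T @ (A @ w - y),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones_like(w)}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    w = np.clip(res.x, 0.0, None)
    residual_norm = float(np.linalg.norm(A @ w - y))
    return pd.Series(w, index=profiles.index, name="proportion"), residual_norm
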