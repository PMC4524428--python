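"""Cross-study meta-analysis of per-1-SD odds ratios.

Study effects arrive as odds ratios with 95% confidence intervals; the log
odds ratio and its standard error are recovered from the CI, combined by
inverse-variance fixed-effect and DerSimonian–Laird random-effects models,
and heterogeneity is assessed with Cochran's Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959964


@dataclass
class StudyEffect:
    """One study's per-1-SD odds ratio with its 95% CI and sample sizes."""

    label: str
    odds_ratio: float
    lower95: float
    upper95: float
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lower95 <= self.odds_ratio <= self.upper95):
            raise ValueError(
                f"study {self.label!r}: CI ordering violated "
                f"({self.lower95}, {self.odds_ratio}, {self.upper95})"
            )


def ci_to_se(effect: StudyEffect):
    """Recover ``(log OR, SE)`` from the 95% CI (symmetric on the log scale).

    A zero-width CI yields SE 0, flagged degenerate by downstream checks.
    """
    log_or = float(np.log(effect.odds_ratio))
    se = float((np.log(effect.upper95) - np.log(effect.lower95)) / (2.0 * Z95))
    return log_or, se


def cochran_q(log_ors, ses):
    """Cochran's Q heterogeneity test over study log odds ratios.

    Returns ``(Q, df, p)`` with ``p`` from the chi-square on k−1 df.
    """
    theta = np.asarray(log_ors, float)
    se = np.asarray(ses, float)
    if len(theta) < 2:
        raise ValueError("need ≥ 2 studies")
    if np.any(se <= 0):
        raise ValueError("degenerate study SE (≤ 0)")
    w = 1.0 / se**2
    theta_fe = np.sum(w * theta) / np.sum(w)
    Q = float(np.sum(w * (theta - theta_fe) ** 2))
    df = len(theta) - 1
    return Q, df, float(stats.chi2.sf(Q, df))


@dataclass
class MetaResult:
    """Random-effects (DerSimonian–Laird) summary with fixed-effect companion."""

    tau2: float
    log_or: float
    se: float
    fixed_log_or: float
    fixed_se: float
    Q: float
    df: int
    p_heterogeneity: float

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci(self):
        return (float(np.exp(self.log_or - Z95 * self.se)), float(np.exp(self.log_or + Z95 * self.se)))

    @property
    def fixed_ci(self):
        return (
            float(np.exp(self.fixed_log_or - Z95 * self.fixed_se)),
            float(np.exp(self.fixed_log_or + Z95 * self.fixed_se)),
        )


def dersimonian_laird(log_ors, ses) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of study log odds ratios.

    ``tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`` with inverse-variance
    fixed-effect weights ``w``; random-effects weights are
    ``1 / (SE² + tau²)``.
    """
    theta = np.asarray(log_ors, float)
    se = np.asarray(ses, float)
    Q, df, p_het = cochran_q(theta, se)
    w = 1.0 / se**2
    sw = w.sum()
    denom = sw - (w**2).sum() / sw
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    w_fe = w
    fixed = float(np.sum(w_fe * theta) / sw)
    fixed_se = float(np.sqrt(1.0 / sw))
    w_re = 1.0 / (se**2 + tau2)
    summary = float(np.sum(w_re * theta) / w_re.sum())
    summary_se = float(np.sqrt(1.0 / w_re.sum()))
    return MetaResult(tau2, summary, summary_se, fixed, fixed_se, Q, df, p_het)


def forest_table(effects, result: MetaResult | None = None) -> pd.DataFrame:
    """Forest-plot-shaped table: one row per study plus the pooled summary."""
    effects = list(effects)
    if result is None:
        pairs = [ci_to_se(e) for e in effects]
        result = dersimonian_laird([t for t, _ in pairs], [s for _, s in pairs])
    rows = [
        {
            "study": e.label,
            "odds_ratio": e.odds_ratio,
            "lower95": e.lower95,
            "upper95": e.upper95,
            "n_cases": e.n_cases,
            "n_controls": e.n_controls,
        }
        for e in effects
    ]
    lo, hi = result.ci
    rows.append(
        {
            "study": "Summary (random effects)",
            "odds_ratio": result.odds_ratio,
            "lower95": lo,
            "upper95": hi,
            "n_cases": sum(e.n_cases or 0 for e in effects) or None,
            "n_controls": sum(e.n_controls or 0 for e in effects) or None,
        }
    )
    return pd.DataFrame(rows).set_index("study")
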