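"""Matched-pair risk models for a methylation exposure.

The central estimator is 1:1 conditional logistic regression: for pair *i*
with case covariates ``x_i^case`` and control covariates ``x_i^ctrl`` the
conditional likelihood contribution is ``expit(d_i' β)`` with
``d_i = x_i^case − x_i^ctrl``, i.e. a no-intercept binary logistic fit on
within-pair differences with the outcome fixed at 1.  Age adjustment enters
as the within-pair age difference (controls are matched to within a few
years, leaving residual differences).

Companions: quartile odds ratios, pair-clustered robust logistic regression
(a confirmation analysis), the paired Wilcoxon signed-rank test, a cubic
B-spline conditional-logistic risk-distribution model, ROC/AUC with DeLong
confidence intervals, stratified analyses with Cochran's Q heterogeneity,
and the two-sample Kolmogorov–Smirnov comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

Z95 = 1.959964

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


class SeparationError(RuntimeError):
    """Complete separation: the conditional likelihood has no finite maximum."""


@dataclass
class EffectEstimate:
    """A log-odds-ratio estimate with Wald inference."""

    term: str
    coef: float
    se: float
    n_pairs: int
    n_informative: int
    flags: tuple = ()

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.coef))

    @property
    def ci(self) -> tuple:
        return (float(np.exp(self.coef - Z95 * self.se)), float(np.exp(self.coef + Z95 * self.se)))

    @property
    def p_value(self) -> float:
        if not np.isfinite(self.se) or self.se == 0:
            return np.nan
        return float(2.0 * stats.norm.sf(abs(self.coef) / self.se))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.ci
        return (
            f"EffectEstimate({self.term}: OR={self.odds_ratio:.3f} "
            f"[{lo:.3f}, {hi:.3f}], p={self.p_value:.3g}, pairs={self.n_pairs})"
        )


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    p_value: float


def make_matched_pairs(sheet: pd.DataFrame, exposure: pd.Series, extra_cols=()) -> pd.DataFrame:
    """Reshape a sample sheet + per-sample exposure to one row per pair.

    Columns: ``case_exposure``, ``control_exposure``, ``case_age``,
    ``control_age`` plus, for each requested extra column, the pair-level
    value taken from the case member (e.g. time-to-diagnosis, ER status).
    """
    rows = {}
    for pair_id, grp in sheet.groupby("pair_id"):
        case = grp.index[grp["status"] == "case"][0]
        ctrl = grp.index[grp["status"] == "control"][0]
        row = {
            "case_exposure": float(exposure.loc[case]),
            "control_exposure": float(exposure.loc[ctrl]),
            "case_age": float(grp.loc[case, "age_at_draw"]),
            "control_age": float(grp.loc[ctrl, "age_at_draw"]),
        }
        for col in extra_cols:
            row[col] = grp.loc[case, col]
        rows[pair_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "pair_id"
    return out


# ---------------------------------------------------------------------------
# Conditional logistic core


def _conditional_loglik(D: np.ndarray, beta: np.ndarray) -> float:
    eta = D @ beta
    # log expit, numerically stable
    return float(-np.logaddexp(0.0, -eta).sum())


def _clogit_newton(D: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Maximise the 1:1 conditional likelihood by Newton–Raphson."""
    n, p = D.shape
    beta = np.zeros(p)
    ll = _conditional_loglik(D, beta)
    for _ in range(max_iter):
        eta = D @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        grad = D.T @ (1.0 - prob)
        if np.linalg.norm(grad) < tol:
            break
        W = prob * (1.0 - prob)
        H = D.T @ (D * W[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        # step halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll_new = _conditional_loglik(D, cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll = cand, ll_new
        if np.linalg.norm(beta) > 50:
            raise SeparationError("estimates diverging; data are separated")
    else:
        raise SeparationError("Newton–Raphson failed to converge in 100 iterations")
    eta = D @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    H = D.T @ (D * (prob * (1.0 - prob))[:, None])
    cov = np.linalg.inv(H)
    return beta, cov


def _fit_clogit_terms(D: pd.DataFrame, primary: str):
    """Fit on difference columns, handling zero-variance columns."""
    active = [c for c in D.columns if np.any(D[c].to_numpy() != 0)]
    degenerate = [c for c in D.columns if c not in active]
    if not active:
        raise ValueError("zero informative pairs: all within-pair differences are zero")
    d_primary = D[primary].to_numpy(float) if primary in active else None
    if d_primary is not None:
        nz = d_primary[d_primary != 0]
        if len(nz) and (np.all(nz > 0) or np.all(nz < 0)):
            raise SeparationError(
                f"all informative within-pair differences of {primary!r} share one sign"
            )
    beta, cov = _clogit_newton(D[active].to_numpy(float))
    coefs = pd.Series(0.0, index=D.columns)
    ses = pd.Series(np.inf, index=D.columns)
    coefs[active] = beta
    ses[active] = np.sqrt(np.diag(cov))
    return coefs, ses, degenerate


def clogit_pairs(pairs: pd.DataFrame, adjust=("age",)) -> EffectEstimate:
    """Age-adjusted conditional logistic regression on matched pairs.

    *pairs* is one row per pair with ``case_exposure``/``control_exposure``
    (and ``case_age``/``control_age`` when adjusting for age; any other
    adjustment ``z`` expects ``case_z``/``control_z`` columns).  The reported
    coefficient is the log-odds ratio per unit of exposure.
    """
    D = pd.DataFrame(index=pairs.index)
    D["exposure"] = pairs["case_exposure"] - pairs["control_exposure"]
    for cov in adjust:
        D[cov] = pairs[f"case_{cov}"] - pairs[f"control_{cov}"]
    coefs, ses, degenerate = _fit_clogit_terms(D, "exposure")
    n_informative = int((D["exposure"] != 0).sum())
    flags = tuple(f"degenerate:{c}" for c in degenerate)
    est = EffectEstimate("exposure", float(coefs["exposure"]), float(ses["exposure"]), len(pairs), n_informative, flags)
    est.adjusted_terms = pd.DataFrame({"coef": coefs, "se": ses})
    return est


def or_by_quartile(pairs: pd.DataFrame, adjust=("age",)) -> dict:
    """Quartile odds ratios vs Q1 from a single conditional-logistic fit.

    *pairs* must carry ``case_quartile``/``control_quartile`` labels.  Q1 is
    the reference with OR fixed at exactly 1.00.
    """
    labels = pd.concat([pairs["case_quartile"], pairs["control_quartile"]])
    for q in QUARTILES:
        if not (labels == q).any():
            raise ValueError(f"quartile {q} is empty among cases and controls")
    D = pd.DataFrame(index=pairs.index)
    for q in ("Q2", "Q3", "Q4"):
        D[q] = (pairs["case_quartile"] == q).astype(float) - (pairs["control_quartile"] == q).astype(float)
    for cov in adjust:
        D[cov] = pairs[f"case_{cov}"] - pairs[f"control_{cov}"]
    coefs, ses, degenerate = _fit_clogit_terms(D, "Q2")
    out = {"Q1": EffectEstimate("Q1", 0.0, 0.0, len(pairs), len(pairs), ("reference",))}
    for q in ("Q2", "Q3", "Q4"):
        n_inf = int((D[q] != 0).sum())
        flags = ("degenerate:" + q,) if q in degenerate else ()
        out[q] = EffectEstimate(q, float(coefs[q]), float(ses[q]), len(pairs), n_inf, flags)
    return out


def robust_logistic(exposure: pd.Series, status: pd.Series, pair_id: pd.Series, adjust: pd.DataFrame | None = None) -> EffectEstimate:
    """Unconditional logistic regression with pair-clustered sandwich SEs.

    A confirmation analysis for the matched conditional model: ignores the
    matching in the mean model but accounts for within-pair correlation in
    the covariance.
    """
    import statsmodels.api as sm

    y = (status == "case").astype(float).to_numpy()
    X = pd.DataFrame({"const": 1.0, "exposure": exposure.astype(float)})
    if adjust is not None:
        for c in adjust.columns:
            X[c] = adjust[c].astype(float).to_numpy()
    groups = pd.Categorical(pair_id).codes
    fit = sm.Logit(y, X.to_numpy()).fit(disp=False, cov_type="cluster", cov_kwds={"groups": groups})
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    n_pairs = int(pd.Series(groups).nunique())
    return EffectEstimate("exposure", coef, se, n_pairs, n_pairs)


def _exact_signed_rank_p(d: np.ndarray, alternative: str) -> float:
    """Exact signed-rank null via the sign-flip generating function.

    Mid-ranks are doubled to make all rank contributions integer, then the
    distribution of W+ is built by dynamic programming over the 2^n
    equiprobable sign assignments.
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    w_obs = int(np.rint(r2[d > 0].sum()))
    p_ge = counts[w_obs:].sum()
    p_le = counts[: w_obs + 1].sum()
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def paired_wilcoxon(case_values, control_values, alternative: str = "two-sided"):
    """Wilcoxon signed-rank test on within-pair differences.

    Zero differences are dropped; mid-ranks are used for tied absolute
    differences.  The exact sign-flip null distribution is used for n ≤ 25,
    otherwise the normal approximation with tie and continuity correction.
    Returns ``(W_plus, p)`` where ``W_plus`` is the positive-rank sum.
    """
    d = np.asarray(case_values, float) - np.asarray(control_values, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no nonzero within-pair differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return w_plus, _exact_signed_rank_p(d, alternative)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    diff = w_plus - mean
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var)
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(diff) - 0.5, scale=np.sqrt(var)) if var > 0 else 1.0
        p = min(1.0, float(p))
    return w_plus, float(p)


# ---------------------------------------------------------------------------
# Spline risk distribution


@dataclass
class SplineRiskResult:
    """Per-subject relative-risk distribution from a spline exposure model."""

    log_rr: pd.Series
    rr_median: float
    rr_lower: float
    rr_upper: float
    coef: np.ndarray = field(repr=False)
    knots: np.ndarray = field(repr=False)

    @property
    def rr_range95(self) -> tuple:
        return (self.rr_lower, self.rr_upper)


def _bspline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(x, knots, 3, extrapolate=True).toarray()


def spline_risk_distribution(
    exposure: pd.Series,
    status: pd.Series,
    pair_id: pd.Series,
    df: int = 4,
    center: str = "mean",
) -> SplineRiskResult:
    """Estimate the individual relative-risk distribution with a cubic spline.

    Fits a conditional logistic model on a cubic B-spline basis of the
    continuous exposure (interior knots at exposure quantiles), computes each
    subject's fitted log relative risk, and centres so the population
    ``center`` (mean or median) log-RR is 0.  Reports the median and 95%
    range (2.5th–97.5th percentiles) of RR across subjects.
    """
    if df < 3:
        raise ValueError("df must be ≥ 3")
    x = exposure.astype(float)
    if x.std(ddof=1) == 0 or x.nunique() <= df:
        raise ValueError("too few distinct exposure values for knot placement")
    n_interior = df - 3
    lo, hi = float(x.min()), float(x.max())
    if n_interior > 0:
        interior = np.quantile(x.to_numpy(), np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])

    basis = _bspline_basis(x.to_numpy(), knots)
    bdf = pd.DataFrame(basis, index=x.index)
    case_ids, ctrl_ids = [], []
    for _, grp in pd.DataFrame({"status": status, "pair": pair_id}).groupby("pair"):
        case_ids.append(grp.index[grp["status"] == "case"][0])
        ctrl_ids.append(grp.index[grp["status"] == "control"][0])
    D = bdf.loc[case_ids].to_numpy() - bdf.loc[ctrl_ids].to_numpy()
    # the basis sums to one, so constants cancel within pairs and D is rank
    # deficient; fit in its well-conditioned row space and map back
    _, s, Vt = np.linalg.svd(D, full_matrices=False)
    keep = s > 1e-8 * s[0]
    Vr = Vt[keep].T / s[keep]  # unit-scaled directions
    beta_r, _ = _clogit_newton(D @ Vr)
    beta = Vr @ beta_r

    eta = pd.Series(basis @ beta, index=x.index, name="log_rr")
    eta = eta - (eta.mean() if center == "mean" else eta.median())
    rr = np.exp(eta.to_numpy())
    return SplineRiskResult(
        log_rr=eta,
        rr_median=float(np.median(rr)),
        rr_lower=float(np.quantile(rr, 0.025)),
        rr_upper=float(np.quantile(rr, 0.975)),
        coef=beta,
        knots=knots,
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance


def roc_auc(scores, status):
    """AUC (Mann–Whitney concordance with tie correction) and DeLong 95% CI.

    Returns ``(auc, (lower, upper))``.
    """
    scores = np.asarray(scores, float)
    status_arr = np.asarray(status)
    is_case = status_arr if status_arr.dtype == bool else status_arr == "case"
    pos, neg = scores[is_case], scores[~is_case]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    allv = np.concatenate([pos, neg])
    tz = stats.rankdata(allv)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var_auc = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + (np.var(v10, ddof=1) / n if n > 1 else 0.0)
    half = Z95 * np.sqrt(var_auc)
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


# ---------------------------------------------------------------------------
# Stratified analysis and distribution comparison


def stratified_analysis(pairs: pd.DataFrame, stratum: str, adjust=("age",)):
    """Per-stratum conditional-logistic estimates + Cochran's Q heterogeneity.

    *stratum* names a pair-level column of *pairs* (e.g. a time-to-diagnosis
    group or ER status).  Returns ``(estimates_by_stratum, heterogeneity)``.
    """
    groups = {s: grp for s, grp in pairs.groupby(stratum) if len(grp)}
    if len(groups) < 2:
        raise ValueError("need ≥ 2 strata with informative pairs")
    estimates = {s: clogit_pairs(grp, adjust=adjust) for s, grp in groups.items()}
    theta = np.array([e.coef for e in estimates.values()])
    se = np.array([e.se for e in estimates.values()])
    w = 1.0 / se**2
    theta_fe = np.sum(w * theta) / np.sum(w)
    Q = float(np.sum(w * (theta - theta_fe) ** 2))
    dfree = len(groups) - 1
    p = float(stats.chi2.sf(Q, dfree))
    return estimates, HeterogeneityResult(Q, dfree, p)


def ks_compare(case_values, control_values):
    """Two-sample Kolmogorov–Smirnov test (asymptotic p)."""
    case_values = np.asarray(case_values, float)
    control_values = np.asarray(control_values, float)
    if len(case_values) == 0 or len(control_values) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(case_values, control_values, method="asymp")
    return float(res.statistic), float(res.pvalue)
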