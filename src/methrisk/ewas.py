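"""Probe-wise two-stage association scan with Bonferroni control.

Stage 1 removes technical variation from each probe's β values with a
beta-distributed-response GLM (logit mean link, constant precision) on chip
and chip-position factors; stage 2 enters the residual methylation in a
Poisson GLM of the case indicator with log person-years of follow-up as
offset and age at blood draw as covariate.  With the person-years offset the
Poisson coefficients approximate incidence-rate (Cox-like) log hazard
ratios.  Probe-wise p-values are compared to the Bonferroni threshold
``alpha / n_tests``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

_CLAMP = 1e-6


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be ≥ 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Stage 1: beta regression (logit mean link, constant precision)


class BetaRegressionError(RuntimeError):
    pass


@dataclass
class BetaRegressionFit:
    coef: np.ndarray
    phi: float
    fitted: np.ndarray
    loglik: float
    n_iter: int


def _beta_loglik(y, mu, phi):
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
    )


def beta_regression(y: np.ndarray, X: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> BetaRegressionFit:
    """Maximum-likelihood beta regression by Fisher scoring.

    Mean model ``mu = expit(X beta)`` with a single precision ``phi``
    (variance ``mu (1 − mu) / (1 + phi)``).  Converges when the joint score
    norm drops below *tol*; raises :class:`BetaRegressionError` otherwise.
    """
    y = np.clip(np.asarray(y, float), _CLAMP, 1 - _CLAMP)
    X = np.asarray(X, float)
    n, k = X.shape

    # start from the logit-scale least-squares fit and a moment precision
    z = np.log(y / (1 - y))
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    s2 = max(float(resid @ resid) / max(n - k, 1), 1e-6)
    mu = special.expit(X @ beta)
    phi = max(float(np.mean(1.0 / (s2 * mu * (1 - mu)))) - 1.0, 0.1)

    ystar = np.log(y / (1 - y))
    ll = _beta_loglik(y, mu, phi)
    for it in range(1, max_iter + 1):
        mu = special.expit(X @ beta)
        a = mu * phi
        b = (1.0 - mu) * phi
        mustar = special.digamma(a) - special.digamma(b)
        dmu = mu * (1.0 - mu)  # dmu/deta for the logit link

        score_beta = phi * (X.T @ ((ystar - mustar) * dmu))
        score_phi = float(
            np.sum(mu * (ystar - mustar) + np.log1p(-y) - special.digamma(b) + special.digamma(phi))
        )
        score = np.append(score_beta, score_phi)
        if np.linalg.norm(score) < tol:
            return BetaRegressionFit(beta, phi, mu, ll, it)

        psi_a = special.polygamma(1, a)
        psi_b = special.polygamma(1, b)
        w = phi * (psi_a + psi_b) * dmu**2
        K_bb = phi * (X.T @ (X * w[:, None]))
        c = phi * (psi_a * mu - psi_b * (1.0 - mu)) * dmu
        K_bp = X.T @ c
        K_pp = float(np.sum(psi_a * mu**2 + psi_b * (1.0 - mu) ** 2) - n * special.polygamma(1, phi))
        K = np.zeros((k + 1, k + 1))
        K[:k, :k] = K_bb
        K[:k, k] = K_bp
        K[k, :k] = K_bp
        K[k, k] = K_pp
        try:
            step = np.linalg.solve(K, score)
        except np.linalg.LinAlgError as exc:
            raise BetaRegressionError("singular Fisher information") from exc
        # step halving: keep phi positive and the likelihood non-decreasing
        for _ in range(40):
            beta_new = beta + step[:k]
            phi_new = phi + step[k]
            if phi_new > 0:
                mu_new = special.expit(X @ beta_new)
                ll_new = _beta_loglik(y, mu_new, phi_new)
                if ll_new >= ll - 1e-10:
                    break
            step = step / 2.0
        else:
            raise BetaRegressionError("step halving failed")
        beta, phi, ll = beta_new, phi_new, ll_new
    raise BetaRegressionError("no convergence in 100 iterations")


def beta_glm_residuals(beta_values, covariates: pd.DataFrame, residual_type: str = "response") -> np.ndarray:
    """Technical-adjustment residuals for one probe.

    *covariates* holds categorical technical factors (chip, position on
    chip), dummy-coded with a dropped reference level.  ``residual_type`` is
    ``'response'`` (observed − fitted mean, the default) or
    ``'standardized'``.
    """
    y = np.asarray(beta_values, float)
    X = _technical_design(covariates, len(y))
    fit = beta_regression(y, X)
    resid = np.clip(y, _CLAMP, 1 - _CLAMP) - fit.fitted
    if residual_type == "standardized":
        var = fit.fitted * (1.0 - fit.fitted) / (1.0 + fit.phi)
        resid = resid / np.sqrt(var)
    elif residual_type != "response":
        raise ValueError("residual_type must be 'response' or 'standardized'")
    return resid


def _technical_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    dummies = pd.get_dummies(covariates.astype("category"), drop_first=True)
    X = np.column_stack([np.ones(n), dummies.to_numpy(float)])
    return X


# ---------------------------------------------------------------------------
# Stage 2: Poisson GLM with person-years offset


def _poisson_irls_batched(y: np.ndarray, X: np.ndarray, offset: np.ndarray, tol: float = 1e-10, max_iter: int = 60):
    """Batched Poisson IRLS.

    ``X`` has shape (P, n, k) — one design per probe (they share all columns
    except the methylation residual).  Returns ``(beta, cov, ok)`` with
    shapes (P, k), (P, k, k), (P,).
    """
    P, n, k = X.shape
    beta = np.zeros((P, k))
    beta[:, 0] = np.log(max(y.sum(), 0.5) / np.exp(offset).sum())
    ok = np.ones(P, dtype=bool)
    for _ in range(max_iter):
        eta = offset[None, :] + np.einsum("pnk,pk->pn", X, beta)
        mu = np.exp(np.clip(eta, -30, 30))
        z = (eta - offset[None, :]) + (y[None, :] - mu) / mu
        XtWX = np.einsum("pni,pn,pnj->pij", X, mu, X)
        XtWz = np.einsum("pni,pn->pi", X, mu * z)
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # fall back probe-wise, flagging singular fits
            beta_new = beta.copy()
            for pidx in range(P):
                try:
                    beta_new[pidx] = np.linalg.solve(XtWX[pidx], XtWz[pidx])
                except np.linalg.LinAlgError:
                    ok[pidx] = False
        bad = ~np.isfinite(beta_new).all(axis=1)
        if bad.any():
            ok &= ~bad
            beta_new[bad] = beta[bad]
        delta = np.max(np.abs(beta_new - beta), axis=1)
        beta = beta_new
        if delta[ok].max(initial=0.0) < tol:
            break
    eta = offset[None, :] + np.einsum("pnk,pk->pn", X, beta)
    mu = np.exp(np.clip(eta, -30, 30))
    XtWX = np.einsum("pni,pn,pnj->pij", X, mu, X)
    cov = np.full_like(XtWX, np.nan)
    for pidx in range(P):
        if ok[pidx]:
            try:
                cov[pidx] = np.linalg.inv(XtWX[pidx])
            except np.linalg.LinAlgError:
                ok[pidx] = False
    return beta, cov, ok


def poisson_offset_assoc(residuals, events, person_years, age=None):
    """Poisson incidence model for one probe's residual methylation.

    Log link, outcome = case indicator, offset = log person-years, covariates
    = residual methylation (+ age when given).  Returns ``(coef, se, p)`` for
    the methylation term.
    """
    events = np.asarray(events, float)
    person_years = np.asarray(person_years, float)
    if np.any(person_years <= 0):
        raise ValueError("person-years must be positive for every subject")
    if events.sum() == 0:
        raise ValueError("no events: the incidence model is not identifiable")
    resid = np.asarray(residuals, float)
    cols = [np.ones_like(resid), resid]
    if age is not None:
        cols.append(np.asarray(age, float))
    Xs = np.column_stack(cols)[None, :, :]
    beta, cov, ok = _poisson_irls_batched(events, Xs, np.log(person_years))
    if not ok[0]:
        raise RuntimeError("Poisson IRLS failed")
    coef = float(beta[0, 1])
    se = float(np.sqrt(cov[0, 1, 1]))
    p = float(2.0 * stats.norm.sf(abs(coef) / se))
    return coef, se, p


# ---------------------------------------------------------------------------
# The scan


@dataclass
class EwasScanResult:
    table: pd.DataFrame
    threshold: float
    n_significant: int
    n_hypo: int  # significant probes lower in cases
    n_hyper: int
    n_failed: int


def ewas_scan(
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    alpha: float = 0.05,
    technical=("chip_id", "position_on_chip"),
    age_col: str = "age_at_draw",
    residual_type: str = "response",
) -> EwasScanResult:
    """Two-stage probe-wise scan over a preprocessed β matrix.

    When *technical* is None (or the listed factors do not vary) stage 1
    reduces to centring each probe at its mean, which leaves stage-2
    inference unchanged; otherwise each probe is residualised with the beta
    GLM.  Per-probe failures are recorded and the scan continues.
    """
    sheet = sheet.loc[m.columns]
    events = (sheet["status"] == "case").to_numpy(float)
    offset = np.log(sheet["followup"].to_numpy(float))
    age = sheet[age_col].to_numpy(float)
    Y = m.to_numpy(float)
    P, n = Y.shape

    tech = None
    if technical:
        cols = [c for c in technical if c in sheet.columns and sheet[c].nunique() > 1]
        if cols:
            tech = sheet[cols]

    failed = np.zeros(P, dtype=bool)
    if tech is None:
        resid = np.clip(Y, _CLAMP, 1 - _CLAMP)
        resid = resid - resid.mean(axis=1, keepdims=True)
    else:
        X1 = _technical_design(tech, n)
        resid = np.empty_like(Y)
        for i in range(P):
            try:
                fit = beta_regression(Y[i], X1)
                r = np.clip(Y[i], _CLAMP, 1 - _CLAMP) - fit.fitted
                if residual_type == "standardized":
                    r = r / np.sqrt(fit.fitted * (1 - fit.fitted) / (1 + fit.phi))
                resid[i] = r
            except BetaRegressionError:
                failed[i] = True
                resid[i] = 0.0

    X = np.empty((P, n, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = resid
    X[:, :, 2] = age[None, :]
    beta, cov, ok = _poisson_irls_batched(events, X, offset)
    failed |= ~ok
    coef = beta[:, 1]
    se = np.sqrt(cov[:, 1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(coef) / se)
    p = np.where(failed, np.nan, p)
    threshold = bonferroni_threshold(int((~failed).sum()), alpha)
    significant = (p < threshold) & ~failed

    table = pd.DataFrame(
        {
            "coef": np.where(failed, np.nan, coef),
            "se": np.where(failed, np.nan, se),
            "p_value": p,
            "significant": significant,
            "direction": np.where(coef < 0, "hypo", "hyper"),
            "failed": failed,
        },
        index=m.index,
    ).sort_values("p_value")
    return EwasScanResult(
        table=table,
        threshold=threshold,
        n_significant=int(significant.sum()),
        n_hypo=int((significant & (coef < 0)).sum()),
        n_hyper=int((significant & (coef > 0)).sum()),
        n_failed=int(failed.sum()),
    )
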