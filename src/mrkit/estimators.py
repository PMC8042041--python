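"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a frame of standardized instrument pairs (columns
``snp, gamma, se_gamma, Gamma, se_Gamma``) and return an :class:`MREstimate`
whose effect is a log-odds ratio for a binary outcome; odds ratios with 95%
confidence intervals are always populated.

* ``wald_ratio``  — single-instrument ratio Gamma/gamma with delta-method SE.
* ``ivw``         — inverse-variance-weighted regression through the origin;
  consistent only when no instrument acts on the outcome through a pathway
  other than the exposure (horizontal pleiotropy biases it).
* ``egger``       — weighted regression with a free intercept; under the
  InSIDE assumption the slope is robust to directional pleiotropy and the
  intercept estimates its mean (intercept p-value = pleiotropy test).
* ``imrp``        — iterative pleiotropy pruning: alternately estimate the
  effect and exclude instruments whose residual test rejects, with optional
  correction for exposure/outcome sample overlap.
* ``mrmix`` (in :mod:`mrkit.mrmix`) — normal-mixture profile estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ParameterError

#: two-sided 95% normal multiplier
Z95 = 1.959964


@dataclass
class MREstimate:
    """One estimator's causal-effect estimate with OR reporting."""

    method: str
    theta: float
    se: float
    pvalue: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_snps_used: int
    excluded_snps: list = field(default_factory=list)
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    pi0: float | None = None
    sigma2: float | None = None
    iterations: int | None = None
    converged: bool = True

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "pvalue": self.pvalue,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_snps_used": self.n_snps_used,
            "n_excluded": len(self.excluded_snps),
            "converged": self.converged,
        }
        for key in ("intercept", "intercept_se", "intercept_p", "pi0", "sigma2", "iterations"):
            v = getattr(self, key)
            if v is not None:
                d[key] = v
        return d


def to_odds_ratio(theta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect into (OR, 95% CI low, high)."""
    if se < 0:
        raise ParameterError("se must be >= 0")
    return (
        float(np.exp(theta)),
        float(np.exp(theta - Z95 * se)),
        float(np.exp(theta + Z95 * se)),
    )


def _finish(method, theta, se, n_used, **kw) -> MREstimate:
    or_, lo, hi = to_odds_ratio(theta, se)
    p = float(2 * stats.norm.sf(abs(theta / se))) if se > 0 else (1.0 if theta == 0 else 0.0)
    return MREstimate(
        method=method, theta=float(theta), se=float(se), pvalue=p,
        odds_ratio=or_, ci_low=lo, ci_high=hi, n_snps_used=int(n_used), **kw,
    )


def _cols(pairs: pd.DataFrame):
    return (
        pairs["gamma"].to_numpy(dtype=float),
        pairs["se_gamma"].to_numpy(dtype=float),
        pairs["Gamma"].to_numpy(dtype=float),
        pairs["se_Gamma"].to_numpy(dtype=float),
    )


def wald_ratio(pair) -> MREstimate:
    """Single-instrument ratio estimate with first-order delta-method SE.

    ``pair`` is a mapping or single-row frame with the standardized fields.
    """
    if isinstance(pair, pd.DataFrame):
        if len(pair) != 1:
            raise EstimationError("wald_ratio takes exactly one instrument")
        pair = pair.iloc[0]
    g, sg = float(pair["gamma"]), float(pair["se_gamma"])
    G, sG = float(pair["Gamma"]), float(pair["se_Gamma"])
    if g == 0:
        raise EstimationError("wald_ratio undefined for gamma_hat = 0")
    theta = G / g
    se = np.sqrt(sG**2 / g**2 + G**2 * sg**2 / g**4)
    return _finish("ratio", theta, se, 1)


def ivw(pairs: pd.DataFrame, weights: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of Gamma on gamma through the
    origin with weights 1/se_Gamma^2.

    ``weights="mre"`` applies the multiplicative random-effects correction,
    inflating the SE by max(1, sqrt(Q/(m-1))) when residual heterogeneity
    exceeds its expectation.
    """
    if weights not in ("fixed", "mre"):
        raise ParameterError(f"unknown weights {weights!r}")
    g, _, G, sG = _cols(pairs)
    if len(g) == 0 or np.all(g == 0):
        raise EstimationError("ivw needs at least one instrument with gamma_hat != 0")
    w = 1.0 / sG**2
    denom = np.sum(w * g**2)
    theta = np.sum(w * g * G) / denom
    se = denom**-0.5
    if weights == "mre" and len(g) > 1:
        q = np.sum(w * (G - theta * g) ** 2)
        se *= max(1.0, np.sqrt(q / (len(g) - 1)))
    return _finish("IVW", theta, se, len(g))


def egger(pairs: pd.DataFrame, orient: bool = True) -> MREstimate:
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    The intercept estimates the mean directional pleiotropic effect and its
    p-value is the MR-Egger pleiotropy test; the slope is the causal effect.
    By default instruments are sign-oriented so gamma_hat >= 0 (flipping
    both coordinates), the standard Egger convention.
    """
    g, _, G, sG = _cols(pairs)
    m = len(g)
    if m < 3:
        raise EstimationError(f"egger needs >= 3 instruments, got {m}")
    if orient:
        s = np.where(g < 0, -1.0, 1.0)
        g, G = g * s, G * s
    w = 1.0 / sG**2
    # weighted normal equations for [intercept, slope]
    sw, swx = np.sum(w), np.sum(w * g)
    swxx, swy, swxy = np.sum(w * g * g), np.sum(w * G), np.sum(w * g * G)
    det = sw * swxx - swx**2
    if det <= 0:
        raise EstimationError("egger design is degenerate (no spread in gamma_hat)")
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = G - intercept - slope * g
    # dispersion-scaled covariance (sigma^2 floored at 1, the usual Egger SE)
    sigma2 = max(1.0, float(np.sum(w * resid**2) / (m - 2)))
    var_int = sigma2 * swxx / det
    var_slope = sigma2 * sw / det
    se_slope = float(np.sqrt(var_slope))
    se_int = float(np.sqrt(var_int))
    int_p = float(2 * stats.t.sf(abs(intercept / se_int), m - 2))
    est = _finish("Egger", slope, se_slope, m)
    est.intercept, est.intercept_se, est.intercept_p = float(intercept), se_int, int_p
    return est


def pleiotropy_variance(se_gamma, se_Gamma, theta, rho_overlap=0.0):
    """Variance of the residual Gamma_hat - theta*gamma_hat under no pleiotropy.

    The cross term corrects for correlated sampling error when exposure and
    outcome GWAS share participants (overlap correlation ``rho_overlap``).
    """
    return (
        np.asarray(se_Gamma, float) ** 2
        + theta**2 * np.asarray(se_gamma, float) ** 2
        - 2.0 * theta * rho_overlap * np.asarray(se_Gamma, float) * np.asarray(se_gamma, float)
    )


def pleiotropy_test(
    pairs: pd.DataFrame, theta: float, rho_overlap: float = 0.0
) -> pd.DataFrame:
    """Per-instrument horizontal-pleiotropy test at a given causal effect.

    t_i = (Gamma_i - theta*gamma_i) / sqrt(var_i) with the overlap-corrected
    variance; two-sided normal p-values, flagged at nominal 0.05 and at the
    Bonferroni level 0.05/m.
    """
    if not -1.0 <= rho_overlap <= 1.0:
        raise ParameterError("rho_overlap must be in [-1, 1]")
    g, sg, G, sG = _cols(pairs)
    var = pleiotropy_variance(sg, sG, theta, rho_overlap)
    if np.any(var <= 0):
        raise ParameterError("non-positive residual variance; rho_overlap too extreme")
    t = (G - theta * g) / np.sqrt(var)
    p = 2 * stats.norm.sf(np.abs(t))
    m = len(g)
    return pd.DataFrame(
        {
            "snp": pairs["snp"].to_numpy() if "snp" in pairs else np.arange(m),
            "t_stat": t,
            "pvalue": p,
            "flagged_nominal": p < 0.05,
            "flagged_bonferroni": p < 0.05 / m,
        }
    )


def imrp(
    pairs: pd.DataFrame,
    alpha_pleio: float = 0.05,
    rho_overlap: float = 0.0,
    max_iter: int = 50,
) -> tuple[MREstimate, pd.DataFrame]:
    """Iterative Mendelian randomization with pleiotropy pruning.

    Alternates between (1) estimating theta on the retained instruments by
    weighted origin regression with the overlap-corrected residual variance
    as weights, and (2) testing every instrument for horizontal pleiotropy
    at that theta, excluding those with p < ``alpha_pleio``; stops when the
    excluded set is stable or ``max_iter`` is reached.  The same corrected
    variance weights both the test and the final estimate.

    Returns the estimate and the final per-instrument pleiotropy frame.
    """
    g, sg, G, sG = _cols(pairs)
    m = len(g)
    if m < 3:
        raise EstimationError(f"imrp needs >= 3 instruments, got {m}")
    snps = pairs["snp"].to_numpy() if "snp" in pairs else np.arange(m)

    def _theta_on(mask: np.ndarray, theta0: float) -> tuple[float, float]:
        """Corrected-weight origin regression, iterated to its fixed point."""
        theta = theta0
        for _ in range(100):
            var = pleiotropy_variance(sg[mask], sG[mask], theta, rho_overlap)
            if np.any(var <= 0):
                raise ParameterError("non-positive variance in IMRP weighting")
            w = 1.0 / var
            denom = np.sum(w * g[mask] ** 2)
            if denom <= 0:
                raise EstimationError("IMRP weighting collapsed (no instrument strength)")
            new = np.sum(w * g[mask] * G[mask]) / denom
            if abs(new - theta) < 1e-12:
                theta = new
                break
            theta = new
        se = float(denom**-0.5)
        return float(theta), se

    theta = ivw(pairs).theta  # initialization
    retained = np.ones(m, dtype=bool)
    converged = False
    iterations = 0
    pleio = None
    for iterations in range(1, max_iter + 1):
        theta, se = _theta_on(retained, theta)
        pleio = pleiotropy_test(pairs, theta, rho_overlap)
        new_retained = (pleio["pvalue"].to_numpy() >= alpha_pleio)
        if not new_retained.any():
            raise EstimationError("IMRP excluded every instrument")
        if np.array_equal(new_retained, retained):
            converged = True
            break
        retained = new_retained
    theta, se = _theta_on(retained, theta)
    pleio = pleiotropy_test(pairs, theta, rho_overlap)

    est = _finish("IMRP", theta, se, int(retained.sum()))
    est.excluded_snps = list(snps[~retained])
    est.iterations = iterations
    est.converged = converged
    return est, pleio
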