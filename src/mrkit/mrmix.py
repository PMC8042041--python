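"""Normal-mixture profile estimator of the causal effect.

For a candidate causal effect theta, the residuals

    d_i = Gamma_hat_i - theta * gamma_hat_i

of valid instruments are pure sampling noise with known variance
s_i^2(theta) = se_Gamma_i^2 + theta^2 * se_gamma_i^2, while horizontally
pleiotropic instruments carry extra spread.  At each theta on a grid the
two-component mixture

    pi0 * N(0, s_i^2) + (1 - pi0) * N(0, s_i^2 + sigma^2)

is fitted by expectation-maximization in (pi0, sigma^2); the profile
objective is the fitted null proportion pi0, maximized at the theta where
the largest share of instruments looks like pure noise.  The estimate is the
grid argmax (ties broken toward smaller |theta|); its standard error comes
from a nonparametric bootstrap over instruments.

The EM is vectorized across bootstrap resamples, so the full profile for
hundreds of resamples costs a few matrix operations per grid point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .estimators import MREstimate, _finish

logger = logging.getLogger(__name__)

SIGMA2_FLOOR = 1e-12


@dataclass
class ProfileCurve:
    """Grid of candidate effects with the mixture objective at each."""

    thetas: np.ndarray
    objective: np.ndarray  # fitted pi0 per theta (NaN where EM failed)
    argmax: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta": self.thetas, "objective": self.objective})


def default_grid(lo: float = -2.0, hi: float = 2.0, step: float = 0.01) -> np.ndarray:
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def _em_rows(d, s2, pi0_init=0.9, tol=1e-6, max_iter=200):
    """Row-wise EM for the two-component scale mixture.

    ``d`` and ``s2`` are (B, m) arrays; each row is fitted independently.
    Converged rows are frozen and removed from the working set so slow rows
    do not hold the rest back.  Returns (pi0, sigma2) arrays of length B.
    """
    B, _ = d.shape
    d2 = d * d
    inv_s2 = 1.0 / s2
    pi0_out = np.full(B, pi0_init)
    # generous overdispersion start: excess of residual scatter over noise
    sig_out = np.maximum(np.mean(d2, axis=1) - np.mean(s2, axis=1), np.mean(s2, axis=1))
    sig_out = np.maximum(sig_out, SIGMA2_FLOOR)

    active = np.arange(B)
    pi0, sigma2 = pi0_out.copy(), sig_out.copy()
    a_d2, a_s2, a_inv = d2, s2, inv_s2
    with np.errstate(over="ignore"):
        return _em_loop(active, pi0, sigma2, a_d2, a_s2, a_inv,
                        pi0_out, sig_out, tol, max_iter)


def _em_loop(active, pi0, sigma2, a_d2, a_s2, a_inv, pi0_out, sig_out, tol, max_iter):
    for _ in range(max_iter):
        v1 = a_s2 + sigma2[:, None]
        # E-step via the density ratio f1/f0 (v1 >= s2 so the exponent is
        # non-negative; clip against overflow)
        expo = np.clip(0.5 * a_d2 * (a_inv - 1.0 / v1), None, 700.0)
        ratio = np.sqrt(a_s2 / v1) * np.exp(expo)
        odds = ((1.0 - pi0) / np.clip(pi0, 1e-300, None))[:, None] * ratio
        r = 1.0 / (1.0 + odds)  # posterior weight of the null component
        new_pi0 = r.mean(axis=1)
        # M-step for sigma^2: fixed-point on the stationarity condition
        w1 = 1.0 - r
        new_sigma2 = sigma2.copy()
        for _inner in range(3):
            u2 = 1.0 / (a_s2 + new_sigma2[:, None]) ** 2
            num = np.einsum("ij,ij->i", w1 * u2, a_d2 - a_s2)
            den = np.einsum("ij,ij->i", w1, u2)
            new_sigma2 = np.where(den > 0, num / np.maximum(den, 1e-300), SIGMA2_FLOOR)
            new_sigma2 = np.maximum(new_sigma2, SIGMA2_FLOOR)
        done = (np.abs(new_pi0 - pi0) < tol) & (
            np.abs(new_sigma2 - sigma2) < tol * np.maximum(sigma2, 1e-30)
        )
        pi0, sigma2 = new_pi0, new_sigma2
        if done.any():
            pi0_out[active[done]] = pi0[done]
            sig_out[active[done]] = sigma2[done]
            if done.all():
                return pi0_out, sig_out
            keep = ~done
            active = active[keep]
            pi0, sigma2 = pi0[keep], sigma2[keep]
            a_d2, a_s2, a_inv = a_d2[keep], a_s2[keep], a_inv[keep]
    pi0_out[active] = pi0
    sig_out[active] = sigma2
    # a numerically failed fit is marked invalid and skipped by the argmax
    bad = ~np.isfinite(pi0_out)
    if bad.any():
        logger.warning("mixture EM produced %d invalid fits (marked NaN)", int(bad.sum()))
        pi0_out[bad] = np.nan
    return pi0_out, sig_out


def _profile(Gamma, gamma, s2G, s2g, thetas, chunk_elems=4_000_000, **em_kw):
    """pi0 profile over the grid for (B, m) instrument matrices.

    Grid points are fitted in chunks, flattened with the B rows, so the EM
    runs over large matrices instead of one small solve per theta.
    """
    B, m = Gamma.shape
    T = len(thetas)
    pi0_grid = np.empty((B, T))
    sigma2_grid = np.empty((B, T))
    t_chunk = max(1, int(chunk_elems / max(1, B * m)))
    for start in range(0, T, t_chunk):
        th = thetas[start:start + t_chunk]  # (Tc,)
        d = Gamma[:, None, :] - th[None, :, None] * gamma[:, None, :]
        s2 = s2G[:, None, :] + (th**2)[None, :, None] * s2g[:, None, :]
        Tc = len(th)
        pi0, sig2 = _em_rows(d.reshape(B * Tc, m), s2.reshape(B * Tc, m), **em_kw)
        pi0_grid[:, start:start + Tc] = pi0.reshape(B, Tc)
        sigma2_grid[:, start:start + Tc] = sig2.reshape(B, Tc)
    return pi0_grid, sigma2_grid


def _boot_argmax(Gm, gm, s2Gm, s2gm, thetas, em_kw, coarse_stride=5):
    """Per-resample profile argmax via a coarse scan plus local refinement.

    The profile is first evaluated on every ``coarse_stride``-th grid point;
    fine points are then evaluated inside a one-coarse-step window around
    every coarse point whose objective comes within 0.01 of that resample's
    coarse maximum (union over resamples).  For unimodal profiles this
    reproduces the full-grid argmax at a fraction of the cost.
    """
    B = Gm.shape[0]
    T = len(thetas)
    coarse = np.unique(np.r_[np.arange(0, T, coarse_stride), T - 1])
    pi0_c, _ = _profile(Gm, gm, s2Gm, s2gm, thetas[coarse], **em_kw)

    fine: set[int] = set()
    for b in range(B):
        row = pi0_c[b]
        near = coarse[row >= np.nanmax(row) - 0.01]
        for j in near:
            fine.update(range(max(0, j - coarse_stride), min(T, j + coarse_stride + 1)))
    fine_idx = np.array(sorted(fine.difference(coarse)), dtype=int)

    eval_idx = np.concatenate([coarse, fine_idx])
    pi0_all = np.empty((B, len(eval_idx)))
    pi0_all[:, : len(coarse)] = pi0_c
    if len(fine_idx):
        pi0_f, _ = _profile(Gm, gm, s2Gm, s2gm, thetas[fine_idx], **em_kw)
        pi0_all[:, len(coarse):] = pi0_f
    sub_thetas = thetas[eval_idx]
    return np.array([_argmax_theta(sub_thetas, pi0_all[b]) for b in range(B)])


def _argmax_theta(thetas, pi0_row):
    """Grid argmax of pi0; exact ties resolved toward the smallest |theta|."""
    valid = ~np.isnan(pi0_row)
    if not valid.any():
        raise EstimationError("mixture EM failed at every grid point")
    best = np.nanmax(pi0_row)
    ties = np.flatnonzero(valid & (pi0_row == best))
    return float(thetas[ties[np.argmin(np.abs(thetas[ties]))]])


def mrmix(
    pairs: pd.DataFrame,
    theta_grid: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    pi0_init: float = 0.9,
    em_tol: float = 1e-4,
    em_max_iter: int = 100,
    flat_tol: float = 1e-3,
) -> tuple[MREstimate, ProfileCurve]:
    """Profile-mixture causal-effect estimate with bootstrap standard error.

    Needs at least 10 instruments and a majority of valid ones to identify
    theta.  A profile whose objective varies by less than ``flat_tol``
    across the grid is flagged unstable (``converged=False``) — the
    wide-confidence-interval regime.
    """
    m = len(pairs)
    if m < 10:
        raise EstimationError(f"mrmix needs >= 10 instruments, got {m}")
    thetas = default_grid() if theta_grid is None else np.asarray(theta_grid, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    g = pairs["gamma"].to_numpy(dtype=float)
    G = pairs["Gamma"].to_numpy(dtype=float)
    s2g = pairs["se_gamma"].to_numpy(dtype=float) ** 2
    s2G = pairs["se_Gamma"].to_numpy(dtype=float) ** 2

    em_kw = dict(pi0_init=pi0_init, tol=em_tol, max_iter=em_max_iter)

    # observed-data profile over the full grid
    pi0_full, sigma2_full = _profile(
        G[None, :], g[None, :], s2G[None, :], s2g[None, :], thetas, **em_kw
    )
    pi0_grid0, sigma2_grid0 = pi0_full[0], sigma2_full[0]
    theta_hat = _argmax_theta(thetas, pi0_grid0)
    j_hat = int(np.argmin(np.abs(thetas - theta_hat)))
    spread = float(np.nanmax(pi0_grid0) - np.nanmin(pi0_grid0))
    stable = spread >= flat_tol
    if not stable:
        logger.warning("mrmix: flat profile (spread %.2g) — estimate unstable", spread)

    if n_boot:
        idx = rng.integers(0, m, size=(n_boot, m))
        boot_thetas = _boot_argmax(G[idx], g[idx], s2G[idx], s2g[idx], thetas, em_kw)
        se = float(np.std(boot_thetas, ddof=1))
    else:
        se = float("nan")
    est = _finish("MRMix", theta_hat, se if np.isfinite(se) and se > 0 else 0.0, m)
    if not (np.isfinite(se) and se > 0):
        est.se, est.pvalue = float(se), float("nan")
    est.pi0 = float(pi0_grid0[j_hat])
    est.sigma2 = float(sigma2_grid0[j_hat])
    est.converged = stable
    curve = ProfileCurve(thetas=thetas, objective=pi0_grid0, argmax=theta_hat)
    return est, curve
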