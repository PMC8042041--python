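"""Standardization of per-allele GWAS effects onto a common unitless scale.

Exposure effects are rescaled by their z-score and sample size,

    gamma_hat = beta_E / (se_E * sqrt(n_E)),   se_gamma = n_E^(-1/2)

while outcome effects are rescaled by the allele-frequency standard
deviation factor sqrt(2*MAF*(1-MAF)),

    Gamma_hat = beta_Y * sqrt(2*MAF*(1-MAF)),  se_Gamma = se_Y * sqrt(2*MAF*(1-MAF)).

Both transforms preserve each variant's z-score exactly
(gamma/se_gamma = beta_E/se_E and Gamma/se_Gamma = beta_Y/se_Y), so
significance is untouched; only the effect scale changes.  The exposure and
outcome are deliberately rescaled by different factors — the transforms are
applied exactly as stated above, with the asymmetry noted in the docs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, ParameterError

logger = logging.getLogger(__name__)

STANDARDIZED_COLUMNS = ["snp", "gamma", "se_gamma", "Gamma", "se_Gamma", "maf"]


def standardize_exposure(beta, se, n):
    """Return (gamma_hat, se_gamma) for per-allele exposure effects.

    Accepts scalars or numpy arrays; ``se`` must be positive and ``n >= 2``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(se <= 0):
        raise ParameterError("standardize_exposure: se must be > 0")
    if np.any(n < 2):
        raise ParameterError("standardize_exposure: n must be >= 2")
    gamma = beta / (se * np.sqrt(n))
    se_gamma = n ** -0.5
    return gamma, se_gamma


def standardize_outcome(beta, se, maf):
    """Return (Gamma_hat, se_Gamma) for per-allele outcome effects.

    ``maf`` is the minor allele frequency min(eaf, 1-eaf), in (0, 0.5].
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any(se <= 0):
        raise ParameterError("standardize_outcome: se must be > 0")
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ParameterError("standardize_outcome: maf must be in (0, 0.5]")
    scale = np.sqrt(2.0 * maf * (1.0 - maf))
    return beta * scale, se * scale


def standardize_pairs(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Standardize a harmonized exposure/outcome frame into instrument pairs.

    MAF is taken from the outcome eaf; where that is missing the exposure
    eaf substitutes with a logged warning.  Monomorphic records (maf == 0)
    and records with missing frequency are dropped and counted in
    ``df.attrs["drop_counts"]``.

    Returns columns ``snp, gamma, se_gamma, Gamma, se_Gamma, maf``.
    """
    eaf = harmonized["eaf_out"].to_numpy(dtype=float)
    missing = np.isnan(eaf)
    if missing.any():
        logger.warning(
            "standardize_pairs: %d records use exposure eaf (outcome eaf missing)",
            int(missing.sum()),
        )
        eaf = np.where(missing, harmonized["eaf_exp"].to_numpy(dtype=float), eaf)
    maf = np.minimum(eaf, 1.0 - eaf)
    ok = ~np.isnan(maf) & (maf > 0)
    dropped = int((~ok).sum())
    sub = harmonized[ok]
    maf = maf[ok]

    gamma, se_gamma = standardize_exposure(
        sub["beta_exp"].to_numpy(), sub["se_exp"].to_numpy(), sub["n_exp"].to_numpy()
    )
    Gamma, se_Gamma = standardize_outcome(
        sub["beta_out"].to_numpy(), sub["se_out"].to_numpy(), maf
    )
    out = pd.DataFrame(
        {
            "snp": sub["snp"].to_numpy(),
            "gamma": gamma,
            "se_gamma": se_gamma,
            "Gamma": Gamma,
            "se_Gamma": se_Gamma,
            "maf": maf,
        }
    )
    out.attrs["drop_counts"] = {"monomorphic_or_missing_maf": dropped}
    return out


@dataclass
class EffectCorrelation:
    """Pearson correlation between standardized exposure and outcome effects."""

    rho_hat: float
    se_rho: float
    m: int
    gamma_summary: dict
    Gamma_summary: dict


def _summary(x: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def effect_correlation(pairs: pd.DataFrame) -> EffectCorrelation:
    """Correlation of standardized exposure vs outcome effect sizes.

    The standard error uses the large-sample normal approximation
    sqrt((1 - rho^2) / (m - 2)); at least 3 pairs are required.
    """
    m = len(pairs)
    if m < 3:
        raise EstimationError(f"effect_correlation needs >= 3 pairs, got {m}")
    g = pairs["gamma"].to_numpy(dtype=float)
    G = pairs["Gamma"].to_numpy(dtype=float)
    rho = float(np.corrcoef(g, G)[0, 1])
    se = float(np.sqrt(max(0.0, 1.0 - rho**2) / (m - 2)))
    return EffectCorrelation(
        rho_hat=rho, se_rho=se, m=m, gamma_summary=_summary(g), Gamma_summary=_summary(G)
    )
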