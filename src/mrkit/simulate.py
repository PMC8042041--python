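"""Synthetic multi-cohort GWAS summary statistics with known causal structure.

The generator works on the standardized effect scale and back-transforms to
per-allele coordinates, so the full pipeline (read, meta-analyze, harmonize,
clump, standardize, estimate) is exercised end to end against a known truth:

* true standardized exposure effects  gamma_i ~ N(0, sigma_gamma^2)
  (half-normal when ``gamma_positive``, for directional-pleiotropy studies
  where sign orientation must not scramble the planted direction);
* a fraction of instruments is horizontally pleiotropic with direct outcome
  effects alpha_i ~ N(pleio_mean, pleio_sd^2) (directional) or
  N(0, pleio_sd^2) (balanced); valid instruments have alpha_i = 0;
* true standardized outcome effects  Gamma_i = theta * gamma_i + alpha_i;
* each cohort observes the truth plus sampling noise of standard deviation
  n^(-1/2) (scaled by ``noise_scale``), with exposure/outcome noise
  correlated by ``rho_overlap`` to emulate shared participants;
* observations are mapped back to per-allele (beta, se) via the inverse of
  the standardization transforms, with drawn minor-allele frequencies and
  random non-palindromic allele pairs.

Defaults emulate the scale of the motivating application: ~129 instruments
(a T2D-sized instrument set), exposure GWAS of ~660k, an outcome GWAS of
~11k, and standardized effect spread sigma_gamma = 0.01 (the order of the
observed per-instrument effect-size SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .ld import LDInfo
from .sumstats import CANONICAL_COLUMNS, SumStatTable

_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
    ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Generating parameters for one synthetic two-sample MR study."""

    m: int = 129
    theta_true: float = 0.5
    maf_range: tuple = (0.05, 0.5)
    n_exposure: int = 659_316
    n_outcome: int = 10_908
    k_cohorts: int = 1
    pleio_fraction: float = 0.0
    pleio_mode: str = "balanced"  # {"balanced", "directional"}
    pleio_sd: float = 0.02
    pleio_mean: float = 0.0
    rho_overlap: float = 0.0
    sigma_gamma: float = 0.01
    gamma_positive: bool = False
    noise_scale: float = 1.0
    ld_blocks: tuple | None = None  # (block_size, within_block_r2)
    palindromic_fraction: float = 0.0
    swapped_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.pleio_fraction <= 1:
            raise ParameterError("pleio_fraction must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must lie within (0, 0.5]")
        if self.pleio_mode not in ("balanced", "directional"):
            raise ParameterError(f"unknown pleio_mode {self.pleio_mode!r}")
        if not -1 < self.rho_overlap < 1:
            raise ParameterError("rho_overlap must be in (-1, 1)")
        if self.m < 1 or self.k_cohorts < 1:
            raise ParameterError("m and k_cohorts must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ParameterError("sample sizes must be >= 2")
        if self.noise_scale < 0:
            raise ParameterError("noise_scale must be >= 0")


@dataclass
class SyntheticTruth:
    """The generating truth a recovery test compares against."""

    theta_true: float
    snp_ids: list
    invalid_ids: list
    alpha: np.ndarray      # per-SNP pleiotropic effect (0 for valid)
    gamma_true: np.ndarray  # per-SNP true standardized exposure effect
    config: SimConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        invalid = set(self.invalid_ids)
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "gamma_true": self.gamma_true,
                "alpha": self.alpha,
                "invalid": [s in invalid for s in self.snp_ids],
            }
        )


def exposure_from_standardized(gamma, n, maf=None, se=None):
    """Invert the exposure standardization: recover per-allele (beta, se).

    The forward transform gamma = beta/(se*sqrt(n)) leaves the per-allele se
    free, so one must be supplied: either directly via ``se`` or as the
    canonical GWAS standard error 1/sqrt(2*maf*(1-maf)*n) of a
    unit-variance trait via ``maf``.
    """
    gamma = np.asarray(gamma, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ParameterError("n must be >= 2")
    if se is None:
        if maf is None:
            raise ParameterError("provide either se or maf")
        maf = np.asarray(maf, dtype=float)
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ParameterError("maf must be in (0, 0.5]")
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    se = np.asarray(se, dtype=float)
    beta = gamma * se * np.sqrt(n)
    return beta, se


def outcome_from_standardized(Gamma, se_Gamma, maf):
    """Invert the outcome standardization: (beta, se) = (Gamma, se_Gamma)/c
    with c = sqrt(2*maf*(1-maf)).  Exact inverse."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ParameterError("maf must be in (0, 0.5]")
    c = np.sqrt(2.0 * maf * (1.0 - maf))
    return np.asarray(Gamma, float) / c, np.asarray(se_Gamma, float) / c


def back_transform(value, se_std, maf, n, role: str = "outcome"):
    """Inverse standardization dispatcher for a single effect.

    ``role="exposure"`` inverts gamma (per-allele se derived from maf and n
    unless ``se_std`` is interpreted as n^(-1/2), which it must equal);
    ``role="outcome"`` inverts Gamma exactly.
    """
    if role == "outcome":
        return outcome_from_standardized(value, se_std, maf)
    if role == "exposure":
        return exposure_from_standardized(value, n, maf=maf)
    raise ParameterError(f"role must be 'exposure' or 'outcome', got {role!r}")


def _assign_alleles(rng, m, palindromic_fraction):
    idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in idx])
    if palindromic_fraction > 0:
        n_pal = int(round(palindromic_fraction * m))
        which = rng.choice(m, size=n_pal, replace=False)
        pidx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n_pal)
        ea[which] = [_PALINDROMIC_PAIRS[i][0] for i in pidx]
        oa[which] = [_PALINDROMIC_PAIRS[i][1] for i in pidx]
    return ea, oa


def _cohort_table(rng, cfg, snp, chrom, pos, ea, oa, eaf, maf,
                  std_effect, std_se, n, trait, role):
    """Back-transform one cohort's standardized observations to a table."""
    if role == "exposure":
        beta, se = exposure_from_standardized(std_effect, n, maf=maf)
    else:
        beta, se = outcome_from_standardized(std_effect, std_se, maf)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    df = pd.DataFrame(
        {
            "snp": snp, "chr": chrom, "pos": pos, "ea": ea, "oa": oa,
            "eaf": eaf, "beta": beta, "se": se, "p": p,
            "n": float(n),
        }
    )[CANONICAL_COLUMNS]
    return SumStatTable(
        df=df,
        trait_name=trait,
        trait_type="binary" if role == "outcome" else "quantitative",
        ancestry_label="synthetic",
    )


def simulate(config: SimConfig):
    """Generate per-cohort exposure and outcome tables plus LD and truth.

    Returns ``(exposure_tables, outcome_tables, ld_info, truth)``.
    Deterministic under ``config.seed``.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m

    snp = np.array([f"rs{i:06d}" for i in range(1, m + 1)])
    chrom = np.full(m, "1")
    spacing = 50_000
    pos = 1_000_000 + spacing * np.arange(m)

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    # report eaf on either strand orientation of the minor allele
    eaf = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)
    ea, oa = _assign_alleles(rng, m, cfg.palindromic_fraction)

    gamma = rng.normal(0.0, cfg.sigma_gamma, size=m)
    if cfg.gamma_positive:
        gamma = np.abs(gamma)
    n_invalid = int(round(cfg.pleio_fraction * m))
    invalid_idx = rng.choice(m, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    alpha = np.zeros(m)
    if n_invalid:
        mean = cfg.pleio_mean if cfg.pleio_mode == "directional" else 0.0
        alpha[invalid_idx] = rng.normal(mean, cfg.pleio_sd, size=n_invalid)
    Gamma = cfg.theta_true * gamma + alpha

    se_g = cfg.n_exposure ** -0.5
    se_G = cfg.n_outcome ** -0.5
    exposure_tables, outcome_tables = [], []
    for c in range(cfg.k_cohorts):
        z_e = rng.standard_normal(m)
        z_y = cfg.rho_overlap * z_e + np.sqrt(1 - cfg.rho_overlap**2) * rng.standard_normal(m)
        g_obs = gamma + cfg.noise_scale * se_g * z_e
        G_obs = Gamma + cfg.noise_scale * se_G * z_y
        exposure_tables.append(
            _cohort_table(rng, cfg, snp, chrom, pos, ea, oa, eaf, maf,
                          g_obs, se_g, cfg.n_exposure, f"exposure_c{c}", "exposure")
        )
        ea_o, oa_o, eaf_o = ea.copy(), oa.copy(), eaf.copy()
        G_tab, seG_tab = G_obs.copy(), np.full(m, se_G)
        if cfg.swapped_fraction > 0:
            n_sw = int(round(cfg.swapped_fraction * m))
            sw = rng.choice(m, size=n_sw, replace=False)
            ea_o[sw], oa_o[sw] = oa[sw], ea[sw]
            eaf_o[sw] = 1.0 - eaf[sw]
            G_tab[sw] = -G_tab[sw]
        outcome_tables.append(
            _cohort_table(rng, cfg, snp, chrom, pos, ea_o, oa_o, eaf_o, maf,
                          G_tab, seG_tab, cfg.n_outcome, f"outcome_c{c}", "outcome")
        )

    ld = LDInfo(positions={s: int(p) for s, p in zip(snp, pos)},
                chroms={s: "1" for s in snp})
    if cfg.ld_blocks is not None:
        block_size, r2_within = cfg.ld_blocks
        for start in range(0, m, int(block_size)):
            block = range(start, min(start + int(block_size), m))
            for i in block:
                for j in block:
                    if i < j:
                        ld.set_r2(snp[i], snp[j], float(r2_within))

    truth = SyntheticTruth(
        theta_true=cfg.theta_true,
        snp_ids=list(snp),
        invalid_ids=sorted(snp[invalid_idx]),
        alpha=alpha,
        gamma_true=gamma,
        config=cfg,
    )
    return exposure_tables, outcome_tables, ld, truth


def config_manifest(cfg: SimConfig) -> dict:
    """Machine-readable echo of the generating configuration."""
    d = asdict(cfg)
    d["maf_range"] = list(d["maf_range"])
    if d["ld_blocks"] is not None:
        d["ld_blocks"] = list(d["ld_blocks"])
    return d
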