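"""End-to-end orchestration: read -> filter -> meta-analyze -> harmonize ->
clump -> standardize -> estimate -> report.

A run is driven by a flat :class:`RunConfig` (loadable from YAML) whose
defaults are the analysis parameters of the motivating study: 500 kb clump
window, index/secondary p thresholds 5e-8, r^2 0.1, frequency filter 1e-4,
pleiotropy alpha 0.05.  Every stage writes its table to the output
directory, record drops are logged with reason codes so instrument
accounting is auditable, and a manifest (config echo + hash) makes reruns
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, MRKitError
from .estimators import egger, imrp, ivw, pleiotropy_test
from .harmonize import harmonize
from .ld import LDInfo, clump
from .meta import meta_analyze
from .mrmix import mrmix
from .standardize import effect_correlation, standardize_pairs
from .sumstats import filter_by_frequency, read_sumstats, write_sumstats

logger = logging.getLogger(__name__)

ALL_ESTIMATORS = ("IVW", "Egger", "IMRP", "MRMix")


@dataclass
class RunConfig:
    exposure_paths: list = field(default_factory=list)
    outcome_paths: list = field(default_factory=list)
    ld_path: str | None = None
    ld_format: str = "long"  # {"long", "matrix"}
    delimiter: str = "\t"
    column_map: dict = field(default_factory=dict)
    min_freq: float = 1e-4
    het_alpha: float = 0.05
    palindromic_policy: str = "infer"
    clump_kb: float = 500.0
    clump_p1: float = 5e-8
    clump_p2: float = 5e-8  # accepted for interface parity; greedy selection uses p1
    clump_r2: float = 0.1
    alpha_pleio: float = 0.05
    rho_overlap: float = 0.0
    estimators: list = field(default_factory=lambda: list(ALL_ESTIMATORS))
    mrmix_grid: list = field(default_factory=lambda: [-2.0, 2.0, 0.01])
    mrmix_n_boot: int = 200
    out_dir: str = "mrkit_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _read_cohorts(paths, cfg, label):
    if not paths:
        raise ConfigurationError(f"no {label} cohort files configured")
    tables = []
    for p in paths:
        if not Path(p).exists():
            raise ConfigurationError(f"{label} file not found: {p}")
        t = read_sumstats(p, column_map=cfg.column_map, delimiter=cfg.delimiter,
                          trait_name=label)
        tables.append(filter_by_frequency(t, cfg.min_freq))
    return tables


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report bundle as an in-memory dict and
    writes per-stage TSVs, a log and a manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mrkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    bundle: dict = {}
    try:
        stage = "read"
        exp_tables = _read_cohorts(config.exposure_paths, config, "exposure")
        out_tables = _read_cohorts(config.outcome_paths, config, "outcome")

        stage = "meta"
        exp_meta, exp_het = meta_analyze(exp_tables, het_alpha=config.het_alpha)
        out_meta, out_het = meta_analyze(out_tables, het_alpha=config.het_alpha)
        write_sumstats(exp_meta, out / "meta_exposure.tsv")
        write_sumstats(out_meta, out / "meta_outcome.tsv")
        exp_het.to_csv(out / "heterogeneity_exposure.tsv", sep="\t", index=False)
        out_het.to_csv(out / "heterogeneity_outcome.tsv", sep="\t", index=False)

        stage = "harmonize"
        pairs = harmonize(exp_meta, out_meta, palindromic_policy=config.palindromic_policy)
        pairs.to_csv(out / "harmonized.tsv", sep="\t", index=False)
        logger.info("harmonize: %d pairs, drops %s", len(pairs), pairs.attrs["drop_counts"])

        stage = "clump"
        if config.ld_path:
            ld = (LDInfo.from_matrix(config.ld_path) if config.ld_format == "matrix"
                  else LDInfo.from_long_table(config.ld_path))
        else:
            ld = LDInfo()  # no LD source: all pairs independent (logged by clump)
        selected = clump(
            pairs.rename(columns={"p_exp": "p"}), ld,
            p1=config.clump_p1, r2_max=config.clump_r2, window_kb=config.clump_kb,
        )
        pd.Series(selected, name="snp").to_csv(out / "instruments.tsv", sep="\t", index=False)
        logger.info("clump: selected %d/%d instruments", len(selected), len(pairs))
        instruments = pairs[pairs["snp"].isin(selected)].reset_index(drop=True)

        stage = "standardize"
        std = standardize_pairs(instruments)
        std.to_csv(out / "standardized.tsv", sep="\t", index=False)
        corr = effect_correlation(std) if len(std) >= 3 else None
        if corr is not None:
            summary = pd.DataFrame(
                [
                    {"quantity": "exposure_effects", **corr.gamma_summary},
                    {"quantity": "outcome_effects", **corr.Gamma_summary},
                    {"quantity": "correlation", "mean": corr.rho_hat,
                     "sd": corr.se_rho, "min": np.nan, "max": np.nan},
                ]
            )
            summary.to_csv(out / "effect_summary.tsv", sep="\t", index=False)
            bundle["effect_correlation"] = corr

        stage = "estimate"
        rows, profile = [], None
        pleio_frame = None
        for method in config.estimators:
            if method == "IVW":
                rows.append(ivw(std).as_dict())
            elif method == "Egger":
                rows.append(egger(std).as_dict())
            elif method == "IMRP":
                est, pleio_frame = imrp(std, alpha_pleio=config.alpha_pleio,
                                        rho_overlap=config.rho_overlap)
                rows.append(est.as_dict())
            elif method == "MRMix":
                lo, hi, step = config.mrmix_grid
                grid = np.round(np.arange(lo, hi + step / 2, step), 10)
                est, profile = mrmix(std, theta_grid=grid,
                                     n_boot=config.mrmix_n_boot, seed=config.seed)
                rows.append(est.as_dict())
            else:
                raise ConfigurationError(f"unknown estimator {method!r}")
        estimates = pd.DataFrame(rows)
        estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
        if pleio_frame is None and len(std) >= 3:
            pleio_frame = pleiotropy_test(std, ivw(std).theta, config.rho_overlap)
        if pleio_frame is not None:
            pleio_frame.to_csv(out / "pleiotropy.tsv", sep="\t", index=False)
        if profile is not None:
            profile.to_frame().to_csv(out / "mrmix_profile.tsv", sep="\t", index=False)

        bundle.update(
            {
                "exposure_meta": exp_meta, "outcome_meta": out_meta,
                "exposure_het": exp_het, "outcome_het": out_het,
                "harmonized": pairs, "instruments": selected,
                "standardized": std, "estimates": estimates,
                "pleiotropy": pleio_frame, "profile": profile,
            }
        )

        manifest = {
            "mrkit_version": __version__,
            "config": asdict(config),
            "config_digest": config.digest(),
            "n_harmonized": int(len(pairs)),
            "n_instruments": int(len(selected)),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        return bundle
    except MRKitError as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise MRKitError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
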