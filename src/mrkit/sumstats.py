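"""Reading, validating, filtering and writing GWAS summary-statistic tables.

One GWAS lives in a :class:`SumStatTable`: a pandas DataFrame with the
canonical columns ``snp, chr, pos, ea, oa, eaf, beta, se, p, n`` plus trait
metadata.  Source files in arbitrary delimited dialects are mapped onto this
schema via a ``column_map``, so estimator code never sees format drift.

Validation drops (and counts) records violating the per-variant invariants:
positive standard error, allele frequency in [0, 1], p in (0, 1], sample
size >= 1, distinct alleles, unique variant id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: canonical column order of the internal schema
CANONICAL_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

_NUMERIC_COLUMNS = ["pos", "eaf", "beta", "se", "p", "n"]


@dataclass
class SumStatTable:
    """Per-variant association records for one GWAS.

    ``df`` holds the canonical columns; ``eaf`` may be NaN (missing frequency
    is tolerated until a step needs it).  ``drop_counts`` records how many
    source rows each validation rule removed.
    """

    df: pd.DataFrame
    trait_name: str = ""
    trait_type: str = "quantitative"  # {"binary", "quantitative"}
    ancestry_label: str = ""
    drop_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'quantitative', got {self.trait_type!r}"
            )
        if self.df["snp"].duplicated().any():
            dupes = self.df["snp"][self.df["snp"].duplicated()].tolist()[:5]
            raise ConfigurationError(f"duplicate snp ids in table: {dupes}")

    def __len__(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame) -> "SumStatTable":
        return replace(self, df=df.reset_index(drop=True))


def _validate(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows failing record invariants; return kept rows and drop counts."""
    counts: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            counts[reason] = counts.get(reason, 0) + k
            df = df[~mask]

    _drop(df["snp"].isna() | (df["snp"].astype(str).str.len() == 0), "missing_snp_id")
    _drop(df["snp"].duplicated(keep="first"), "duplicate_snp_id")
    _drop(~(df["se"] > 0), "nonpositive_se")
    _drop(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)), "eaf_out_of_range")
    _drop(~((df["p"] > 0) & (df["p"] <= 1)), "pvalue_out_of_range")
    _drop(~(df["n"] >= 1), "invalid_n")
    _drop(df["beta"].isna(), "missing_beta")
    _drop(df["ea"].str.upper() == df["oa"].str.upper(), "identical_alleles")
    return df, counts


def read_sumstats(
    path,
    column_map: dict | None = None,
    delimiter: str = "\t",
    trait_name: str = "",
    trait_type: str = "quantitative",
    ancestry_label: str = "",
) -> SumStatTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row; gzip is detected by suffix.
    column_map : dict, optional
        Mapping of canonical name -> source column name, e.g.
        ``{"beta": "Effect"}``.  Unmapped canonical names are looked up
        verbatim in the header.
    delimiter : str
        Field separator (tab by default).

    Rows violating record invariants are dropped and counted in
    ``SumStatTable.drop_counts``; a missing mandatory column raises
    :class:`ConfigurationError`; if more than half the rows have unparseable
    numerics the file is rejected with :class:`FormatError`.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=delimiter, dtype=str, compression="infer")
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise ConfigurationError(
                f"column {src!r} (canonical {canon!r}) not found in header of {path}"
            )
        rename[src] = canon
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()

    n_rows = len(df)
    bad_numeric = np.zeros(n_rows, dtype=bool)
    for col in _NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if col != "eaf":  # eaf may legitimately be empty
            bad_numeric |= (parsed.isna() & df[col].notna()).to_numpy()
        df[col] = parsed
    if n_rows and bad_numeric.sum() > 0.5 * n_rows:
        raise FormatError(
            f"{path}: {int(bad_numeric.sum())}/{n_rows} rows have unparseable numerics"
        )

    df["snp"] = df["snp"].astype(str)
    df["chr"] = df["chr"].astype(str)
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()

    counts: dict[str, int] = {}
    k = int(bad_numeric.sum())
    if k:
        counts["unparseable_numeric"] = k
        df = df[~bad_numeric]
    df, inv_counts = _validate(df)
    for reason, c in inv_counts.items():
        counts[reason] = counts.get(reason, 0) + c
    if counts:
        logger.info("read_sumstats(%s): dropped %s", path, counts)

    return SumStatTable(
        df=df.reset_index(drop=True),
        trait_name=trait_name,
        trait_type=trait_type,
        ancestry_label=ancestry_label,
        drop_counts=counts,
    )


def filter_by_frequency(table: SumStatTable, min_freq: float) -> SumStatTable:
    """Keep records with minor allele frequency strictly above ``min_freq``.

    MAF is min(eaf, 1 - eaf).  Records with missing eaf survive only a
    threshold of 0 (downstream standardization needs MAF); otherwise they are
    dropped and counted.  Order is preserved; the filter is idempotent and
    monotone in ``min_freq``.
    """
    if not 0 <= min_freq <= 0.5:
        raise ConfigurationError(f"min_freq must be in [0, 0.5], got {min_freq}")
    df = table.df
    if min_freq == 0:
        return table.with_df(df)
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep = maf > min_freq  # NaN compares False -> dropped
    n_missing = int(df["eaf"].isna().sum())
    out = table.with_df(df[keep])
    out.drop_counts = dict(table.drop_counts)
    dropped = len(df) - int(keep.sum())
    if dropped:
        out.drop_counts["maf_filter"] = out.drop_counts.get("maf_filter", 0) + dropped
        if n_missing:
            logger.info("filter_by_frequency: %d records had missing eaf", n_missing)
    return out


def write_sumstats(table: SumStatTable, path) -> None:
    """Write the canonical tab-delimited representation.

    Floats are written at full repr precision so that
    ``read_sumstats(write_sumstats(t))`` reproduces ``t`` exactly.
    """
    table.df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)
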