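"""Fixed-effect (inverse-variance-weighted) meta-analysis of GWAS cohorts.

Per-variant estimates from k cohorts are combined with weights 1/se^2:

    beta_meta = sum(beta_k / se_k^2) / sum(1 / se_k^2)
    se_meta   = (sum(1 / se_k^2))^(-1/2)

Between-study heterogeneity is screened with Cochran's Q on k-1 degrees of
freedom, flagged at a Bonferroni-adjusted threshold across all variants
tested in more than one cohort.  Flagged variants are retained but reported.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import _match_orientation
from .sumstats import CANONICAL_COLUMNS, SumStatTable

logger = logging.getLogger(__name__)

META_COLUMNS = ["snp", "Q", "Q_pvalue", "k", "het_flag"]


def _align_to_reference(ref_ea, ref_oa, row):
    """Sign-align one cohort record to the reference allele pair.

    Returns (beta, eaf) aligned, or None when alleles are unreconcilable.
    """
    rel = _match_orientation(ref_ea, ref_oa, row.ea, row.oa)
    if rel is None:
        return None
    if rel in ("swap", "strand_swap"):
        eaf = 1.0 - row.eaf if not np.isnan(row.eaf) else np.nan
        return -row.beta, eaf
    return row.beta, row.eaf


def meta_analyze(
    tables: list[SumStatTable], het_alpha: float = 0.05
) -> tuple[SumStatTable, pd.DataFrame]:
    """Combine per-cohort tables into one fixed-effect meta-analyzed table.

    Variants are matched by id; each cohort's record is sign-aligned to the
    allele pair of the first cohort reporting the variant (swap or strand
    flip), and unreconcilable records are excluded with a logged count.
    Variants present in a single cohort pass through with Q undefined and
    ``het_flag`` False.  Combined sample size is the sum over cohorts; the
    combined eaf is the n-weighted mean.

    Returns the meta table and a per-variant heterogeneity frame with
    columns ``snp, Q, Q_pvalue, k, het_flag``.
    """
    if not tables:
        raise ValueError("meta_analyze needs at least one table")
    if len(tables) == 1:
        t = tables[0]
        het = pd.DataFrame(
            {
                "snp": t.df["snp"],
                "Q": np.nan,
                "Q_pvalue": np.nan,
                "k": 1,
                "het_flag": False,
            }
        )
        return t.with_df(t.df.copy()), het

    # reference allele pair per variant: first table reporting it
    ref: dict[str, tuple] = {}
    order: list[str] = []
    for t in tables:
        for row in t.df.itertuples(index=False):
            if row.snp not in ref:
                ref[row.snp] = (row.ea, row.oa, row.chr, row.pos)
                order.append(row.snp)

    per_snp: dict[str, list] = {s: [] for s in order}
    n_excluded = 0
    for t in tables:
        for row in t.df.itertuples(index=False):
            ea, oa, _, _ = ref[row.snp]
            aligned = _align_to_reference(ea, oa, row)
            if aligned is None:
                n_excluded += 1
                continue
            beta, eaf = aligned
            per_snp[row.snp].append((beta, row.se, eaf, row.n, row.p))
    if n_excluded:
        logger.info("meta_analyze: excluded %d unreconcilable cohort records", n_excluded)

    rows = []
    for snp in order:
        recs = per_snp[snp]
        if not recs:
            continue
        ea, oa, chrom, pos = ref[snp]
        beta = np.array([r[0] for r in recs])
        se = np.array([r[1] for r in recs])
        eaf = np.array([r[2] for r in recs], dtype=float)
        n = np.array([r[3] for r in recs], dtype=float)
        k = len(recs)
        if k == 1:
            rows.append((snp, chrom, pos, ea, oa, eaf[0], beta[0], se[0], recs[0][4],
                         n[0], np.nan, np.nan, 1))
            continue
        w = 1.0 / se**2
        b_meta = float(np.sum(w * beta) / np.sum(w))
        se_meta = float(np.sum(w) ** -0.5)
        p_meta = float(2 * stats.norm.sf(abs(b_meta / se_meta)))
        q = float(np.sum(w * (beta - b_meta) ** 2))
        q_p = float(stats.chi2.sf(q, k - 1))
        if np.isnan(eaf).all():
            eaf_meta = np.nan
        else:
            ok = ~np.isnan(eaf)
            eaf_meta = float(np.sum(eaf[ok] * n[ok]) / np.sum(n[ok]))
        rows.append((snp, chrom, pos, ea, oa, eaf_meta, b_meta, se_meta, p_meta,
                     float(np.sum(n)), q, q_p, k))

    df = pd.DataFrame(
        rows,
        columns=CANONICAL_COLUMNS + ["Q", "Q_pvalue", "k"],
    )
    m_tested = int((df["k"] > 1).sum())
    thresh = het_alpha / m_tested if m_tested else np.nan
    het_flag = (df["Q_pvalue"] < thresh).fillna(False)
    het = pd.DataFrame(
        {
            "snp": df["snp"],
            "Q": df["Q"],
            "Q_pvalue": df["Q_pvalue"],
            "k": df["k"],
            "het_flag": het_flag.astype(bool),
        }
    )
    n_flag = int(het["het_flag"].sum())
    if n_flag:
        logger.info("meta_analyze: %d variants heterogeneous at Bonferroni %g", n_flag, thresh)
    meta_table = replace(
        tables[0],
        df=df[CANONICAL_COLUMNS].reset_index(drop=True),
        drop_counts={"unreconcilable_alleles": n_excluded} if n_excluded else {},
    )
    return meta_table, het
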