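"""Allele harmonization between exposure and outcome summary statistics.

Both tables report each variant relative to an (effect allele, other allele)
pair, but the pair may be swapped, reported on the opposite strand, or both.
Harmonization rewrites the outcome record so that its effect allele equals
the exposure's: a swap negates the outcome beta and reflects its allele
frequency; a strand flip relabels via base complement without sign change.

Palindromic variants (A/T or C/G) are strand-ambiguous — swap and strand
flip produce the same allele labels — so orientation can only be inferred
from allele frequency.  Three policies are offered:

``infer`` (default)
    Keep the variant when both minor-allele frequencies are below
    ``palindromic_maf_max`` (0.4); flip when the two eafs sit on opposite
    sides of 0.5, otherwise leave as-is.  Drop when either frequency is too
    close to 0.5 to be informative.
``drop``
    Remove all palindromic variants.
``keep``
    Align by allele labels alone, ignoring strand ambiguity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import HarmonizationError
from .sumstats import SumStatTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str | None:
    """Base complement of a single-nucleotide allele; None if not applicable."""
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def is_palindromic(ea: str, oa: str) -> bool:
    """True when the allele pair is its own strand complement (A/T or C/G)."""
    return complement(ea) == oa


def _match_orientation(ref_ea, ref_oa, ea, oa):
    """Classify how (ea, oa) relates to the reference pair.

    Returns one of ``"same"``, ``"swap"``, ``"strand"``, ``"strand_swap"``
    or None when the pairs cannot be reconciled.  Strand logic is only
    attempted for single-base A/C/G/T alleles (indels are label-matched
    only).
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return "swap"
    cea, coa = complement(ea), complement(oa)
    if cea is None or coa is None or len(ea) > 1 or len(oa) > 1:
        return None
    if (cea, coa) == (ref_ea, ref_oa):
        return "strand"
    if (cea, coa) == (ref_oa, ref_ea):
        return "strand_swap"
    return None


def harmonize(
    exposure: SumStatTable,
    outcome: SumStatTable,
    palindromic_policy: str = "infer",
    palindromic_maf_max: float = 0.4,
) -> pd.DataFrame:
    """Merge exposure and outcome by variant id and align effect alleles.

    Returns a DataFrame with one row per retained variant and columns
    ``snp, chr, pos, ea, oa``, exposure fields suffixed ``_exp``, outcome
    fields suffixed ``_out``, plus ``flipped`` and ``palindromic`` booleans.
    Drop reasons are counted in ``df.attrs["drop_counts"]``.

    Raises :class:`HarmonizationError` when the id intersection is empty.
    """
    if palindromic_policy not in ("infer", "drop", "keep"):
        raise HarmonizationError(f"unknown palindromic policy {palindromic_policy!r}")

    exp = exposure.df.add_suffix("_exp").rename(columns={"snp_exp": "snp"})
    out = outcome.df.add_suffix("_out").rename(columns={"snp_out": "snp"})
    merged = exp.merge(out, on="snp", how="inner")
    if merged.empty:
        ex_ids = exposure.df["snp"].head(3).tolist()
        out_ids = outcome.df["snp"].head(3).tolist()
        raise HarmonizationError(
            "no shared variant ids between exposure and outcome tables "
            f"(exposure ids look like {ex_ids}, outcome ids like {out_ids}); "
            "check the id column and format"
        )

    counts = {"unreconcilable_alleles": 0, "palindromic_dropped": 0}
    keep = np.ones(len(merged), dtype=bool)
    flip = np.zeros(len(merged), dtype=bool)
    palin = np.zeros(len(merged), dtype=bool)

    ea_e = merged["ea_exp"].to_numpy()
    oa_e = merged["oa_exp"].to_numpy()
    ea_o = merged["ea_out"].to_numpy()
    oa_o = merged["oa_out"].to_numpy()
    eaf_e = merged["eaf_exp"].to_numpy(dtype=float)
    eaf_o = merged["eaf_out"].to_numpy(dtype=float)

    for i in range(len(merged)):
        pal = is_palindromic(ea_e[i], oa_e[i])
        palin[i] = pal
        rel = _match_orientation(ea_e[i], oa_e[i], ea_o[i], oa_o[i])
        if rel is None:
            keep[i] = False
            counts["unreconcilable_alleles"] += 1
            continue
        if not pal:
            flip[i] = rel in ("swap", "strand_swap")
            continue
        # palindromic: swap and strand_swap are indistinguishable
        if palindromic_policy == "drop":
            keep[i] = False
            counts["palindromic_dropped"] += 1
        elif palindromic_policy == "keep":
            flip[i] = rel in ("swap", "strand_swap")
        else:  # infer orientation from allele frequency
            f_e, f_o = eaf_e[i], eaf_o[i]
            maf_e = min(f_e, 1 - f_e)
            maf_o = min(f_o, 1 - f_o)
            if np.isnan(maf_e) or np.isnan(maf_o) or max(maf_e, maf_o) >= palindromic_maf_max:
                keep[i] = False
                counts["palindromic_dropped"] += 1
            else:
                # discordant frequency sides -> the outcome reports the
                # complementary physical allele -> sign flip
                flip[i] = (f_e < 0.5) != (f_o < 0.5)

    res = merged[keep].reset_index(drop=True).copy()
    fl = flip[keep]
    res["beta_out"] = np.where(fl, -res["beta_out"], res["beta_out"])
    res["eaf_out"] = np.where(fl, 1.0 - res["eaf_out"], res["eaf_out"])
    res["ea_out"] = res["ea_exp"]
    res["oa_out"] = res["oa_exp"]
    res["flipped"] = fl
    res["palindromic"] = palin[keep]
    res = res.rename(columns={"ea_exp": "ea", "oa_exp": "oa",
                              "chr_exp": "chr", "pos_exp": "pos"})
    res = res.drop(columns=["ea_out", "oa_out", "chr_out", "pos_out"])
    res.attrs["drop_counts"] = counts
    if any(counts.values()):
        logger.info("harmonize: dropped %s", counts)
    return res
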