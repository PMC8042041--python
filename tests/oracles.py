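"""Independent reference implementations used only to cross-check mrkit.

These deliberately use different machinery from the package: linear-algebra
solves instead of summation formulas, statsmodels instead of hand-written
normal equations, and a plain-Python greedy walk for clumping.
"""

import numpy as np


def ivw_oracle(gamma, Gamma, se_Gamma):
    """Weighted origin regression via explicit least-squares solve."""
    w = 1.0 / np.asarray(se_Gamma, float) ** 2
    X = (np.sqrt(w) * np.asarray(gamma, float))[:, None]
    y = np.sqrt(w) * np.asarray(Gamma, float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    se = float(np.sqrt(np.linalg.inv(X.T @ X)[0, 0]))
    return float(coef[0]), se


def egger_oracle(gamma, Gamma, se_Gamma):
    """Weighted regression with intercept via statsmodels WLS.

    Returns (slope, slope_se, intercept, intercept_se) with the residual
    dispersion floored at 1, the convention the package uses.
    """
    import statsmodels.api as sm

    g = np.asarray(gamma, float)
    G = np.asarray(Gamma, float)
    s = np.where(g < 0, -1.0, 1.0)
    g, G = g * s, G * s
    res = sm.WLS(G, sm.add_constant(g), weights=1.0 / np.asarray(se_Gamma, float) ** 2).fit()
    corr = np.sqrt(max(1.0, res.scale) / res.scale)
    return (
        float(res.params[1]),
        float(res.bse[1] * corr),
        float(res.params[0]),
        float(res.bse[0] * corr),
    )


def brute_clump(records, r2_lookup, p1, r2_max, window_kb):
    """Plain-Python greedy index-SNP selection.

    ``records`` is a list of dicts with keys snp, chr, pos, p;
    ``r2_lookup(a, b)`` returns the pairwise squared correlation.
    """
    cand = sorted((r for r in records if r["p"] < p1), key=lambda r: (r["p"], r["snp"]))
    selected, removed = [], set()
    for r in cand:
        if r["snp"] in removed:
            continue
        selected.append(r["snp"])
        for other in cand:
            if other["snp"] in removed or other["snp"] in selected:
                continue
            if (
                other["chr"] == r["chr"]
                and abs(other["pos"] - r["pos"]) <= window_kb * 1000
                and r2_lookup(r["snp"], other["snp"]) >= r2_max
            ):
                removed.add(other["snp"])
    return selected


def random_clump_instance(rng, max_snps=20):
    """A random clumping problem: records, an r2 lookup, and its pair dict."""
    n = int(rng.integers(3, max_snps + 1))
    records = []
    for i in range(n):
        records.append(
            {
                "snp": f"rs{i:03d}",
                "chr": str(rng.integers(1, 3)),
                "pos": int(rng.integers(0, 2_000_000)),
                "p": float(10.0 ** rng.uniform(-30, -4)),
            }
        )
    pairs = {}
    ids = [r["snp"] for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.6:  # leave some pairs missing
                pairs[(ids[i], ids[j])] = float(rng.random())

    def lookup(a, b):
        if a == b:
            return 1.0
        return pairs.get((a, b), pairs.get((b, a), 0.0))

    return records, lookup, pairs
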