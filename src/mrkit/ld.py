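"""Pairwise linkage-disequilibrium lookup and greedy LD clumping.

Clumping re-implements the PLINK ``--clump`` selection: among variants with
p below the index threshold ``p1``, repeatedly promote the smallest-p
remaining variant to index SNP and discard every remaining variant on the
same chromosome within ``window_kb`` whose squared correlation with it is at
least ``r2_max``.  Ties on p are broken lexicographically by variant id so
the selection is independent of input row order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class LDInfo:
    """Symmetric r^2 lookup with per-variant positions.

    Pairs absent from the source are treated as r^2 = 0 (independent), with
    a counter of how often that default was used — matching how PLINK treats
    pairs missing from the reference panel.
    """

    def __init__(self, pairs: dict | None = None,
                 positions: dict | None = None,
                 chroms: dict | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), v in (pairs or {}).items():
            self.set_r2(a, b, v)
        self.positions = dict(positions or {})
        self.chroms = dict(chroms or {})
        self.n_missing_lookups = 0

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2({a},{b}) = {r2} outside [0, 1]")
        self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        val = self._r2.get(self._key(a, b))
        if val is None:
            self.n_missing_lookups += 1
            return 0.0
        return val

    @classmethod
    def from_long_table(cls, path, delimiter: str | None = None) -> "LDInfo":
        """Parse a PLINK ``.ld``-style long table with SNP_A, SNP_B, R2 columns."""
        df = pd.read_csv(path, sep=delimiter or r"\s+", engine="python")
        cols = {c.upper(): c for c in df.columns}
        for need in ("SNP_A", "SNP_B", "R2"):
            if need not in cols:
                raise ValueError(f"{path}: missing column {need}")
        info = cls()
        for row in df.itertuples(index=False):
            info.set_r2(
                str(getattr(row, cols["SNP_A"])),
                str(getattr(row, cols["SNP_B"])),
                float(getattr(row, cols["R2"])),
            )
        if "BP_A" in cols and "BP_B" in cols:
            for row in df.itertuples(index=False):
                info.positions[str(getattr(row, cols["SNP_A"]))] = int(getattr(row, cols["BP_A"]))
                info.positions[str(getattr(row, cols["SNP_B"]))] = int(getattr(row, cols["BP_B"]))
        return info

    @classmethod
    def from_matrix(cls, path, delimiter: str = "\t") -> "LDInfo":
        """Parse a square r^2 matrix with variant ids as header and row labels."""
        mat = pd.read_csv(path, sep=delimiter, index_col=0)
        mat.index = mat.index.astype(str)
        mat.columns = mat.columns.astype(str)
        if list(mat.index) != list(mat.columns):
            raise ValueError(f"{path}: row and column labels differ")
        arr = mat.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError(f"{path}: LD matrix is not symmetric")
        info = cls()
        ids = list(mat.index)
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                if arr[i, j] != 0.0:
                    info.set_r2(a, ids[j], arr[i, j])
        return info


def clump(
    df: pd.DataFrame,
    ld: LDInfo,
    p1: float = 5e-8,
    r2_max: float = 0.1,
    window_kb: float = 500.0,
    p_col: str = "p",
) -> list[str]:
    """Greedy index-SNP selection; returns selected ids in selection order.

    ``df`` needs columns ``snp, chr, pos`` and a p-value column.  Positions
    and chromosomes fall back to ``ld.positions`` / ``ld.chroms`` when the
    frame lacks them.
    """
    if p1 <= 0 or r2_max <= 0 or window_kb <= 0:
        raise ValueError("clump thresholds must be positive")
    cand = df[df[p_col] < p1]
    if cand.empty:
        return []
    snp = cand["snp"].astype(str).to_numpy()
    if "pos" in cand.columns:
        pos = cand["pos"].to_numpy(dtype=float)
        chrom = cand["chr"].astype(str).to_numpy()
    else:
        pos = np.array([ld.positions[s] for s in snp], dtype=float)
        chrom = np.array([str(ld.chroms.get(s, "1")) for s in snp])
    pvals = cand[p_col].to_numpy(dtype=float)

    order = np.lexsort((snp, pvals))  # ascending p, ties by id
    window = window_kb * 1000.0
    alive = np.ones(len(order), dtype=bool)
    selected: list[str] = []
    for rank, idx in enumerate(order):
        if not alive[rank]:
            continue
        index_snp = snp[idx]
        selected.append(index_snp)
        alive[rank] = False
        for later in range(rank + 1, len(order)):
            if not alive[later]:
                continue
            j = order[later]
            if chrom[j] != chrom[idx] or abs(pos[j] - pos[idx]) > window:
                continue
            if ld.r2(index_snp, snp[j]) >= r2_max:
                alive[later] = False
    if ld.n_missing_lookups:
        logger.warning(
            "clump: %d variant pairs absent from LD source treated as r2=0",
            ld.n_missing_lookups,
        )
    return selected
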