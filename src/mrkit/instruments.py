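"""Instrument selection and strength diagnostics.

Instruments are SNPs associated with the exposure at genome-wide significance
(p < 5e-8 by default), pruned to approximate linkage-equilibrium by greedy
clumping (retain pairwise r^2 < 0.01 within a 10,000 kb window, keeping the
most significant SNP per locus). Instrument strength is summarised by per-SNP
F statistics and the variance in the exposure they jointly explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .summary_data import SummaryDataError, SummaryDataset, HarmonizedSet

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.01
CLUMP_WINDOW_KB = 10_000.0


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r^2) matrix keyed by rsID."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r2.shape} does not match {k} rsids")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("LD matrix diagonal must equal 1")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("LD matrix must be symmetric")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("LD r^2 entries must lie in [0, 1]")
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def lookup(self, a: str, b: str) -> float | None:
        """r^2 between two rsids, or None when either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(path, sep="\t")


@dataclass
class StrengthReport:
    """Instrument-strength summary for a harmonised instrument set."""

    per_snp_F: np.ndarray
    mean_F: float
    approx_R2: float
    score_F: float
    n_snps: int
    n_exposure: float


def filter_genome_wide(ds: SummaryDataset, p_threshold: float = GENOME_WIDE_P) -> SummaryDataset:
    """Keep SNPs with exposure p-value strictly below ``p_threshold``."""
    if not len(ds):
        return ds
    kept = ds.table[ds.table["pvalue"] < p_threshold]
    if kept.empty:
        logger.warning("%s: no SNPs reach p < %g", ds.trait_name, p_threshold)
    return SummaryDataset(ds.trait_name, ds.trait_type, kept.reset_index(drop=True),
                          ds.provenance)


def greedy_clump(ds: SummaryDataset, ld: LDMatrix | None = None,
                 r2_max: float = CLUMP_R2,
                 window_kb: float = CLUMP_WINDOW_KB) -> SummaryDataset:
    """Greedy LD clumping: prune to an approximately independent SNP set.

    Repeatedly select the remaining SNP with the smallest p-value (ties broken
    by rsid), then remove every unselected SNP on the same chromosome within
    ``window_kb`` whose r^2 with the index SNP is >= ``r2_max``; "independent"
    retained pairs therefore satisfy r^2 < r2_max. Pairs absent from ``ld``
    are treated as unlinked (r^2 = 0) with a warning. Without an LD matrix,
    window-only pruning is performed (positions required). Returns the
    selection sorted by chromosome then position.
    """
    tab = ds.table
    if ld is None and tab["pos"].isna().any():
        raise SummaryDataError("greedy_clump without an LD matrix requires positions")
    if len(tab) == 0:
        return ds

    order = tab.sort_values(["pvalue", "rsid"], kind="mergesort").index.to_list()
    alive = set(tab.index)
    selected: list[int] = []
    warned_missing = False

    for idx in order:
        if idx not in alive:
            continue
        selected.append(idx)
        alive.discard(idx)
        row = tab.loc[idx]
        for j in list(alive):
            other = tab.loc[j]
            same_chr = (pd.notna(row["chrom"]) and pd.notna(other["chrom"])
                        and str(row["chrom"]) == str(other["chrom"]))
            if not same_chr:
                continue
            if pd.notna(row["pos"]) and pd.notna(other["pos"]):
                if abs(float(row["pos"]) - float(other["pos"])) > window_kb * 1000:
                    continue
            r2 = ld.lookup(row["rsid"], other["rsid"]) if ld is not None else None
            if r2 is None:
                if ld is not None and not warned_missing:
                    logger.warning("clump: some pairs absent from LD matrix; assuming r^2 = 0")
                    warned_missing = True
                r2 = 0.0 if ld is not None else 1.0  # window-only pruning links all in-window pairs
            if r2 >= r2_max:
                alive.discard(j)

    kept = tab.loc[selected].sort_values(["chrom", "pos", "rsid"]).reset_index(drop=True)
    return SummaryDataset(ds.trait_name, ds.trait_type, kept, ds.provenance)


def instrument_strength(h: HarmonizedSet, n_exposure: float) -> StrengthReport:
    """Per-SNP F statistics and approximate exposure variance explained.

    F_j = (beta_exp_j / se_exp_j)^2; each SNP's variance explained is
    r2_j = F_j / (F_j + n - 2), summed into approx_R2; the K-instrument score
    F = R2 (n - K - 1) / (K (1 - R2)) summarises joint strength (> 10 is the
    conventional weak-instrument bar).
    """
    if not len(h):
        raise SummaryDataError("instrument_strength requires a non-empty harmonised set")
    k = len(h)
    if not n_exposure > k + 1:
        raise SummaryDataError(f"n_exposure ({n_exposure}) must exceed n_snps + 1 ({k + 1})")
    beta, se, _, _ = h.arrays()
    per_f = (beta / se) ** 2
    r2_j = per_f / (per_f + n_exposure - 2)
    approx_r2 = float(r2_j.sum())
    score_f = approx_r2 * (n_exposure - k - 1) / (k * (1 - approx_r2))
    return StrengthReport(per_snp_F=per_f, mean_F=float(per_f.mean()),
                          approx_R2=approx_r2, score_F=float(score_f),
                          n_snps=k, n_exposure=float(n_exposure))
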