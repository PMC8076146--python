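"""Multivariable MR: direct effects conditional on co-exposures.

Regressing outcome betas jointly on several exposures' betas (no intercept,
weights 1/se_out^2) estimates each exposure's *direct* effect on the outcome,
i.e. the effect not flowing through the co-exposures. When a co-exposure
mediates the primary exposure's effect, the primary coefficient attenuates
toward the direct effect while univariable IVW keeps returning the total
effect — the standard mediation contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EstimationError, HetStats, MREstimate, _het_stats, to_or
from .summary_data import SummaryDataError, SummaryDataset, is_palindromic

logger = logging.getLogger(__name__)


@dataclass
class MVHarmonizedSet:
    """SNP associations with K exposures and one outcome, allele-aligned.

    ``beta_exp`` and ``se_exp`` are J x K arrays; column 0 is the primary
    exposure. Requires more SNPs than exposures (J > K).
    """

    exposure_names: list[str]
    outcome_name: str
    rsids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    dropped: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, float))
        self.beta_out = np.asarray(self.beta_out, float)
        self.se_out = np.asarray(self.se_out, float)
        j, k = self.beta_exp.shape
        if k < 2:
            raise SummaryDataError("multivariable MR needs at least 2 exposures")
        if len(self.exposure_names) != k:
            raise SummaryDataError("exposure_names length does not match beta matrix")
        if j <= k:
            raise SummaryDataError(f"need more SNPs than exposures (J={j}, K={k})")
        if not (self.se_out > 0).all():
            raise SummaryDataError("se_out must be positive for all records")

    @property
    def n_snps(self) -> int:
        return self.beta_exp.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.beta_exp.shape[1]


def harmonize_multi(exposure_sets: list[SummaryDataset], outcome: SummaryDataset,
                    palindrome_policy: str = "infer_by_frequency",
                    ambiguity_band: float = 0.08) -> MVHarmonizedSet:
    """Align several exposure datasets and one outcome to common effect alleles.

    The first exposure is the primary one and defines the reference allele
    coding per SNP; only SNPs present in *every* dataset survive. Swapped
    alleles flip the trait's beta; palindromic SNPs follow the same frequency
    policy as two-trait harmonisation; other configurations drop the SNP.
    """
    if len(exposure_sets) < 2:
        raise SummaryDataError("harmonize_multi needs >= 2 exposure datasets")
    primary = exposure_sets[0]
    others = [ds.table.set_index("rsid") for ds in exposure_sets[1:] + [outcome]]

    rsids, betas, ses, b_out, s_out = [], [], [], [], []
    dropped: list[dict] = []
    lo, hi = 0.5 - ambiguity_band, 0.5 + ambiguity_band

    for row in primary.table.itertuples(index=False):
        ea, oa = row.effect_allele, row.other_allele
        palin = is_palindromic(ea, oa)
        if palin and palindrome_policy == "drop_all":
            dropped.append({"rsid": row.rsid, "reason": "palindromic-dropped"})
            continue
        row_betas, row_ses = [row.beta], [row.se]
        ok, reason = True, ""
        for tab in others:
            if row.rsid not in tab.index:
                ok, reason = False, "missing-in-a-dataset"
                break
            o = tab.loc[row.rsid]
            if (o["effect_allele"], o["other_allele"]) == (ea, oa):
                sign, eaf_o = 1.0, o["eaf"]
            elif (o["effect_allele"], o["other_allele"]) == (oa, ea):
                sign = -1.0
                eaf_o = np.nan if pd.isna(o["eaf"]) else 1.0 - float(o["eaf"])
            else:
                ok, reason = False, "allele-mismatch"
                break
            if palin:
                if (pd.isna(row.eaf) or pd.isna(eaf_o)
                        or lo <= float(row.eaf) <= hi or lo <= float(eaf_o) <= hi):
                    ok, reason = False, "palindromic-ambiguous"
                    break
                if (float(row.eaf) > 0.5) != (float(eaf_o) > 0.5):
                    sign = -sign
            row_betas.append(sign * float(o["beta"]))
            row_ses.append(float(o["se"]))
        if not ok:
            dropped.append({"rsid": row.rsid, "reason": reason})
            continue
        rsids.append(row.rsid)
        betas.append(row_betas[:-1])
        ses.append(row_ses[:-1])
        b_out.append(row_betas[-1])
        s_out.append(row_ses[-1])

    k = len(exposure_sets)
    if len(rsids) <= k:
        raise SummaryDataError(
            f"only {len(rsids)} SNPs survive multivariable harmonisation for "
            f"{k} exposures; need J > K")
    return MVHarmonizedSet(
        exposure_names=[ds.trait_name for ds in exposure_sets],
        outcome_name=outcome.trait_name,
        rsids=rsids, beta_exp=np.array(betas), se_exp=np.array(ses),
        beta_out=np.array(b_out), se_out=np.array(s_out),
        dropped=pd.DataFrame(dropped, columns=["rsid", "reason"]))


def mvmr_ivw(mv: MVHarmonizedSet,
             re_mode: str = "multiplicative_random") -> tuple[list[MREstimate], HetStats]:
    """Multivariable IVW: joint weighted regression on all exposures' betas.

    No-intercept WLS of beta_out on the J x K exposure-beta matrix with
    weights 1/se_out^2; coefficient k is the direct effect of exposure k.
    The first returned estimate (the primary exposure's) is the headline
    direct effect. Residual heterogeneity is measured on J - K degrees of
    freedom; ``multiplicative_random`` inflates all SEs by max(1, sqrt(Q/df)).
    """
    if re_mode not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown re_mode {re_mode!r}")
    j, k = mv.n_snps, mv.n_exposures
    # an exposure with no genetic signal at these SNPs (all betas zero)
    # carries no information: its direct effect is fixed at 0 and it is
    # excluded from the design rather than making the fit singular
    active = np.flatnonzero(np.any(mv.beta_exp != 0, axis=0))
    if active.size == 0:
        raise EstimationError("all exposure betas are zero")
    x = mv.beta_exp[:, active]
    w = 1.0 / mv.se_out**2
    xtwx = x.T @ (w[:, None] * x)
    cond = np.linalg.cond(xtwx)
    if cond > 1e12:
        raise EstimationError(
            f"exposure-beta matrix is numerically rank-deficient "
            f"(condition number {cond:.2e}); direct effects are unidentified")
    coef_active = np.linalg.solve(xtwx, x.T @ (w * mv.beta_out))
    resid = mv.beta_out - x @ coef_active
    q = float(np.sum(w * resid**2))
    df = j - k
    het = _het_stats(q, df)
    ses_active = np.sqrt(np.diag(np.linalg.inv(xtwx)))
    method = "mvmr_ivw_fixed"
    if re_mode == "multiplicative_random":
        ses_active = ses_active * max(1.0, np.sqrt(q / df))
        method = "mvmr_ivw_random"
    coef = np.zeros(k)
    ses = np.full(k, np.inf)
    coef[active] = coef_active
    ses[active] = ses_active
    estimates = [to_or(MREstimate(method=method, beta=float(b), se=float(s), n_snps=j))
                 for b, s in zip(coef, ses)]
    return estimates, het
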