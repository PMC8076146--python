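"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are generated directly at the summary level: per-SNP true
instrument effects gamma_j on the exposure, true outcome effects
Gamma_j = theta * gamma_j + alpha_j (alpha_j a direct, pleiotropic effect for
the invalid fraction of instruments), and observed betas drawn normally
around the truth with the standard errors implied by allele frequency and
GWAS sample size, se = 1/sqrt(2 f (1-f) n). Optionally the exposure and
outcome sampling errors are correlated, standing in for sample overlap
between the two GWAS.

Each simulated SNP is reported on its exposure-increasing allele (gamma_j
>= 0, frequency flipped accordingly), the convention under which a
"directional" pleiotropy mean is well defined; instruments are drawn without
linkage disequilibrium and with non-palindromic alleles by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import CANONICAL_COLUMNS, SummaryDataset

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_N_CHROM = 22
_POS_SPACING = 25_000_000  # keeps simulated loci outside any clump window


@dataclass
class MediatorSpec:
    """A mediator pathway: exposure -> mediator -> outcome.

    ``n_own_snps`` independent SNPs act on the mediator only (variance
    ``own_R2`` in total); without them the mediator's instrument betas are
    proportional to the exposure's and its direct effect is unidentifiable.
    """

    exposure_to_mediator: float
    mediator_to_outcome: float
    n_own_snps: int = 100
    own_R2: float = 0.02
    n_mediator: int = 500_000
    name: str = "mediator"


@dataclass
class SimulationParams:
    """Generating parameters for a two-sample summary-statistic simulation.

    Defaults mirror a large insomnia-style exposure GWAS: 208 independent
    instruments jointly explaining 2.6% of liability variance in 1.33M
    individuals, with a 368k-individual binary-outcome GWAS.
    """

    n_snps: int = 208
    n_exposure: int = 1_331_010
    n_outcome: int = 367_586
    theta: float = 0.0
    gamma_dist: str = "normal"
    target_R2: float = 0.026
    prop_invalid: float = 0.0
    pleiotropy_mode: str = "balanced"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.002
    overlap_corr: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.95)
    mediators: list[MediatorSpec] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimulationParams requires an explicit seed")
        if not 0 <= self.prop_invalid <= 1:
            raise ValueError("prop_invalid must lie in [0, 1]")
        if not 0 < self.target_R2 < 1:
            raise ValueError("target_R2 must lie in (0, 1)")
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise ValueError("sample sizes must be >= 100")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 <= self.overlap_corr <= 1:
            raise ValueError("overlap_corr must lie in [0, 1]")
        if self.gamma_dist not in ("normal", "uniform"):
            raise ValueError(f"unknown gamma_dist {self.gamma_dist!r}")


@dataclass
class SimulationTruth:
    """Ground truth of one simulation, for parameter-recovery testing."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    invalid_mask: np.ndarray
    eaf: np.ndarray
    rsids: list[str]
    mediator_gamma: dict[str, np.ndarray] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"rsid": self.rsids, "gamma": self.gamma, "alpha": self.alpha,
                      "invalid": self.invalid_mask, "eaf": self.eaf}).to_csv(
            path, sep="\t", index=False)


#: named parameter presets
PRESETS: dict[str, dict] = {
    "insomnia-like": dict(n_snps=208, target_R2=0.026,
                          n_exposure=1_331_010, n_outcome=367_586),
    "small-fast": dict(n_snps=50, target_R2=0.02,
                       n_exposure=100_000, n_outcome=50_000),
}


def preset_params(name: str, seed: int, **overrides) -> SimulationParams:
    """Build :class:`SimulationParams` from a named preset plus overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SimulationParams(seed=seed, **kw)


def _draw_gamma(rng: np.random.Generator, n: int, dist: str) -> np.ndarray:
    if dist == "normal":
        return rng.standard_normal(n)
    return rng.uniform(-1.0, 1.0, n)


def _scaled_effects(rng: np.random.Generator, n: int, dist: str,
                    f: np.ndarray, r2: float) -> np.ndarray:
    """Raw effects rescaled so that sum(2 f (1-f) gamma^2) hits ``r2``."""
    g = _draw_gamma(rng, n, dist)
    denom = float(np.sum(2 * f * (1 - f) * g**2))
    if denom <= 0:
        raise ValueError("degenerate effect draw; cannot scale to target variance")
    return g * math.sqrt(r2 / denom)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _dataset(trait: str, rsids, chrom, pos, ea, oa, eaf, beta, se, n) -> SummaryDataset:
    tab = pd.DataFrame({
        "rsid": rsids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": _pvalues(beta, se),
        "n": float(n)}, columns=CANONICAL_COLUMNS)
    return SummaryDataset(trait, "binary", tab, provenance="simulated")


def _snp_annotations(rng: np.random.Generator, n: int, start: int = 0):
    rsids = [f"rs{1000 + i}" for i in range(start, start + n)]
    chrom = [str(1 + (start + i) % _N_CHROM) for i in range(n)]
    pos = [1_000_000 + ((start + i) // _N_CHROM) * _POS_SPACING for i in range(n)]
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), n)]
    ea = [p[0] for p in pairs]
    oa = [p[1] for p in pairs]
    return rsids, chrom, pos, ea, oa


def simulate_two_sample(params: SimulationParams
                        ) -> tuple[SummaryDataset, SummaryDataset, SimulationTruth]:
    """Simulate exposure and outcome GWAS summary statistics.

    Returns (exposure dataset, outcome dataset, ground truth); byte-identical
    for identical parameters and seed.
    """
    rng = np.random.default_rng(params.seed)
    j = params.n_snps
    f = rng.uniform(*params.maf_range, j)
    gamma = _scaled_effects(rng, j, params.gamma_dist, f, params.target_R2)
    # canonicalise to the exposure-increasing allele
    flip = gamma < 0
    gamma = np.abs(gamma)
    f = np.where(flip, 1 - f, f)

    n_invalid = math.ceil(params.prop_invalid * j)
    invalid = np.zeros(j, bool)
    invalid[rng.choice(j, size=n_invalid, replace=False)] = True
    mean = params.alpha_mean if params.pleiotropy_mode == "directional" else 0.0
    alpha = np.where(invalid, rng.normal(mean, params.alpha_sd, j), 0.0)

    se_x = 1.0 / np.sqrt(2 * f * (1 - f) * params.n_exposure)
    se_y = 1.0 / np.sqrt(2 * f * (1 - f) * params.n_outcome)
    z1 = rng.standard_normal(j)
    z2 = rng.standard_normal(j)
    rho = params.overlap_corr
    beta_x = gamma + se_x * z1
    beta_y = params.theta * gamma + alpha + se_y * (rho * z1 + math.sqrt(1 - rho**2) * z2)

    rsids, chrom, pos, ea, oa = _snp_annotations(rng, j)
    exposure = _dataset("exposure", rsids, chrom, pos, ea, oa, f,
                        beta_x, se_x, params.n_exposure)
    outcome = _dataset("outcome", rsids, chrom, pos, ea, oa, f,
                       beta_y, se_y, params.n_outcome)
    truth = SimulationTruth(theta=params.theta, gamma=gamma, alpha=alpha,
                            invalid_mask=invalid, eaf=f, rsids=rsids)
    return exposure, outcome, truth


def simulate_with_mediator(params: SimulationParams
                           ) -> tuple[SummaryDataset, list[SummaryDataset],
                                      SummaryDataset, SimulationTruth]:
    """Simulate exposure, mediator(s) and outcome summary statistics.

    The exposure's instruments act on each mediator with the specified
    pathway effect (delta_j = m_x * gamma_j) and on the outcome both directly
    (``params.theta``, the direct effect) and through each mediator
    (m_x * m_y * gamma_j). Each mediator additionally carries its own
    independent instruments affecting the outcome only through the mediator.

    Returns (exposure, [mediator datasets], outcome, truth); every dataset
    covers the union of all SNPs so any instrument subset can be harmonised.
    """
    if not params.mediators:
        raise ValueError("simulate_with_mediator requires params.mediators")
    rng = np.random.default_rng(params.seed)
    j = params.n_snps
    n_own = [m.n_own_snps for m in params.mediators]
    total = j + sum(n_own)

    f = rng.uniform(*params.maf_range, total)
    gamma = np.zeros(total)
    gamma[:j] = _scaled_effects(rng, j, params.gamma_dist, f[:j], params.target_R2)
    flip = gamma[:j] < 0
    gamma[:j] = np.abs(gamma[:j])
    f[:j] = np.where(flip, 1 - f[:j], f[:j])

    n_invalid = math.ceil(params.prop_invalid * j)
    invalid = np.zeros(total, bool)
    invalid[rng.choice(j, size=n_invalid, replace=False)] = True
    mean = params.alpha_mean if params.pleiotropy_mode == "directional" else 0.0
    alpha = np.where(invalid, rng.normal(mean, params.alpha_sd, total), 0.0)

    # true mediator effects: pathway from the exposure plus own instruments
    med_gamma: dict[str, np.ndarray] = {}
    start = j
    Gamma_out = params.theta * gamma + alpha
    for spec, n_k in zip(params.mediators, n_own):
        delta = spec.exposure_to_mediator * gamma
        block = slice(start, start + n_k)
        eta = _scaled_effects(rng, n_k, params.gamma_dist, f[block], spec.own_R2)
        flip_k = eta < 0
        eta = np.abs(eta)
        f[block] = np.where(flip_k, 1 - f[block], f[block])
        delta[block] = eta
        med_gamma[spec.name] = delta
        Gamma_out = Gamma_out + spec.mediator_to_outcome * delta
        start += n_k

    se_x = 1.0 / np.sqrt(2 * f * (1 - f) * params.n_exposure)
    se_y = 1.0 / np.sqrt(2 * f * (1 - f) * params.n_outcome)
    z1 = rng.standard_normal(total)
    z2 = rng.standard_normal(total)
    rho = params.overlap_corr
    beta_x = gamma + se_x * z1
    beta_y = Gamma_out + se_y * (rho * z1 + math.sqrt(1 - rho**2) * z2)

    rsids, chrom, pos, ea, oa = _snp_annotations(rng, total)
    exposure = _dataset("exposure", rsids, chrom, pos, ea, oa, f,
                        beta_x, se_x, params.n_exposure)
    outcome = _dataset("outcome", rsids, chrom, pos, ea, oa, f,
                       beta_y, se_y, params.n_outcome)
    mediator_sets = []
    for spec in params.mediators:
        se_m = 1.0 / np.sqrt(2 * f * (1 - f) * spec.n_mediator)
        beta_m = med_gamma[spec.name] + se_m * rng.standard_normal(total)
        mediator_sets.append(_dataset(spec.name, rsids, chrom, pos, ea, oa, f,
                                      beta_m, se_m, spec.n_mediator))

    truth = SimulationTruth(theta=params.theta, gamma=gamma, alpha=alpha,
                            invalid_mask=invalid, eaf=f, rsids=rsids,
                            mediator_gamma=med_gamma)
    return exposure, mediator_sets, outcome, truth
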