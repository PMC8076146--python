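"""Study orchestration: one exposure against many outcomes.

For each outcome the pipeline selects instruments (genome-wide filter +
greedy clumping), harmonises, orients, runs the full estimator battery
(random-effects IVW as the headline, weighted median and MR-Egger as
sensitivity analyses, optional multivariable MR per adjustment trait), and
classifies each association against a Bonferroni-corrected threshold into
``significant`` / ``suggestive`` / ``limited`` evidence tiers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import EstimationError, ivw, mr_egger, to_or, weighted_median
from .instruments import LDMatrix, filter_genome_wide, greedy_clump, instrument_strength
from .multivariable import harmonize_multi, mvmr_ivw
from .summary_data import (SummaryDataError, SummaryDataset, harmonize,
                           orient_positive_exposure, read_summary_table)

logger = logging.getLogger(__name__)

FOREST_COLUMNS = ["outcome", "method", "n_snps", "or", "or_low", "or_high",
                  "pvalue", "Q", "I2", "tier"]


class PipelineError(RuntimeError):
    """Raised when the study cannot produce any output."""


@dataclass
class TableSpec:
    """A summary-statistic file plus how to read it."""

    name: str
    path: str
    column_map: dict = field(default_factory=dict)
    trait_type: str = "binary"

    def load(self) -> SummaryDataset:
        return read_summary_table(self.path, column_map=self.column_map or None,
                                  trait_type=self.trait_type, trait_name=self.name)


@dataclass
class StudyConfig:
    """Resolved configuration of a full MR study run."""

    exposure: TableSpec
    outcomes: list[TableSpec]
    ld_matrix: str | None = None
    adjustments: list[TableSpec] = field(default_factory=list)
    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000.0
    alpha: float = 0.05
    n_outcomes_for_bonferroni: int | None = None
    suggestive_level: float = 0.05
    re_mode: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int | None = None
    palindrome_policy: str = "infer_by_frequency"
    ambiguity_band: float = 0.08
    output_dir: str = "mr_output"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_outcomes_for_bonferroni is None:
            self.n_outcomes_for_bonferroni = max(1, len(self.outcomes))
        if self.n_outcomes_for_bonferroni < 1:
            raise ValueError("n_outcomes_for_bonferroni must be >= 1")
        if self.seed is None and self.n_boot > 0:
            raise ValueError("a seed is required when bootstrap SEs are enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        exposure = TableSpec(**raw.pop("exposure"))
        outcomes = [TableSpec(**o) for o in raw.pop("outcomes")]
        adjustments = [TableSpec(**a) for a in raw.pop("adjustments", [])]
        return cls(exposure=exposure, outcomes=outcomes, adjustments=adjustments, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class ForestTable:
    """Per outcome x method study report: OR, CI, p, heterogeneity, tier."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FOREST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"forest table lacks columns {missing}")
        self.table = self.table[FOREST_COLUMNS].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m over m outcomes."""
    if m < 1:
        raise ValueError("number of outcomes must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m

def classify_association(p: float, threshold: float,
                         suggestive_level: float = 0.05) -> str:
    """Evidence tier: ``significant`` below the Bonferroni threshold,
    ``suggestive`` between it and the nominal level, else ``limited``."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < threshold:
        return "significant"
    if p < suggestive_level:
        return "suggestive"
    return "limited"


def select_instruments(exposure: SummaryDataset, ld: LDMatrix | None,
                       p_threshold: float, clump_r2: float,
                       clump_window_kb: float) -> SummaryDataset:
    """Genome-wide filter then greedy clump, logging the counts."""
    sig = filter_genome_wide(exposure, p_threshold)
    logger.info("instruments: %d/%d SNPs at p < %g", len(sig), len(exposure), p_threshold)
    clumped = greedy_clump(sig, ld, r2_max=clump_r2, window_kb=clump_window_kb)
    logger.info("instruments: %d retained after clumping (r2 < %g, %g kb window)",
                len(clumped), clump_r2, clump_window_kb)
    return clumped


def _estimate_one_outcome(instruments: SummaryDataset, outcome: SummaryDataset,
                          config: StudyConfig, threshold: float) -> list[dict]:
    h = harmonize(instruments, outcome,
                  palindrome_policy=config.palindrome_policy,
                  ambiguity_band=config.ambiguity_band)
    h = orient_positive_exposure(h)
    rows = []

    est, het = ivw(h, re_mode=config.re_mode)
    rows.append(_row(outcome.trait_name, "ivw", est, het, threshold, config))

    if len(h) >= 3:
        wm = weighted_median(h, n_boot=config.n_boot, seed=config.seed)
        rows.append(_row(outcome.trait_name, "weighted_median", wm, None, threshold, config))
        egger = mr_egger(h, re_mode=config.re_mode)
        row = _row(outcome.trait_name, "mr_egger", egger.slope, egger.het, threshold, config)
        row["egger_intercept"] = egger.intercept
        row["egger_intercept_p"] = egger.intercept_p
        rows.append(row)
    else:
        logger.warning("%s: only %d harmonised SNPs — skipping weighted median and MR-Egger",
                       outcome.trait_name, len(h))
    return rows


def _row(outcome_name, method, est, het, threshold, config) -> dict:
    return {
        "outcome": outcome_name, "method": method, "n_snps": est.n_snps,
        "or": est.or_, "or_low": est.or_low, "or_high": est.or_high,
        "pvalue": est.pvalue,
        "Q": het.Q if het is not None else float("nan"),
        "I2": het.I2 if het is not None else float("nan"),
        "tier": classify_association(est.pvalue, threshold, config.suggestive_level),
    }


def run_study(config: StudyConfig) -> ForestTable:
    """Run the full study and write all result tables under ``output_dir``.

    Per outcome: instrument selection, harmonisation, orientation, IVW
    (headline) + weighted median + MR-Egger, tier classification; optional
    multivariable MR per adjustment trait (one co-exposure per model).
    Deterministic for a fixed config and seed. Outcomes whose inputs fail are
    logged and skipped; no usable outcome at all is fatal.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    threshold = bonferroni_threshold(config.alpha, config.n_outcomes_for_bonferroni)
    logger.info("run: alpha=%g over %d outcomes -> threshold %.5f (mrkit %s)",
                config.alpha, config.n_outcomes_for_bonferroni, threshold, __version__)

    exposure = config.exposure.load()
    ld = LDMatrix.from_tsv(config.ld_matrix) if config.ld_matrix else None
    instruments = select_instruments(exposure, ld, config.p_threshold,
                                     config.clump_r2, config.clump_window_kb)
    if not len(instruments):
        raise PipelineError("no instruments survive selection")

    rows: list[dict] = []
    mv_rows: list[dict] = []
    failures: list[str] = []
    for spec in config.outcomes:
        try:
            outcome = spec.load()
            out_rows = _estimate_one_outcome(instruments, outcome, config, threshold)
        except (SummaryDataError, EstimationError, OSError) as exc:
            logger.error("outcome %s failed: %s", spec.name, exc)
            failures.append(spec.name)
            continue
        rows.extend(out_rows)

        h = harmonize(instruments, outcome, palindrome_policy=config.palindrome_policy,
                      ambiguity_band=config.ambiguity_band)
        h.to_tsv(out_dir / f"snps_{spec.name}.tsv")
        h.drop_log_to_tsv(out_dir / f"dropped_{spec.name}.tsv")

        strength = instrument_strength(orient_positive_exposure(h),
                                       n_exposure=_exposure_n(exposure))
        logger.info("%s: %d SNPs, mean F=%.1f, score F=%.1f, R2=%.4f",
                    spec.name, len(h), strength.mean_F, strength.score_F,
                    strength.approx_R2)

        for adj in config.adjustments:
            try:
                mv = harmonize_multi([instruments, adj.load()],
                                     outcome, palindrome_policy=config.palindrome_policy,
                                     ambiguity_band=config.ambiguity_band)
                ests, het = mvmr_ivw(mv, re_mode=config.re_mode)
            except (SummaryDataError, EstimationError, OSError) as exc:
                logger.error("MVMR %s | %s failed: %s", spec.name, adj.name, exc)
                continue
            row = _row(spec.name, "mvmr_ivw", ests[0], het, threshold, config)
            row["adjusted_for"] = adj.name
            mv_rows.append(row)

    if not rows:
        raise PipelineError(f"all outcomes failed: {failures}")

    forest = ForestTable(pd.DataFrame(rows))
    forest.to_tsv(out_dir / "forest.tsv")
    if mv_rows:
        pd.DataFrame(mv_rows).to_csv(out_dir / "forest_mvmr.tsv", sep="\t", index=False)
    config.to_yaml(out_dir / "resolved_config.yaml")
    if failures:
        logger.warning("run completed with failed outcomes: %s", failures)
    forest.failures = failures
    return forest


def _exposure_n(exposure: SummaryDataset) -> float:
    n = exposure.table["n"].dropna()
    return float(n.median()) if len(n) else 1e6
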