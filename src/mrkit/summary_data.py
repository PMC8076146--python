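"""Reading, validation and harmonisation of GWAS summary statistics.

Two-sample MR consumes one summary-association table per trait (one row per
SNP: alleles, effect size, standard error, p-value, allele frequency). This
module loads such tables, enforces the row-level invariants, and aligns an
exposure and an outcome dataset to a common effect allele per SNP so that the
ratio ``beta_out / beta_exp`` is meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names understood throughout the package
CANONICAL_COLUMNS = ["rsid", "chrom", "pos", "effect_allele", "other_allele",
                     "eaf", "beta", "se", "pvalue", "n"]

#: default header spellings mapped onto canonical names
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "EA", "other_allele": "OA",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N",
}

_REQUIRED = ["rsid", "effect_allele", "other_allele", "beta", "se", "pvalue"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryDataError(ValueError):
    """Raised for unusable summary-statistic inputs."""


@dataclass
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the additive per-effect-allele effect: log-odds for a binary
    trait, SD units for a continuous one.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if not self.se > 0:
            raise SummaryDataError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(f"{self.rsid}: effect and other allele are identical")
        if not (0 < self.pvalue <= 1):
            raise SummaryDataError(f"{self.rsid}: pvalue must lie in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not np.isnan(self.eaf) and not (0 < self.eaf < 1):
            raise SummaryDataError(f"{self.rsid}: eaf must lie in (0, 1), got {self.eaf}")


@dataclass
class SummaryDataset:
    """An ordered set of variant associations for a single trait.

    ``table`` holds one row per SNP with the canonical columns; rsids are
    unique within a dataset.
    """

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    table: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise SummaryDataError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SummaryDataError(f"table lacks canonical columns: {missing}")
        if self.table["rsid"].duplicated().any():
            dups = self.table.loc[self.table["rsid"].duplicated(), "rsid"].tolist()
            raise SummaryDataError(f"duplicate rsids in {self.trait_name}: {dups[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> list[VariantAssociation]:
        out = []
        for row in self.table.itertuples(index=False):
            out.append(VariantAssociation(
                rsid=row.rsid, effect_allele=row.effect_allele,
                other_allele=row.other_allele, beta=row.beta, se=row.se,
                pvalue=row.pvalue,
                chrom=None if pd.isna(row.chrom) else row.chrom,
                pos=None if pd.isna(row.pos) else int(row.pos),
                eaf=None if pd.isna(row.eaf) else row.eaf,
                n=None if pd.isna(row.n) else row.n))
        return out

    @classmethod
    def from_records(cls, trait_name: str, trait_type: str,
                     records: list[VariantAssociation], provenance: str = "") -> "SummaryDataset":
        table = pd.DataFrame(
            [{"rsid": r.rsid, "chrom": r.chrom, "pos": r.pos,
              "effect_allele": r.effect_allele, "other_allele": r.other_allele,
              "eaf": r.eaf, "beta": r.beta, "se": r.se,
              "pvalue": r.pvalue, "n": r.n} for r in records],
            columns=CANONICAL_COLUMNS)
        return cls(trait_name, trait_type, table, provenance)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure/outcome betas aligned to a common effect allele per SNP.

    ``snps`` columns: rsid, beta_exp, se_exp, beta_out, se_out, eaf_exp.
    ``dropped`` logs every rsid removed during harmonisation with its reason
    (missing-in-outcome, palindromic-ambiguous, allele-mismatch, ...).
    """

    exposure_name: str
    outcome_name: str
    snps: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"]))

    def __post_init__(self) -> None:
        need = ["rsid", "beta_exp", "se_exp", "beta_out", "se_out"]
        missing = [c for c in need if c not in self.snps.columns]
        if missing:
            raise SummaryDataError(f"harmonised table lacks columns {missing}")
        if "eaf_exp" not in self.snps.columns:
            self.snps = self.snps.assign(eaf_exp=np.nan)
        if len(self.snps):
            if not (self.snps["se_exp"] > 0).all() or not (self.snps["se_out"] > 0).all():
                raise SummaryDataError("harmonised records require positive standard errors")
            if self.snps["rsid"].duplicated().any():
                raise SummaryDataError("duplicate rsids in harmonised set")
        self.snps = self.snps.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.snps)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        s = self.snps
        return (s["beta_exp"].to_numpy(float), s["se_exp"].to_numpy(float),
                s["beta_out"].to_numpy(float), s["se_out"].to_numpy(float))

    def to_tsv(self, path: str | Path) -> None:
        self.snps[["rsid", "beta_exp", "se_exp", "beta_out", "se_out"]].to_csv(
            path, sep="\t", index=False)

    def drop_log_to_tsv(self, path: str | Path) -> None:
        self.dropped.to_csv(path, sep="\t", index=False)


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_summary_table(path: str | Path,
                       column_map: Mapping[str, str] | None = None,
                       trait_type: str = "binary",
                       trait_name: str | None = None) -> SummaryDataset:
    """Read a delimited summary-statistic table into a :class:`SummaryDataset`.

    ``column_map`` maps canonical field names (``rsid``, ``beta``, ...) to the
    column names actually present in the header; unmapped optional fields
    (``chrom``, ``pos``, ``eaf``, ``n``) are filled with NA. Rows violating a
    row-level invariant (non-positive SE, identical alleles, p outside (0,1],
    eaf outside (0,1)) are skipped and counted; more than 50% invalid rows is
    treated as a malformed file.
    """
    path = Path(path)
    if not path.is_file():
        raise SummaryDataError(f"cannot read summary-statistic file {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    with open(path) as fh:
        header = fh.readline()
    sep = _detect_delimiter(header)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]

    # accept the mapped header name, falling back to the canonical name
    # itself so simulator/round-trip TSVs read without a column map
    present = {canon: col for canon, col in cmap.items() if col in raw.columns}
    for canon in CANONICAL_COLUMNS:
        if canon not in present and canon in raw.columns:
            present[canon] = canon
    absent_required = [c for c in _REQUIRED if c not in present]
    if absent_required:
        raise SummaryDataError(
            f"{path}: mapped column(s) missing from header: "
            f"{[cmap[c] for c in absent_required]} (header has {list(raw.columns)})")

    df = pd.DataFrame({canon: raw[col] for canon, col in present.items()})
    for canon in CANONICAL_COLUMNS:
        if canon not in df.columns:
            df[canon] = np.nan
    for col in ("eaf", "beta", "se", "pvalue", "n", "pos"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.strip().str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.strip().str.upper()
    df["rsid"] = df["rsid"].astype(str).str.strip()
    chrom = df["chrom"].astype(str).str.strip()
    df["chrom"] = chrom.where(chrom != "nan")

    ok = (
        df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
        & df["pvalue"].notna() & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        & (df["effect_allele"] != df["other_allele"])
        & (df["effect_allele"].str.fullmatch(r"[ACGT]+") | False).fillna(False)
        & (df["other_allele"].str.fullmatch(r"[ACGT]+") | False).fillna(False)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: skipped %d/%d invalid rows", path.name, n_bad, len(df))
    if len(df) and n_bad > 0.5 * len(df):
        raise SummaryDataError(
            f"{path}: {n_bad}/{len(df)} rows failed validation — wrong column mapping?")
    df = df.loc[ok, CANONICAL_COLUMNS]
    df = df.drop_duplicates(subset="rsid", keep="first")
    return SummaryDataset(trait_name or path.stem, trait_type, df, provenance=str(path))


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T or C/G SNPs cannot be strand-resolved from allele labels alone."""
    return (len(a1) == 1 and len(a2) == 1
            and _COMPLEMENT.get(a1.upper()) == a2.upper())


def harmonize(exposure: SummaryDataset, outcome: SummaryDataset,
              palindrome_policy: str = "infer_by_frequency",
              ambiguity_band: float = 0.08) -> HarmonizedSet:
    """Align outcome associations to the exposure's effect allele per SNP.

    Matching is by rsID. For each shared SNP:

    * outcome alleles identical to the exposure's — kept as-is;
    * outcome alleles swapped — ``beta_out`` negated, ``eaf_out`` reflected;
    * palindromic pair (A/T or C/G) — dropped under ``drop_all``; under
      ``infer_by_frequency`` the allele frequencies on both sides orient the
      SNP, and it is dropped when either frequency falls inside
      ``0.5 ± ambiguity_band``;
    * anything else — dropped as an allele mismatch.

    Every removal is logged in ``dropped`` with its reason.
    """
    if palindrome_policy not in ("infer_by_frequency", "drop_all"):
        raise SummaryDataError(f"unknown palindrome_policy {palindrome_policy!r}")
    if not len(exposure) or not len(outcome):
        raise SummaryDataError("harmonize requires non-empty exposure and outcome datasets")

    exp = exposure.table.set_index("rsid")
    out = outcome.table.set_index("rsid")

    kept_rows: list[dict] = []
    dropped_rows: list[dict] = []

    for rsid in exposure.table["rsid"]:
        if rsid not in out.index:
            dropped_rows.append({"rsid": rsid, "reason": "missing-in-outcome"})
            continue
        e, o = exp.loc[rsid], out.loc[rsid]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        beta_out, eaf_out = float(o["beta"]), o["eaf"]

        if (ea_o, oa_o) == (ea_e, oa_e):
            sign = 1.0
        elif (ea_o, oa_o) == (oa_e, ea_e):
            sign = -1.0
            eaf_out = np.nan if pd.isna(eaf_out) else 1.0 - float(eaf_out)
        else:
            dropped_rows.append({"rsid": rsid, "reason": "allele-mismatch"})
            continue

        if is_palindromic(ea_e, oa_e):
            if palindrome_policy == "drop_all":
                dropped_rows.append({"rsid": rsid, "reason": "palindromic-dropped"})
                continue
            eaf_exp = e["eaf"]
            lo, hi = 0.5 - ambiguity_band, 0.5 + ambiguity_band
            if (pd.isna(eaf_exp) or pd.isna(eaf_out)
                    or lo <= float(eaf_exp) <= hi or lo <= float(eaf_out) <= hi):
                dropped_rows.append({"rsid": rsid, "reason": "palindromic-ambiguous"})
                continue
            # discordant frequencies imply the outcome reported the opposite
            # strand: the label-based orientation must be reversed
            if (float(eaf_exp) > 0.5) != (float(eaf_out) > 0.5):
                sign = -sign

        kept_rows.append({
            "rsid": rsid,
            "beta_exp": float(e["beta"]), "se_exp": float(e["se"]),
            "beta_out": sign * beta_out, "se_out": float(o["se"]),
            "eaf_exp": np.nan if pd.isna(e["eaf"]) else float(e["eaf"]),
        })

    if not kept_rows:
        counts = pd.Series([d["reason"] for d in dropped_rows]).value_counts().to_dict()
        raise SummaryDataError(
            f"no SNPs survive harmonisation of {exposure.trait_name} vs "
            f"{outcome.trait_name}; drop reasons: {counts}")

    snps = pd.DataFrame(kept_rows)
    dropped = pd.DataFrame(dropped_rows, columns=["rsid", "reason"])
    return HarmonizedSet(exposure.trait_name, outcome.trait_name, snps, dropped)


def orient_positive_exposure(h: HarmonizedSet) -> HarmonizedSet:
    """Flip SNPs so every exposure beta is non-negative.

    MR-Egger's intercept is only identified once all instruments are coded on
    the exposure-increasing allele; joint negation of (beta_exp, beta_out)
    leaves every Wald ratio unchanged. Idempotent.
    """
    if not len(h):
        raise SummaryDataError("cannot orient an empty harmonised set")
    snps = h.snps.copy()
    flip = snps["beta_exp"] < 0
    snps.loc[flip, "beta_exp"] *= -1.0
    snps.loc[flip, "beta_out"] *= -1.0
    snps.loc[flip, "eaf_exp"] = 1.0 - snps.loc[flip, "eaf_exp"]
    return HarmonizedSet(h.exposure_name, h.outcome_name, snps, h.dropped)
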