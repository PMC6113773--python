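"""GWAS summary-statistics data model, I/O and allele harmonisation.

The unit of exchange is :class:`SummaryStatsTable`, a validated per-SNP
association table for one trait (one stage of one GWAS).  Two tables for an
exposure and an outcome are merged into a :class:`HarmonizedInstrumentSet`
by :func:`harmonize`, which puts both effects on a shared effect-allele
convention — the input two-sample Mendelian randomisation expects.

File format: tab-delimited text with header columns
``SNP CHR POS EA OA EAF BETA SE P N`` (plus optional ``N_STUDIES``);
gzip is handled transparently by extension.  ``column_map`` allows renames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from osteomr.errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: canonical internal column order
COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: default file header -> internal name
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pvalue",
    "N": "n",
    "N_STUDIES": "n_studies",
}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: strand-ambiguous allele pairs
_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SummaryStatsTable:
    """Per-SNP association records for one trait/stage.

    Parameters
    ----------
    trait_name : str
        Label for the trait (e.g. ``"fracture"``).
    trait_type : {"binary", "quantitative"}
        Binary traits carry log-odds betas; quantitative traits carry
        effects in trait SD or natural units.
    df : pandas.DataFrame
        One row per SNP with the canonical columns (see ``COLUMNS``),
        optionally ``n_studies``.
    genomic_lambda : float, optional
        Genomic-control inflation factor; populated by
        :func:`osteomr.meta.genomic_control`.
    """

    trait_name: str
    trait_type: str
    df: pd.DataFrame
    genomic_lambda: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise InputError(f"unknown trait_type {self.trait_type!r}")
        if self.genomic_lambda is not None and self.genomic_lambda < 0:
            raise InputError("genomic_lambda must be non-negative")
        if self.df["snp_id"].duplicated().any():
            dups = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].tolist()
            raise InputError(f"duplicate snp_id in table: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome effect pairs on a shared effect-allele convention.

    ``df`` has columns ``snp_id, bx, se_bx, by, se_by`` where ``bx`` is the
    per-allele effect on the exposure and ``by`` the effect on the outcome,
    both for the same effect allele.  ``exclusions`` maps a reason
    (``"palindromic"``, ``"allele_mismatch"``) to the SNPs dropped for it.
    """

    exposure_name: str
    outcome_name: str
    exposure_type: str
    df: pd.DataFrame
    exclusions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.df[["se_bx", "se_by"]] <= 0).any().any():
            raise InputError("harmonised standard errors must be positive")
        if self.df["snp_id"].duplicated().any():
            raise InputError("duplicate snp_id in harmonised set")

    def __len__(self) -> int:
        return len(self.df)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (bx, se_bx, by, se_by) as float arrays."""
        return (
            self.df["bx"].to_numpy(float),
            self.df["se_bx"].to_numpy(float),
            self.df["by"].to_numpy(float),
            self.df["se_by"].to_numpy(float),
        )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating per-SNP invariants; return survivors and counts."""
    drops: dict[str, int] = {}

    def gate(mask: pd.Series, reason: str) -> pd.Series:
        n_bad = int((~mask).sum())
        if n_bad:
            drops[reason] = drops.get(reason, 0) + n_bad
        return mask

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    keep = gate(df["effect_allele"].isin(_VALID_ALLELES)
                & df["other_allele"].isin(_VALID_ALLELES), "non_biallelic_snp")
    keep &= gate(df["effect_allele"] != df["other_allele"], "identical_alleles")
    keep &= gate(df["se"] > 0, "nonpositive_se")
    keep &= gate(df["eaf"].between(0.0, 1.0), "eaf_out_of_range")
    keep &= gate((df["pvalue"] > 0) & (df["pvalue"] <= 1), "pvalue_out_of_range")
    keep &= gate(df[["beta", "se", "eaf", "pvalue"]].notna().all(axis=1), "missing_value")
    return df.loc[keep].reset_index(drop=True), drops


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: str = "binary",
) -> SummaryStatsTable:
    """Read and validate a tab-delimited summary-statistics file.

    Rows violating the per-SNP invariants (non-ACGT or identical alleles,
    se <= 0, EAF outside [0,1], p outside (0,1]) are dropped and the drop
    counts logged.  Indels and multi-allelic records are rejected the same
    way: only single-base A/C/G/T biallelic SNPs survive.

    Raises
    ------
    ConfigurationError
        If a mandatory column is missing after applying ``column_map``.
    InputError
        If the file has no data rows.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype={"CHR": str},
                      float_precision="round_trip")
    if raw.empty:
        raise InputError(f"no data rows in {path}")
    renamed = raw.rename(columns=cmap)
    missing = [c for c in COLUMNS if c not in renamed.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s) {missing} in {path}")
    cols = COLUMNS + (["n_studies"] if "n_studies" in renamed.columns else [])
    df = renamed[cols].copy()
    df["chrom"] = df["chrom"].astype(str)
    df, drops = _validate_rows(df)
    if drops:
        logger.info("read_sumstats(%s): dropped rows %s", path, drops)
    return SummaryStatsTable(trait_name=trait_name, trait_type=trait_type, df=df)


def write_sumstats(table: SummaryStatsTable, path) -> None:
    """Write a table in the canonical tab-delimited format.

    Floats are written with 17 significant digits so that a write/read
    round trip reproduces every value bit-for-bit.
    """
    inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    out = table.df.rename(columns=inv)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def is_palindromic(ea: str, oa: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) allele pairs."""
    return (ea, oa) in _PALINDROMES


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedInstrumentSet:
    """Merge exposure and outcome tables onto the exposure's effect alleles.

    SNPs are matched by rsID.  When the outcome's effect allele equals the
    exposure's other allele (directly or after strand complementing) the
    outcome beta is sign-flipped and its EAF complemented.  Strand-ambiguous
    (A/T, C/G) SNPs whose EAF lies within ``palindrome_eaf_window`` of 0.5
    in either table are excluded as unresolvable; ambiguous SNPs outside
    the window are oriented by EAF concordance.  Allele pairs that cannot
    be reconciled even after complementing are excluded.

    Raises
    ------
    InputError
        If the two tables share no SNPs.
    """
    merged = exposure.df.merge(
        outcome.df, on="snp_id", suffixes=("_x", "_y"), how="inner"
    )
    if merged.empty:
        raise InputError("exposure and outcome tables share no SNPs")

    rows = []
    excl: dict[str, list[str]] = {"palindromic": [], "allele_mismatch": []}
    for rec in merged.itertuples(index=False):
        ea_x, oa_x = rec.effect_allele_x, rec.other_allele_x
        ea_y, oa_y = rec.effect_allele_y, rec.other_allele_y
        by, eaf_y = rec.beta_y, rec.eaf_y

        if is_palindromic(ea_x, oa_x):
            near_half = (
                abs(rec.eaf_x - 0.5) < palindrome_eaf_window
                or abs(eaf_y - 0.5) < palindrome_eaf_window
            )
            if near_half:
                excl["palindromic"].append(rec.snp_id)
                continue
            # complementing maps the pair onto itself; orient by EAF side
            if (rec.eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                by, eaf_y = -by, 1.0 - eaf_y
        else:
            pair = (ea_y, oa_y)
            comp = (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y])
            if pair == (ea_x, oa_x) or comp == (ea_x, oa_x):
                pass
            elif pair == (oa_x, ea_x) or comp == (oa_x, ea_x):
                by, eaf_y = -by, 1.0 - eaf_y
            else:
                excl["allele_mismatch"].append(rec.snp_id)
                continue

        rows.append((rec.snp_id, rec.beta_x, rec.se_x, by, rec.se_y))

    for reason, snps in excl.items():
        if snps:
            logger.info("harmonize: excluded %d SNP(s) as %s: %s",
                        len(snps), reason, snps[:10])
    df = pd.DataFrame(rows, columns=["snp_id", "bx", "se_bx", "by", "se_by"])
    return HarmonizedInstrumentSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        exposure_type=exposure.trait_type,
        df=df,
        exclusions={k: v for k, v in excl.items() if v},
    )
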