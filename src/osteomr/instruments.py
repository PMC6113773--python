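"""Instrument selection for Mendelian randomisation.

Significance and minor-allele-frequency gates, greedy LD clumping that
keeps the lowest-p SNP per correlated group, and the per-doubling-of-odds
rescaling applied to causal estimates when the exposure is itself a
binary disease trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from osteomr.errors import ConfigurationError, ContractViolation, InputError
from osteomr.meta import Z95
from osteomr.sumstats import SummaryStatsTable

#: log-odds multiplier converting a per-unit-liability effect of a binary
#: exposure to an effect per doubling of the odds of the exposure disease;
#: applied exactly as conventionally printed (0.693, not ln 2)
PER_DOUBLING_FACTOR = 0.693


@dataclass
class LDMatrix:
    """Square matrix of squared correlations (r2) over an ordered SNP set."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.r2, dtype=float)
        if m.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise InputError("r2 matrix shape does not match snp_ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise InputError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise InputError("r2 matrix diagonal must be 1")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise InputError("r2 entries must lie in [0, 1]")
        self.r2 = m
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def read(cls, path) -> "LDMatrix":
        """Read a square tab-delimited matrix with snp_id header row/column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=[str(s) for s in df.index], r2=df.to_numpy(float))

    def write(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )


def select_instruments(
    table: SummaryStatsTable,
    p_threshold: float = 5e-8,
    maf_threshold: float = 0.05,
) -> SummaryStatsTable:
    """Keep common variants strongly associated with the exposure.

    Gates: ``p < p_threshold`` and minor allele frequency
    ``min(eaf, 1 - eaf) > maf_threshold``.  An empty survivor set is a
    warning, not an error.
    """
    df = table.df
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    keep = (df["pvalue"] < p_threshold) & (maf > maf_threshold)
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        import logging

        logging.getLogger(__name__).warning(
            "select_instruments: no SNPs pass p<%g and MAF>%g",
            p_threshold,
            maf_threshold,
        )
    return SummaryStatsTable(
        trait_name=table.trait_name,
        trait_type=table.trait_type,
        df=out,
        genomic_lambda=table.genomic_lambda,
    )


def greedy_clump(
    table: SummaryStatsTable, ld: LDMatrix, r2_threshold: float = 0.05
) -> SummaryStatsTable:
    """Greedy LD clumping: keep the lowest-p SNP per correlated group.

    SNPs are visited in ascending p (ties broken lexicographically by
    rsID); a SNP is kept iff its r2 with every already-kept SNP is at or
    below ``r2_threshold``.  The result is ordered by p.

    Raises
    ------
    ConfigurationError
        If a table SNP is absent from the LD matrix (named in the message).
    """
    missing = [s for s in table.df["snp_id"] if s not in ld._index]
    if missing:
        raise ConfigurationError(f"SNP(s) missing from LD matrix: {missing[:10]}")
    order = table.df.sort_values(
        ["pvalue", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    kept_idx: list[int] = []
    kept_ld: list[int] = []
    for i, rec in order.iterrows():
        j = ld._index[rec["snp_id"]]
        if all(ld.r2[j, k] <= r2_threshold for k in kept_ld):
            kept_idx.append(i)
            kept_ld.append(j)
    out = order.loc[kept_idx].reset_index(drop=True)
    return SummaryStatsTable(
        trait_name=table.trait_name,
        trait_type=table.trait_type,
        df=out,
        genomic_lambda=table.genomic_lambda,
    )


def rescale_binary_exposure(estimate):
    """Re-express a causal estimate per doubling of the odds of the exposure.

    Multiplies the causal log-effect, its standard error and CI bounds by
    0.693 (log-odds scale) before exponentiation; the z-statistic, and
    hence the p-value, is unchanged.

    Raises
    ------
    ContractViolation
        If the estimate's exposure is not binary.
    """
    if estimate.exposure_type != "binary":
        raise ContractViolation(
            "rescale_binary_exposure requires a binary exposure"
        )
    beta = estimate.beta * PER_DOUBLING_FACTOR
    se = estimate.se * PER_DOUBLING_FACTOR
    return replace(
        estimate,
        beta=beta,
        se=se,
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
    )
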