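"""Genomic control and fixed-effects inverse-variance meta-analysis.

Implements the discovery -> replication -> combined chain of a multi-stage
case-control GWAS: per-study genomic-control correction of test statistics,
precision-weighted pooling of log-odds ratios across stages or cohorts with
Cochran's Q / I-squared heterogeneity, and the genome-wide-significance
filter applied to the pooled results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from osteomr.errors import InputError
from osteomr.sumstats import SummaryStatsTable

logger = logging.getLogger(__name__)

#: standard-normal quantile at 0.975, fixed at this precision for
#: reproducible confidence intervals
Z95 = 1.959964

#: median of the chi-square(1) distribution (the genomic-control null
#: denominator, quoted as 0.455 at reporting precision)
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class StageEstimate:
    """One stage's (or cohort's) log-odds estimate for a single SNP."""

    label: str
    beta: float
    se: float
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise InputError(f"stage {self.label!r}: se must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate for one SNP across stages/cohorts.

    ``ci_low``/``ci_high`` are 95% bounds on the odds-ratio scale;
    ``i2`` is the heterogeneity percentage in [0, 100].
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    q_stat: float
    i2: float
    k: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


def se_from_ci(
    or_point: float, ci_low: float, ci_high: float, level: float = 0.95
) -> float:
    """Recover the log-odds standard error from a printed OR and CI.

    ``se = (ln(ci_high) - ln(ci_low)) / (2 z)`` with ``z`` the
    standard-normal quantile at ``(1 + level) / 2``.  Used to consume
    published tables that print only ``OR (95% CI)`` cells.

    Raises
    ------
    InputError
        If ``0 < ci_low <= or_point <= ci_high`` does not hold.
    """
    if not (0 < ci_low <= or_point <= ci_high):
        raise InputError(
            f"CI ordering violated: need 0 < {ci_low} <= {or_point} <= {ci_high}"
        )
    if not 0 < level < 1:
        raise InputError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    return (math.log(ci_high) - math.log(ci_low)) / (2 * z)


def se_from_ci_robust(
    or_point: float, ci_low: float, ci_high: float, level: float = 0.95
) -> float:
    """Like :func:`se_from_ci` but tolerant of inconsistent printed cells.

    Published tables occasionally carry typographic cells whose CI does not
    bracket the point estimate, or collapses to zero width at the printed
    precision.  This variant takes the larger one-sided half-width around
    the point estimate on the log scale, which is exact for a well-formed
    symmetric interval and a conservative (never smaller) reconstruction
    otherwise.
    """
    if min(or_point, ci_low, ci_high) <= 0:
        raise InputError("odds ratios must be positive")
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = math.log(ci_low), math.log(ci_high)
    mid = math.log(or_point)
    half = max(abs(hi - mid), abs(mid - lo), (hi - lo) / 2)
    se = half / z
    if se == 0:
        raise InputError("degenerate interval: cannot recover a positive se")
    return se


def genomic_control(table: SummaryStatsTable) -> SummaryStatsTable:
    """Apply genomic-control correction to one study's summary statistics.

    The inflation factor is ``lambda = median(chi2) / 0.455`` with
    ``chi2 = (beta/se)^2``.  When ``lambda > 1`` every standard error is
    multiplied by ``sqrt(lambda)`` and p-values are recomputed from the
    deflated z-scores; ``lambda <= 1`` leaves the table unchanged apart
    from recording lambda.  Correction is per input study, before pooling.
    """
    df = table.df.copy()
    if len(df) < 100:
        logger.warning(
            "genomic_control: only %d SNPs; lambda estimate will be noisy", len(df)
        )
    chi2 = (df["beta"].to_numpy() / df["se"].to_numpy()) ** 2
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    if lam > 1:
        df["se"] = df["se"] * math.sqrt(lam)
        z = df["beta"].to_numpy() / df["se"].to_numpy()
        df["pvalue"] = 2 * stats.norm.sf(np.abs(z))
    return SummaryStatsTable(
        trait_name=table.trait_name,
        trait_type=table.trait_type,
        df=df,
        genomic_lambda=lam,
    )


def fixed_effects_meta(estimates: Sequence[StageEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects pooling of per-stage estimates.

    beta = sum(b_i / se_i^2) / sum(1 / se_i^2);  se = 1 / sqrt(sum(1/se_i^2));
    Q = sum w_i (b_i - beta)^2;  I2 = max(0, (Q - (k-1)) / Q) * 100.
    """
    if len(estimates) == 0:
        raise InputError("fixed_effects_meta requires at least one estimate")
    b = np.array([e.beta for e in estimates], dtype=float)
    w = np.array([1.0 / e.se**2 for e in estimates], dtype=float)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = beta / se
    pvalue = float(2 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (b - beta) ** 2))
    k = len(estimates)
    i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0
    return MetaResult(
        beta=beta,
        se=se,
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        pvalue=pvalue,
        q_stat=q,
        i2=i2,
        k=k,
    )


def gws_filter(
    meta: Iterable[tuple[str, MetaResult, int, float]],
    p_threshold: float = 5e-8,
    min_studies: int = 2,
    maf_threshold: float = 0.01,
) -> list[str]:
    """Genome-wide-significance filter on pooled results.

    Keeps SNPs with ``p < p_threshold``, present in strictly more than
    ``min_studies`` studies, and minor allele frequency >= ``maf_threshold``;
    input order is preserved.
    """
    survivors = []
    for snp_id, result, n_studies, maf in meta:
        if result.pvalue < p_threshold and n_studies > min_studies and maf >= maf_threshold:
            survivors.append(snp_id)
    return survivors


def meta_analyse_tables(
    tables: Sequence[SummaryStatsTable],
    apply_gc: bool = True,
    trait_name: str | None = None,
) -> SummaryStatsTable:
    """Pool several studies' summary statistics SNP-by-SNP.

    Each study is genomic-control corrected first (when ``apply_gc``), then
    every SNP present in at least one study is pooled with
    :func:`fixed_effects_meta` over the studies carrying it.  Allele
    conventions are assumed pre-aligned (the generator and file formats
    guarantee this); ``n`` is summed, ``n_studies`` counts contributors.
    """
    if not tables:
        raise InputError("no tables to meta-analyse")
    if apply_gc:
        tables = [genomic_control(t) for t in tables]
    meta_rows = []
    frames = [t.df.set_index("snp_id") for t in tables]
    all_snps: list[str] = []
    seen = set()
    for t in tables:
        for s in t.df["snp_id"]:
            if s not in seen:
                seen.add(s)
                all_snps.append(s)
    for snp in all_snps:
        ests, rows = [], []
        for i, f in enumerate(frames):
            if snp in f.index:
                r = f.loc[snp]
                ests.append(StageEstimate(label=tables[i].trait_name,
                                          beta=float(r["beta"]), se=float(r["se"])))
                rows.append(r)
        res = fixed_effects_meta(ests)
        first = rows[0]
        meta_rows.append(
            {
                "snp_id": snp,
                "chrom": first["chrom"],
                "pos": first["pos"],
                "effect_allele": first["effect_allele"],
                "other_allele": first["other_allele"],
                "eaf": float(np.mean([float(r["eaf"]) for r in rows])),
                "beta": res.beta,
                "se": res.se,
                "pvalue": res.pvalue,
                "n": int(sum(float(r["n"]) for r in rows)),
                "n_studies": len(rows),
                "q_stat": res.q_stat,
                "i2": res.i2,
            }
        )
    import pandas as pd

    df = pd.DataFrame(meta_rows)
    return SummaryStatsTable(
        trait_name=trait_name or tables[0].trait_name,
        trait_type=tables[0].trait_type,
        df=df,
    )
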