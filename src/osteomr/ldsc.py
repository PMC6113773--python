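"""LD score regression for heritability and genetic correlation.

Under a polygenic model the expected association chi-square of SNP j grows
linearly in its LD score ``l_j`` (the sum of its r2 with all SNPs):
``E[chi2_j] = 1 + N h2 l_j / M``.  Regressing chi-square on LD score
therefore separates polygenic signal (slope) from confounding such as
population stratification (intercept).  The cross-trait analogue regresses
``z1_j * z2_j`` on ``l_j``: its slope scales to the genetic covariance and
its intercept absorbs correlation induced by overlapping samples.

Weights are ``1/l_j`` as a single-step heteroskedasticity proxy — a
documented simplification of the original method's iterative weighting.
Standard errors come from a delete-one block jackknife over contiguous
SNP blocks (20 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from osteomr.errors import InputError
from osteomr.instruments import LDMatrix

logger = logging.getLogger(__name__)


@dataclass
class LDScores:
    """Per-SNP LD scores and the polygenicity denominator M."""

    snp_ids: list[str]
    ell: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.ell = np.asarray(self.ell, dtype=float)
        if len(self.ell) != len(self.snp_ids):
            raise InputError("ell length does not match snp_ids")
        if self.m < len(self.snp_ids):
            raise InputError("M must be at least the number of scored SNPs")
        if np.any(self.ell < 1 - 1e-9):
            raise InputError("LD scores including self-r2 must be >= 1")


@dataclass
class LdscFit:
    """Result of one LD score regression.

    ``estimate`` is h2 for a single-trait fit and the genetic covariance
    for a cross-trait fit; ``rg`` (with jackknife ``rg_se``) is populated
    only for cross-trait fits.  ``rg_raw`` preserves the pre-clamping
    value when |rg| exceeded 1.  ``reason`` is set when rg is undefined
    (non-positive heritability in either trait).
    """

    kind: str
    estimate: float
    se: float
    intercept: float
    intercept_se: float
    n_blocks: int
    rg: float | None = None
    rg_se: float | None = None
    rg_raw: float | None = None
    pvalue: float | None = None
    significant_after_bonferroni: bool | None = None
    reason: str | None = None


def ld_scores(ld: LDMatrix, m: int | None = None) -> LDScores:
    """LD scores as row sums of the r2 matrix, including the diagonal."""
    ell = ld.r2.sum(axis=1)
    return LDScores(snp_ids=list(ld.snp_ids), ell=ell,
                    m=m if m is not None else len(ld.snp_ids))


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = np.sqrt(w)
    X = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(X, sw * y, rcond=None)
    return float(coef[0]), float(coef[1])


def _block_bounds(n_snps: int, n_blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n_snps, n_blocks + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _jackknife(values: np.ndarray) -> float:
    """Delete-one jackknife standard error from per-block pseudo-estimates."""
    b = len(values)
    mean = values.mean()
    return float(math.sqrt((b - 1) / b * np.sum((values - mean) ** 2)))


def h2_regression(
    z: np.ndarray, n: float, scores: LDScores, n_blocks: int = 20
) -> LdscFit:
    """Single-trait LD score regression.

    Regresses ``chi2_j = z_j^2`` on ``l_j`` with weights ``1/l_j``;
    ``h2 = slope * M / N``.  The intercept is ~1 in a well-calibrated
    GWAS and inflates under stratification.  Jackknife standard errors
    over ``n_blocks`` contiguous SNP blocks.
    """
    z = np.asarray(z, dtype=float)
    if len(z) != len(scores.ell):
        raise InputError("z and LD scores are not aligned")
    if n_blocks < 2:
        raise InputError("n_blocks must be >= 2")
    if len(z) < n_blocks:
        raise InputError("fewer SNPs than jackknife blocks")
    chi2 = z**2
    ell = scores.ell
    w = 1.0 / ell

    def fit(mask: np.ndarray) -> tuple[float, float]:
        icpt, slope = _wls_line(ell[mask], chi2[mask], w[mask])
        return icpt, slope * scores.m / n

    full_mask = np.ones(len(z), dtype=bool)
    icpt, h2 = fit(full_mask)
    blocks = _block_bounds(len(z), n_blocks)
    loo = np.array([
        fit(np.r_[np.ones(a, bool), np.zeros(b - a, bool), np.ones(len(z) - b, bool)])
        for a, b in blocks
    ])
    return LdscFit(
        kind="h2",
        estimate=h2,
        se=_jackknife(loo[:, 1]),
        intercept=icpt,
        intercept_se=_jackknife(loo[:, 0]),
        n_blocks=n_blocks,
    )


def rg_regression(
    z1: np.ndarray,
    z2: np.ndarray,
    n1: float,
    n2: float,
    scores: LDScores,
    n_blocks: int = 20,
    n_shared: float = 0,
    n_tests: int = 12,
) -> LdscFit:
    """Cross-trait LD score regression for genetic correlation.

    Regresses ``z1_j z2_j`` on ``l_j`` (weights ``1/l_j``); the genetic
    covariance is ``slope * M / sqrt(N1 N2)`` and
    ``rg = cov / sqrt(h1^2 h2^2)`` with the heritabilities from
    single-trait fits on the same SNPs.  The intercept absorbs the
    correlation induced by ``n_shared`` overlapping samples, so overlap
    inflates the intercept, not rg.  The whole ratio is jackknifed over
    contiguous blocks; rg outside [-1, 1] is clamped with a warning.
    A Bonferroni flag at ``0.05 / n_tests`` is attached.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if not (len(z1) == len(z2) == len(scores.ell)):
        raise InputError("z-scores and LD scores are not aligned")
    if len(z1) < n_blocks:
        raise InputError("fewer SNPs than jackknife blocks")
    ell = scores.ell
    w = 1.0 / ell
    prod = z1 * z2

    def cov_fit(mask) -> tuple[float, float]:
        icpt, slope = _wls_line(ell[mask], prod[mask], w[mask])
        return icpt, slope * scores.m / math.sqrt(n1 * n2)

    def h2_of(z, n, mask) -> float:
        _, slope = _wls_line(ell[mask], (z**2)[mask], w[mask])
        return slope * scores.m / n

    full = np.ones(len(z1), dtype=bool)
    icpt, gencov = cov_fit(full)
    h1 = h2_of(z1, n1, full)
    h2_ = h2_of(z2, n2, full)
    if h1 <= 0 or h2_ <= 0:
        return LdscFit(
            kind="rg", estimate=gencov, se=float("nan"),
            intercept=icpt, intercept_se=float("nan"), n_blocks=n_blocks,
            reason="non-positive estimated heritability; rg undefined",
        )
    rg_raw = gencov / math.sqrt(h1 * h2_)

    blocks = _block_bounds(len(z1), n_blocks)
    loo_cov, loo_icpt, loo_rg = [], [], []
    for a, b in blocks:
        mask = full.copy()
        mask[a:b] = False
        ic, gc = cov_fit(mask)
        h1b, h2b = h2_of(z1, n1, mask), h2_of(z2, n2, mask)
        loo_cov.append(gc)
        loo_icpt.append(ic)
        loo_rg.append(gc / math.sqrt(h1b * h2b) if h1b > 0 and h2b > 0 else rg_raw)
    rg_se = _jackknife(np.array(loo_rg))

    rg = rg_raw
    if abs(rg_raw) > 1:
        logger.warning("rg %.4f outside [-1, 1]; clamped", rg_raw)
        rg = math.copysign(1.0, rg_raw)
    p = float(2 * stats.norm.sf(abs(rg_raw / rg_se))) if rg_se > 0 else 0.0
    return LdscFit(
        kind="rg",
        estimate=gencov,
        se=_jackknife(np.array(loo_cov)),
        intercept=icpt,
        intercept_se=_jackknife(np.array(loo_icpt)),
        n_blocks=n_blocks,
        rg=rg,
        rg_se=rg_se,
        rg_raw=rg_raw,
        pvalue=p,
        significant_after_bonferroni=bool(p < 0.05 / n_tests),
    )
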