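"""Two-sample Mendelian randomisation estimators and power calculation.

Five estimators over a harmonised instrument set:

* Wald ratio — single-SNP causal estimate ``by/bx`` with first-order
  delta-method standard error.
* IVW — fixed-effects inverse-variance pooling of the per-SNP ratios,
  the primary estimator.
* MR-Egger — weighted regression with a free intercept; the intercept
  estimates directional horizontal pleiotropy (valid under InSIDE).
* Weighted median — consistent when instruments carrying at least half
  of the weight are valid.
* Penalised weighted median — weighted median with heterogeneity-penalised
  weights, down-weighting outlying ratios.

Plus the binary-outcome power calculation and Bonferroni significance
flagging across the set of tested risk factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats

from osteomr.errors import InputError
from osteomr.meta import Z95
from osteomr.sumstats import HarmonizedInstrumentSet

#: methods exposed by the suite
METHODS = ("wald", "ivw", "egger", "wmedian", "pwmedian")


@dataclass(frozen=True)
class MREstimate:
    """Causal effect estimate from one MR method.

    ``beta`` is on the log-odds scale for a binary outcome (per unit of a
    quantitative exposure, or per unit log-odds of a binary exposure before
    :func:`osteomr.instruments.rescale_binary_exposure`); ``ci_low`` and
    ``ci_high`` are exponentiated.  Egger results additionally carry the
    intercept triple.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    exposure_type: str = "quantitative"
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    significant_after_bonferroni: bool | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InputError(f"unknown method {self.method!r}")
        if self.n_snps < 1:
            raise InputError("n_snps must be >= 1")
        has_intercept = self.intercept is not None
        if has_intercept != (self.method == "egger"):
            raise InputError("intercept fields are present iff method='egger'")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the binary-outcome MR power calculation.

    ``r2_gx`` is the fraction of exposure variance explained by the
    instruments; ``case_fraction`` is the outcome case proportion K.
    """

    alpha: float
    n_outcome: int
    case_fraction: float
    r2_gx: float
    target_or: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")
        if not 0 < self.case_fraction < 1:
            raise InputError("case_fraction must be in (0, 1)")
        if not 0 <= self.r2_gx <= 1:
            raise InputError("r2_gx must be in [0, 1]")
        if self.target_or <= 0 or self.n_outcome <= 0:
            raise InputError("target_or and n_outcome must be positive")


def _normal_ci_p(beta: float, se: float) -> tuple[float, float, float]:
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else 0.0
    return math.exp(beta - Z95 * se), math.exp(beta + Z95 * se), float(p)


def wald_ratio(
    bx: float, se_bx: float, by: float, se_by: float,
    exposure_type: str = "quantitative",
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument causal estimate ``by / bx``.

    The default standard error is the first-order delta method
    ``se_by / |bx|`` (exposure-side uncertainty ignored, matching
    inverse-variance weighting); ``second_order=True`` adds the
    exposure-uncertainty term ``by^2 se_bx^2 / bx^4``.
    """
    if bx == 0:
        raise InputError("wald_ratio undefined for bx = 0")
    beta = by / bx
    var = se_by**2 / bx**2
    if second_order:
        var += by**2 * se_bx**2 / bx**4
    se = math.sqrt(var)
    lo, hi, p = _normal_ci_p(beta, se)
    return MREstimate("wald", beta, se, lo, hi, p, 1, exposure_type)


def ivw(instruments: HarmonizedInstrumentSet) -> MREstimate:
    """Fixed-effects inverse-variance-weighted estimate.

    ``beta = sum(bx by / se_by^2) / sum(bx^2 / se_by^2)`` with
    ``se = 1 / sqrt(sum(bx^2 / se_by^2))`` — a zero-intercept weighted
    regression of outcome on exposure effects, with no overdispersion
    scaling.  Reduces to the Wald ratio for a single instrument.
    """
    if len(instruments) == 0:
        raise InputError("ivw requires at least one instrument")
    bx, _, by, se_by = instruments.arrays()
    w = bx**2 / se_by**2
    beta = float(np.sum(bx * by / se_by**2) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    lo, hi, p = _normal_ci_p(beta, se)
    return MREstimate("ivw", beta, se, lo, hi, p,
                      len(instruments), instruments.exposure_type)


def egger(instruments: HarmonizedInstrumentSet) -> MREstimate:
    """MR-Egger regression: WLS of by on bx with a free intercept.

    Instruments are first oriented so all ``bx >= 0`` (joint sign flips
    leave the causal slope invariant but are required for the intercept to
    measure directional pleiotropy).  Weights are ``1/se_by^2``; inference
    uses the t distribution on ``k - 2`` degrees of freedom with the
    regression's residual-variance-scaled standard errors.

    Requires more than two instruments.
    """
    k = len(instruments)
    if k <= 2:
        raise InputError("egger requires more than two instruments")
    bx, _, by, se_by = instruments.arrays()
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / se_by**2).fit()
    a, beta = float(fit.params[0]), float(fit.params[1])
    a_se, se = float(fit.bse[0]), float(fit.bse[1])
    df = k - 2
    p = float(2 * stats.t.sf(abs(beta / se), df))
    a_p = float(2 * stats.t.sf(abs(a / a_se), df))
    return MREstimate(
        "egger", beta, se,
        math.exp(beta - Z95 * se), math.exp(beta + Z95 * se), p,
        k, instruments.exposure_type,
        intercept=a, intercept_se=a_se, intercept_p=a_p,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted median with midpoint interpolation, vectorised over rows.

    For each row: sort ratios, form normalised cumulative weights
    ``s_j``, evaluate the midpoint positions ``s'_j = s_j - w_j/2`` and
    linearly interpolate the ratio at position 0.5.
    """
    r = np.atleast_2d(ratios)
    w = np.atleast_2d(weights).astype(float)
    order = np.argsort(r, axis=1)
    r = np.take_along_axis(r, order, axis=1)
    w = np.take_along_axis(w, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w  # midpoint positions in (0, 1)
    out = np.empty(r.shape[0])
    for i in range(r.shape[0]):
        si, ri = s[i], r[i]
        if 0.5 <= si[0]:
            out[i] = ri[0]
        elif 0.5 >= si[-1]:
            out[i] = ri[-1]
        else:
            out[i] = np.interp(0.5, si, ri)
    return out


def _median_bootstrap_se(
    instruments: HarmonizedInstrumentSet,
    n_boot: int,
    seed: int,
    weight_fn,
) -> float:
    """Parametric bootstrap: redraw (bx, by) from their normal errors."""
    bx, se_bx, by, se_by = instruments.arrays()
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, se_bx, size=(n_boot, len(bx)))
    by_b = rng.normal(by, se_by, size=(n_boot, len(by)))
    bx_b = np.where(bx_b == 0, 1e-300, bx_b)
    ratios = by_b / bx_b
    weights = weight_fn(bx_b, by_b, se_by)
    ests = _weighted_median_point(ratios, weights)
    return float(np.std(ests, ddof=1))


def weighted_median(
    instruments: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Weights are the inverse-variance weights ``bx^2 / se_by^2``; the
    estimate interpolates between the ratios bracketing cumulative weight
    0.5 (midpoint convention).  The standard error is the standard
    deviation of ``n_boot`` seeded parametric-bootstrap replicates.
    Consistent when valid instruments carry at least 50% of the weight.
    """
    if len(instruments) < 3:
        raise InputError("weighted_median requires at least 3 instruments")
    bx, _, by, se_by = instruments.arrays()
    if np.any(bx == 0):
        raise InputError("weighted_median undefined for bx = 0")
    beta = float(_weighted_median_point(by / bx, bx**2 / se_by**2)[0])
    se = _median_bootstrap_se(
        instruments, n_boot, seed, lambda bxb, byb, seb: bxb**2 / seb**2
    )
    lo, hi, p = _normal_ci_p(beta, se)
    return MREstimate("wmedian", beta, se, lo, hi, p,
                      len(instruments), instruments.exposure_type)


def _penalised_weights(
    bx: np.ndarray, by: np.ndarray, se_by: np.ndarray, penalty_scale: float
) -> np.ndarray:
    """Heterogeneity-penalised inverse-variance weights (row-wise).

    Per-SNP heterogeneity is measured against the robust weighted-median
    anchor: ``Q_j = w_j (r_j - beta_wm)^2`` with one degree of freedom,
    ``q_j`` its upper-tail chi-square probability, and the penalised
    weight ``w_j * min(1, penalty_scale * q_j)``.  Anchoring at the
    weighted median (rather than IVW) keeps valid instruments from being
    penalised when an outlier drags the anchor.
    """
    w = bx**2 / se_by**2
    ratios = by / bx
    anchor = _weighted_median_point(np.atleast_2d(ratios), np.atleast_2d(w))
    if ratios.ndim == 1:
        anchor = anchor[0]
    else:
        anchor = anchor[:, None]
    q_stat = w * (ratios - anchor) ** 2
    q_tail = stats.chi2.sf(q_stat, df=1)
    return w * np.minimum(1.0, penalty_scale * q_tail)


def penalized_weighted_median(
    instruments: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
    penalty_scale: float = 20.0,
) -> MREstimate:
    """Weighted median with outlier-penalised weights.

    Ratios far from the weighted-median anchor (large per-SNP
    heterogeneity Q_j)
    have their weights multiplied by ``min(1, penalty_scale * q_j)`` where
    ``q_j`` is the chi-square(1) upper-tail probability of Q_j; the
    weighted median then proceeds as usual.  With homogeneous ratios the
    penalties are inactive and the estimate equals the plain weighted
    median.
    """
    if len(instruments) < 3:
        raise InputError("penalized_weighted_median requires at least 3 instruments")
    bx, _, by, se_by = instruments.arrays()
    if np.any(bx == 0):
        raise InputError("penalized_weighted_median undefined for bx = 0")
    w_pen = _penalised_weights(bx, by, se_by, penalty_scale)
    beta = float(_weighted_median_point(by / bx, w_pen)[0])
    se = _median_bootstrap_se(
        instruments, n_boot, seed,
        lambda bxb, byb, seb: _penalised_weights(bxb, byb, seb, penalty_scale),
    )
    lo, hi, p = _normal_ci_p(beta, se)
    return MREstimate("pwmedian", beta, se, lo, hi, p,
                      len(instruments), instruments.exposure_type)


def mr_power(params: PowerParams) -> float:
    """Power of a two-sided MR test for a binary outcome.

    Non-centrality ``z = ln(OR) * sqrt(N * R2_GX * K * (1-K))``;
    power = Phi(z - z_{1-a/2}) + Phi(-z - z_{1-a/2}).  At OR = 1 this
    returns the test size alpha.
    """
    z_crit = stats.norm.ppf(1 - params.alpha / 2)
    ncp = math.log(params.target_or) * math.sqrt(
        params.n_outcome
        * params.r2_gx
        * params.case_fraction
        * (1 - params.case_fraction)
    )
    return float(stats.norm.cdf(ncp - z_crit) + stats.norm.cdf(-ncp - z_crit))


def bonferroni_flag(results, n_tests: int):
    """Attach Bonferroni significance flags at level 0.05 / n_tests.

    The comparison is strict: a p-value exactly at the threshold is not
    flagged.  Returns new estimates in input order.
    """
    if n_tests < 1:
        raise InputError("n_tests must be >= 1")
    threshold = 0.05 / n_tests
    return [
        replace(r, significant_after_bonferroni=bool(r.pvalue < threshold))
        for r in results
    ]
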