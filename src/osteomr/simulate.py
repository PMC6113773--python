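"""Synthetic-data generators with known ground truth.

Three test beds, all pure functions of (parameters, seed):

* :func:`simulate_cohort_gwas` — individual-level multi-cohort case-control
  GWAS.  Genotypes come from autoregressive LD blocks; case status from a
  logistic model with sex, age (linear and quadratic), height and weight
  covariates plus the specified per-allele SNP effects; each cohort's
  summary statistics are produced by per-SNP logistic regression fitted by
  iteratively reweighted least squares.
* :func:`simulate_two_sample` — summary-level exposure/outcome instrument
  sets with a configurable causal effect, an invalid-instrument fraction
  carrying direct (pleiotropic) outcome effects, and an optional knob
  correlating pleiotropy with instrument strength (breaking InSIDE).
* :func:`simulate_ldsc_pair` — z-scores for two polygenic traits whose
  per-SNP true effects are bivariate normal with the requested
  heritabilities and genetic correlation, with LD tagging and
  overlapping-sample correlation.

All randomness flows from a single master seed through named substreams so
modules can be exercised in isolation yet reproduce bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from osteomr.errors import InputError
from osteomr.instruments import LDMatrix
from osteomr.ldsc import LDScores
from osteomr.sumstats import SummaryStatsTable

#: substream labels -> offsets mixed into the master seed
_STREAMS = {"genotypes": 1, "phenotypes": 2, "noise": 3, "layout": 4}

#: non-strand-ambiguous allele pairs cycled over simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters against which recovery is tested.

    ``causal_beta`` is the true causal effect of the exposure on the
    outcome (log-odds per exposure unit); ``frac_invalid`` of instruments
    carry direct outcome effects drawn from
    Normal(pleiotropy_mean, pleiotropy_sd^2); ``pleiotropy_bx_corr``
    couples those direct effects with instrument strength, violating
    InSIDE when non-zero.  ``h2_1, h2_2, rg_true`` parameterise the
    polygenic test bed; ``case_fraction`` is the outcome case proportion
    used for the outcome-side standard errors.
    """

    causal_beta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    frac_invalid: float = 0.0
    pleiotropy_bx_corr: float = 0.0
    h2_1: float = 0.3
    h2_2: float = 0.3
    rg_true: float = 0.0
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    n_shared: int = 0
    case_fraction: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_invalid <= 1:
            raise InputError("frac_invalid must be in [0, 1]")
        if not -1 <= self.rg_true <= 1:
            raise InputError("rg_true must be in [-1, 1]")
        if not 0 < self.case_fraction < 1:
            raise InputError("case_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _block_sizes(n_snps: int, ld_block_spec) -> list[tuple[int, float]]:
    """Normalise a block spec to [(size, rho), ...] covering n_snps."""
    if ld_block_spec is None:
        ld_block_spec = [(10, 0.0)]
    out: list[tuple[int, float]] = []
    total = 0
    i = 0
    while total < n_snps:
        size, rho = ld_block_spec[i % len(ld_block_spec)]
        size = min(size, n_snps - total)
        out.append((int(size), float(rho)))
        total += size
        i += 1
    return out


def _ar1_corr(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def block_ld_matrix(n_snps: int, ld_block_spec, snp_ids=None) -> LDMatrix:
    """Block-diagonal LD (r2) matrix from autoregressive blocks."""
    r2 = np.zeros((n_snps, n_snps))
    start = 0
    for size, rho in _block_sizes(n_snps, ld_block_spec):
        r2[start : start + size, start : start + size] = _ar1_corr(size, rho) ** 2
        start += size
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(n_snps)]
    return LDMatrix(snp_ids=list(snp_ids), r2=r2)


def _sample_genotypes(
    rng: np.random.Generator, n_ind: int, eaf: np.ndarray, blocks
) -> np.ndarray:
    """Genotypes (0/1/2) with AR(1) LD via a Gaussian copula per haplotype."""
    n_snps = len(eaf)
    thresh = stats.norm.ppf(eaf)
    g = np.zeros((n_ind, n_snps), dtype=np.int8)
    for _ in range(2):  # two haplotypes
        z = np.empty((n_ind, n_snps))
        start = 0
        for size, rho in blocks:
            e = rng.standard_normal((n_ind, size))
            zb = np.empty_like(e)
            zb[:, 0] = e[:, 0]
            c = math.sqrt(1 - rho**2)
            for j in range(1, size):
                zb[:, j] = rho * zb[:, j - 1] + c * e[:, j]
            z[:, start : start + size] = zb
            start += size
        g += (z < thresh).astype(np.int8)
    return g


def _logistic_irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic regression by iteratively reweighted least squares.

    Returns (coefficients, standard errors, converged).  Convergence is
    declared when the max absolute coefficient update falls below ``tol``.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        xtx = X.T @ Xw
        xtz = Xw.T @ z
        new = np.linalg.solve(xtx, xtz)
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-10)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov)), converged


def _snp_frame(snp_ids, eaf, beta, se, pvalue, n) -> pd.DataFrame:
    k = len(snp_ids)
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(k)]
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": ["1"] * k,
            "pos": (np.arange(k) + 1) * 10_000,
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": np.clip(pvalue, np.nextafter(0, 1), 1.0),
            "n": n,
        }
    )


def simulate_cohort_gwas(
    n_cohorts: int,
    n_snps: int,
    n_cases: int,
    n_controls: int,
    ld_block_spec=None,
    effect_spec: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[list[SummaryStatsTable], SimulationTruth]:
    """Individual-level multi-cohort case-control GWAS.

    Each cohort draws genotypes from the shared allele frequencies and LD
    blocks, simulates case status from a logistic model including sex,
    age, age^2, height and weight plus the SNP effects in ``effect_spec``
    (a mapping of SNP index to per-allele log-odds), samples ``n_cases``
    cases and ``n_controls`` controls, and fits one covariate-adjusted
    logistic regression per SNP.  Non-converged fits are dropped.

    Returns one :class:`SummaryStatsTable` per cohort plus the truth.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise InputError("n_cases and n_controls must be positive")
    effect_spec = effect_spec or {}
    blocks = _block_sizes(n_snps, ld_block_spec)
    layout_rng = _rng(seed, "layout")
    eaf = layout_rng.uniform(0.05, 0.95, size=n_snps)
    betas = np.zeros(n_snps)
    for idx, b in effect_spec.items():
        betas[int(idx)] = float(b)
    snp_ids = [f"rs{i + 1}" for i in range(n_snps)]

    # covariate effects on the liability (log-odds) scale
    cov_effects = np.array([0.25, 0.015, 0.0002, -0.01, 0.005])
    tables = []
    for c in range(n_cohorts):
        geno_rng = np.random.default_rng([seed, _STREAMS["genotypes"], c])
        pheno_rng = np.random.default_rng([seed, _STREAMS["phenotypes"], c])
        pool = int(2.5 * (n_cases + n_controls))
        g = _sample_genotypes(geno_rng, pool, eaf, blocks)
        sex = pheno_rng.integers(0, 2, size=pool).astype(float)
        age = pheno_rng.normal(60, 10, size=pool)
        height = pheno_rng.normal(170, 10, size=pool) + 6 * (sex - 0.5)
        weight = pheno_rng.normal(75, 12, size=pool)
        covs = np.column_stack([sex, age, age**2, height, weight])
        eta = (covs - covs.mean(axis=0)) @ cov_effects
        eta += (g - 2 * eaf) @ betas
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = (pheno_rng.random(pool) < prob).astype(float)
        case_idx = np.flatnonzero(y == 1)[:n_cases]
        ctrl_idx = np.flatnonzero(y == 0)[:n_controls]
        if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
            raise InputError("simulated pool too small for requested counts")
        keep = np.concatenate([case_idx, ctrl_idx])
        gk, yk = g[keep].astype(float), y[keep]
        covk = covs[keep]
        covk = (covk - covk.mean(axis=0)) / covk.std(axis=0)
        base = np.column_stack([np.ones(len(keep)), covk])

        est = np.full(n_snps, np.nan)
        se = np.full(n_snps, np.nan)
        ok = np.zeros(n_snps, dtype=bool)
        X = np.column_stack([base, np.zeros(len(keep))])
        for j in range(n_snps):
            X[:, -1] = gk[:, j]
            try:
                coef, bse, conv = _logistic_irls(X, yk)
            except np.linalg.LinAlgError:
                continue
            if conv and np.isfinite(bse[-1]) and bse[-1] > 0:
                est[j], se[j], ok[j] = coef[-1], bse[-1], True
        z = est[ok] / se[ok]
        pv = 2 * stats.norm.sf(np.abs(z))
        obs_eaf = gk[:, ok].mean(axis=0) / 2
        df = _snp_frame(
            [snp_ids[j] for j in np.flatnonzero(ok)],
            obs_eaf, est[ok], se[ok], pv, n_cases + n_controls,
        )
        tables.append(
            SummaryStatsTable(trait_name=f"cohort_{c + 1}", trait_type="binary", df=df)
        )
    truth = SimulationTruth(seed=seed)
    return tables, truth


def simulate_two_sample(
    truth: SimulationTruth, n_snps: int, ld_block_spec=None,
    positive_bx: bool = False,
) -> tuple[SummaryStatsTable, SummaryStatsTable, LDMatrix]:
    """Summary-level two-sample MR instrument sets.

    True instrument effects ``bx`` have magnitudes uniform on
    [0.03, 0.15] (per-allele effects on a unit-variance exposure) with
    random signs (all positive when ``positive_bx``, emulating effect
    alleles pre-oriented to increase the exposure — the convention under
    which directional pleiotropy is directional); outcome effects are
    ``by = causal_beta * bx + alpha`` where ``alpha`` is zero for valid
    instruments and Normal(pleiotropy_mean, pleiotropy_sd^2) for the
    invalid fraction (optionally correlated with |bx| through
    ``pleiotropy_bx_corr``, violating InSIDE).  Observed effects add
    sampling noise at the two samples' sizes; outcome standard errors use
    the binary-outcome variance with case fraction K.
    """
    seed = truth.seed
    layout = _rng(seed, "layout")
    noise = _rng(seed, "noise")
    eaf = layout.uniform(0.1, 0.9, size=n_snps)
    signs = layout.choice([-1.0, 1.0], size=n_snps)
    if positive_bx:
        signs = np.ones(n_snps)
    bx_true = layout.uniform(0.03, 0.15, size=n_snps) * signs
    n_invalid = int(round(truth.frac_invalid * n_snps))
    alpha = np.zeros(n_snps)
    if n_invalid:
        invalid = layout.choice(n_snps, size=n_invalid, replace=False)
        eps = noise.standard_normal(n_invalid)
        if truth.pleiotropy_bx_corr != 0:
            strength = np.abs(bx_true[invalid])
            zs = (strength - strength.mean()) / (strength.std() or 1.0)
            rho = truth.pleiotropy_bx_corr
            eps = rho * zs + math.sqrt(1 - rho**2) * eps
        alpha[invalid] = truth.pleiotropy_mean + truth.pleiotropy_sd * eps
    by_true = truth.causal_beta * bx_true + alpha

    var_g = 2 * eaf * (1 - eaf)
    se_bx = 1.0 / np.sqrt(truth.n_exposure * var_g)
    k = truth.case_fraction
    se_by = 1.0 / np.sqrt(truth.n_outcome * k * (1 - k) * var_g)
    bx_hat = bx_true + noise.standard_normal(n_snps) * se_bx
    by_hat = by_true + noise.standard_normal(n_snps) * se_by

    snp_ids = [f"rs{i + 1}" for i in range(n_snps)]
    p_x = 2 * stats.norm.sf(np.abs(bx_hat / se_bx))
    p_y = 2 * stats.norm.sf(np.abs(by_hat / se_by))
    exposure = SummaryStatsTable(
        "exposure", "quantitative",
        _snp_frame(snp_ids, eaf, bx_hat, se_bx, p_x, truth.n_exposure),
    )
    outcome = SummaryStatsTable(
        "outcome", "binary",
        _snp_frame(snp_ids, eaf, by_hat, se_by, p_y, truth.n_outcome),
    )
    ld = block_ld_matrix(n_snps, ld_block_spec or [(1, 0.0)], snp_ids)
    return exposure, outcome, ld


def simulate_ldsc_pair(
    truth: SimulationTruth, n_snps: int, ld_block_spec=None
) -> tuple[np.ndarray, np.ndarray, LDScores]:
    """Z-scores for two polygenic traits over an LD-structured SNP set.

    Per-SNP true effects are bivariate normal with variances ``h2/M`` and
    correlation ``rg_true``; z-scores add LD tagging (through the signed
    correlation matrix) and residual noise whose cross-trait correlation
    is ``n_shared / sqrt(N1 N2)``, the sample-overlap term absorbed by
    the regression intercept.
    """
    if ld_block_spec is None:
        # mixture of LD architectures: isolated SNPs through strong blocks,
        # giving a wide LD-score range for the regression
        ld_block_spec = [(1, 0.0), (5, 0.4), (20, 0.6), (50, 0.9)]
    seed = truth.seed
    rng = _rng(seed, "noise")
    m = n_snps
    h1, h2_, rg = truth.h2_1, truth.h2_2, truth.rg_true
    cov_b = np.array(
        [[h1 / m, rg * math.sqrt(h1 * h2_) / m],
         [rg * math.sqrt(h1 * h2_) / m, h2_ / m]]
    )
    chol_b = np.linalg.cholesky(cov_b + 1e-18 * np.eye(2))
    b = (chol_b @ rng.standard_normal((2, n_snps))).T  # (n_snps, 2)

    rho_ov = truth.n_shared / math.sqrt(truth.n_exposure * truth.n_outcome)
    chol_ov = np.linalg.cholesky(np.array([[1.0, rho_ov], [rho_ov, 1.0]]))

    z1 = np.empty(n_snps)
    z2 = np.empty(n_snps)
    ell = np.empty(n_snps)
    start = 0
    for size, rho in _block_sizes(n_snps, ld_block_spec):
        sl = slice(start, start + size)
        corr = _ar1_corr(size, rho)
        ell[sl] = (corr**2).sum(axis=1)
        chol_r = np.linalg.cholesky(corr + 1e-12 * np.eye(size))
        # tagged signal
        sig1 = corr @ b[sl, 0] * math.sqrt(truth.n_exposure)
        sig2 = corr @ b[sl, 1] * math.sqrt(truth.n_outcome)
        # residual noise: LD-correlated within trait, overlap across traits
        e = rng.standard_normal((2, size))
        e = chol_ov @ e  # cross-trait overlap correlation
        e1 = chol_r @ e[0]
        e2 = chol_r @ e[1]
        z1[sl] = sig1 + e1
        z2[sl] = sig2 + e2
        start += size
    scores = LDScores(
        snp_ids=[f"rs{i + 1}" for i in range(n_snps)], ell=ell, m=m
    )
    return z1, z2, scores
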