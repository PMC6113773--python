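"""Access to the packaged published-study reference tables.

The published fracture study prints its stage-level results only as
``OR (95% CI)`` cells.  :func:`recombine_loci` rebuilds each stage's
log-odds standard error from the printed interval and pools discovery and
replication with the fixed-effects model, which should reproduce the
printed combined odds ratio up to input-rounding error (|difference| of at
most 0.01 on the 2-decimal OR scale).
"""

from __future__ import annotations

import importlib.resources as resources
import math
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from osteomr.meta import (
    StageEstimate,
    fixed_effects_meta,
    se_from_ci,
    se_from_ci_robust,
)

#: (cases, controls) per analysis stage as published
STAGE_SIZES = {
    "discovery": (37_857, 227_116),
    "replication": (147_200, 150_085),
    "combined": (185_057, 377_201),
}


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("osteomr.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_loci_table() -> pd.DataFrame:
    """The fifteen genome-wide-significant fracture loci, per stage."""
    return _read_packaged("fracture_loci_stages.tsv")


def load_mr_table() -> pd.DataFrame:
    """The published two-sample MR results for the 15 risk factors."""
    return _read_packaged("fracture_mr_results.tsv")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _stage_se(or_point, lo, hi) -> float:
    try:
        return se_from_ci(or_point, lo, hi)
    except Exception:
        # inconsistent printed cell: fall back to the one-sided half-width
        return se_from_ci_robust(or_point, lo, hi)


def recombine_loci(loci: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pool printed discovery + replication cells and compare to combined.

    Returns one row per locus with the pooled OR (2-decimal, half-up),
    the printed combined OR and their discrepancy.
    """
    if loci is None:
        loci = load_loci_table()
    rows = []
    for rec in loci.itertuples(index=False):
        stages = [
            StageEstimate(
                "discovery",
                math.log(rec.or_disc),
                _stage_se(rec.or_disc, rec.lo_disc, rec.hi_disc),
            ),
            StageEstimate(
                "replication",
                math.log(rec.or_repl),
                _stage_se(rec.or_repl, rec.lo_repl, rec.hi_repl),
            ),
        ]
        pooled = fixed_effects_meta(stages)
        or_pooled = round_half_up(pooled.odds_ratio, 2)
        rows.append(
            {
                "snp_id": rec.snp_id,
                "or_pooled": or_pooled,
                "or_pooled_exact": pooled.odds_ratio,
                "or_printed": rec.or_comb,
                "discrepancy": round(abs(or_pooled - rec.or_comb), 10),
                "i2_pooled": pooled.i2,
            }
        )
    return pd.DataFrame(rows)
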