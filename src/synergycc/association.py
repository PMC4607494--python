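"""2x2 association statistics: Wald odds-ratio intervals, Fisher's exact
test, stratum-vs-reference odds ratios, and the sum/product additivity
comparison.

Odds ratios are unconditional ML (cross-product) estimates; confidence
intervals use the normal approximation on the log scale (Wald method) with
``se = sqrt(1/a + 1/b + 1/c + 1/d)``. In a rare-disease setting these ORs
stand in for relative risks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .cohort import JointTable


@dataclass(frozen=True)
class OddsRatioEstimate:
    or_value: float
    log_or: float
    se_log_or: float
    ci_lower: float
    ci_upper: float
    confidence_level: float = 0.95
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.or_value <= self.ci_upper):
            raise ValueError("CI does not bracket the point estimate")


class StratumOddsRatios(NamedTuple):
    """Stratum-vs-reference ORs; indices follow the exposure pattern
    (11 = both carriers, 10 = B27 only, 01 = B60 only)."""

    or11: OddsRatioEstimate
    or10: OddsRatioEstimate
    or01: OddsRatioEstimate


@dataclass(frozen=True)
class AdditivityComparison:
    """Literal comparison of the joint OR against the sum and the product
    of the single-exposure ORs (descriptive, no inference)."""

    or11: float
    sum_of_risks: float
    product_of_risks: float
    exceeds_sum: bool
    exceeds_product: bool


def odds_ratio_2x2(
    exposed_cases: int,
    unexposed_cases: int,
    exposed_controls: int,
    unexposed_controls: int,
    confidence_level: float = 0.95,
    continuity_correction: bool = False,
) -> OddsRatioEstimate:
    """Cross-product OR with a Wald interval on the log scale.

    Zero cells raise unless ``continuity_correction`` is set, in which
    case 0.5 is added to every cell and the result flagged as corrected.
    """
    cells = [exposed_cases, unexposed_cases, exposed_controls, unexposed_controls]
    if any(c < 0 or c != int(c) for c in cells):
        raise ValueError("cell counts must be non-negative integers")
    corrected = False
    if 0 in cells:
        if not continuity_correction:
            raise ValueError(
                "zero cell in 2x2 table; pass continuity_correction=True to add 0.5 to every cell"
            )
        cells = [c + 0.5 for c in cells]
        corrected = True
    a, b, c, d = cells
    or_value = (a * d) / (b * c)
    log_or = math.log(or_value)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence_level / 2)
    return OddsRatioEstimate(
        or_value=or_value,
        log_or=log_or,
        se_log_or=se,
        ci_lower=math.exp(log_or - z * se),
        ci_upper=math.exp(log_or + z * se),
        confidence_level=confidence_level,
        continuity_corrected=corrected,
    )


def stratum_odds_ratios(table: JointTable, confidence_level: float = 0.95) -> StratumOddsRatios:
    """ORs of the three exposed strata against the doubly-negative reference.

    Each stratum's 2x2 is (stratum cases, reference cases, stratum
    controls, reference controls). The reference's own OR is 1 by
    definition and not returned.
    """
    if table.cases[3] == 0 or table.controls[3] == 0:
        raise ValueError("reference stratum (B27-/B60-) must be positive in both arms")
    ests = [
        odds_ratio_2x2(*table.stratum_2x2(s), confidence_level=confidence_level)
        for s in (0, 1, 2)
    ]
    return StratumOddsRatios(or11=ests[0], or10=ests[1], or01=ests[2])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Point-probability method: sum the hypergeometric probabilities of
    every table with the observed margins whose probability does not
    exceed the observed table's (relative tolerance 1 + 1e-7 guards
    floating ties) — the convention of mainstream statistical software.
    """
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table has no exact test")
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def additivity_comparison(or11: float, or10: float, or01: float) -> AdditivityComparison:
    """Compare the joint-exposure OR against the sum and product of the
    single-exposure ORs (strict inequalities, direct arithmetic)."""
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    s, p = or10 + or01, or10 * or01
    return AdditivityComparison(
        or11=or11,
        sum_of_risks=s,
        product_of_risks=p,
        exceeds_sum=or11 > s,
        exceeds_product=or11 > p,
    )
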