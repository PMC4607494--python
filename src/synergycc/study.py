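"""Printed values from the source case-control study of HLA-B27 (tagged by
rs13202464) and HLA-B60 in ankylosing spondylitis: 471 Taiwanese patients
and 557 healthy controls.

These constants are the published inputs the analysis reproduces — arm
totals, per-factor carrier marginals, the main-effects logistic
coefficient table, the stratum ORs as printed, and the per-stratum
severity moments. They are fixture data, never recomputed; everything the
package reports is computed from them at run time.
"""

from __future__ import annotations

from .cohort import MarginalSummary, TaggingConstants
from .reconstruct import ReconstructionProblem

#: Arm totals and carrier marginals (cases 471: 431 B27+, 100 B60+;
#: controls 557: 43 B27+, 73 B60+).
MARGINALS = MarginalSummary(
    n_cases=471, n_controls=557,
    cases_b27pos=431, cases_b60pos=100,
    controls_b27pos=43, controls_b60pos=73,
)

#: Main-effects logistic coefficients (intercept, B27, B60) and SEs,
#: printed to 4 decimals.
LOGISTIC_COEFFS = (-2.6914, 4.8794, 0.7493)
LOGISTIC_SES = (0.1795, 0.2326, 0.3074)

#: Stratum ORs versus the B27-/B60- reference, at printed rounding
#: (integers for the large ORs, one decimal for the small one).
PRINTED_STRATUM_ORS = {"or11": 201.0, "or10": 152.0, "or01": 2.9}
PRINTED_STRATUM_CIS = {"or11": (85.0, 475.0), "or10": (91.0, 255.0), "or01": (1.4, 6.0)}

#: Printed additive-interaction block.
PRINTED_INTERACTION = {
    "reri": (46.79, -117.58, 211.16),
    "ap": (0.23, -0.41, 0.88),
    "s": (1.31, 0.56, 3.04),
}

#: Marginal B60 2x2 (B60+ cases, B60- cases, B60+ controls, B60- controls)
#: with its printed OR and CI.
B60_MARGINAL_2X2 = (100, 371, 73, 484)
B60_PRINTED_OR = (1.79, 1.29, 2.49)

#: rs13202464 tag performance for HLA-B27 (documentation only).
TAGGING = TaggingConstants(sensitivity=0.987, specificity=0.980)

#: Population prevalence of ankylosing spondylitis in Taiwan (0.167%),
#: the rare-disease justification for OR-for-RR substitution.
PREVALENCE = 0.00167

KNOWN_INCONSISTENCIES = (
    "The published marginal B27 OR 120.80 (CI 83.31-204.82) does not equal the "
    "cross-product of its own printed counts, 431*514/(40*43) = 128.80; the "
    "computed value is reported here and the printed one flagged as a probable typo.",
    "The published Fisher p-values appear swapped between the B27-only stratum "
    "(OR 152, printed p = 0.0072) and the B60-only stratum (OR 2.9, printed "
    "p = 1.222e-157); both are recomputed here and neither pairing is matched.",
)


def coefficient_problem() -> ReconstructionProblem:
    """Reconstruction problem: match the main-effects coefficient triple
    to the printed 4 decimals.

    On its own this identifies only the ridge x + y = 95 (the main-effects
    likelihood depends on the free cells through their sum alone), so it
    narrows 1804 candidates to 36 but cannot single out the table; it is
    the cross-check for the OR-matching mode, and :func:`combined_problem`
    is the identifying criterion.
    """
    return ReconstructionProblem(
        marginals=MARGINALS,
        matching_mode="logistic_coefficients",
        targets=LOGISTIC_COEFFS,
        rounding=(4, 4, 4),
    )


def odds_ratio_problem() -> ReconstructionProblem:
    """Reconstruction problem: match the stratum ORs at printed rounding
    (OR11 and OR10 as integers, OR01 to one decimal)."""
    return ReconstructionProblem(
        marginals=MARGINALS,
        matching_mode="stratum_odds_ratios",
        targets=(PRINTED_STRATUM_ORS["or11"], PRINTED_STRATUM_ORS["or10"],
                 PRINTED_STRATUM_ORS["or01"]),
        rounding=(0, 0, 1),
    )


def combined_problem() -> ReconstructionProblem:
    """Reconstruction problem matching both the coefficient triple and the
    printed stratum ORs — the tightest published criterion."""
    return ReconstructionProblem(
        marginals=MARGINALS,
        matching_mode="combined",
        targets=LOGISTIC_COEFFS + (PRINTED_STRATUM_ORS["or11"],
                                   PRINTED_STRATUM_ORS["or10"],
                                   PRINTED_STRATUM_ORS["or01"]),
        rounding=(4, 4, 4, 0, 0, 1),
    )


def reconstruct_study_table():
    """Recover the study's full 2x2x2 table from the printed values.

    Uses the combined criterion, asserts the OR-only mode agrees, and
    asserts the coefficient-only ridge contains the table (the two
    published statistic sets cross-validate each other).
    """
    from .reconstruct import enumerate_matches, reconstruct_joint_table

    result = reconstruct_joint_table(combined_problem())
    by_or = reconstruct_joint_table(odds_ratio_problem())
    if not (by_or.table.to_dict() == result.table.to_dict()):
        raise AssertionError("OR-matching mode disagrees with the combined criterion")
    ridge, _, _ = enumerate_matches(coefficient_problem())
    if not any(t.to_dict() == result.table.to_dict() for _, _, t, _ in ridge):
        raise AssertionError("coefficient-matching ridge does not contain the table")
    return result
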