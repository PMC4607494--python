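"""Recover the full 2x2x2 joint table from printed marginals by integer search.

Published reports often print only arm totals, per-factor carrier counts,
and summary statistics (logistic coefficients, stratum odds ratios). Given
the marginals, the whole table has exactly two free integer cells — the
doubly-positive case cell x and the doubly-positive control cell y — so an
exhaustive grid over their feasible ranges, matching each candidate's
recomputed statistics against the printed ones at the printed rounding,
recovers the table and certifies whether the match is unique. At desk
scale (<~2000 candidates) this is trivially correct and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .cohort import JointTable, MarginalSummary
from .logistic import SeparationError, fit_logistic

MATCH_MODES = ("logistic_coefficients", "stratum_odds_ratios", "combined")

#: number of target statistics per matching mode
_N_TARGETS = {"logistic_coefficients": 3, "stratum_odds_ratios": 3, "combined": 6}


@dataclass(frozen=True)
class ReconstructionProblem:
    """Marginals plus the printed statistics to match.

    ``targets``/``rounding`` depend on the mode:

    * ``logistic_coefficients`` — targets ``(b0, b1, b2)`` of the
      main-effects fit; rounding is a decimals triple (default 4 each).
      Note: the grouped main-effects likelihood depends on the two free
      cells only through their sum, so this mode identifies a ridge of
      candidates, never a single table on its own;
    * ``stratum_odds_ratios`` — targets ``(OR11, OR10, OR01)``; rounding
      per value as printed;
    * ``combined`` — the coefficient triple followed by the OR triple
      (6 targets), the tightest criterion.

    A rounding entry of ``None`` means match at full precision (absolute
    tolerance 1e-9).
    """

    marginals: MarginalSummary
    matching_mode: str
    targets: tuple[float, ...]
    rounding: tuple[int | None, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.matching_mode not in MATCH_MODES:
            raise ValueError(f"matching_mode must be one of {MATCH_MODES}")
        k = _N_TARGETS[self.matching_mode]
        if len(self.targets) != k:
            raise ValueError(f"mode {self.matching_mode!r} requires {k} target statistics")
        if self.rounding is None:
            default = {"logistic_coefficients": (4, 4, 4),
                       "stratum_odds_ratios": (None,) * 3,
                       "combined": (4, 4, 4, None, None, None)}[self.matching_mode]
            object.__setattr__(self, "rounding", default)
        if len(self.rounding) != k:
            raise ValueError("rounding spec must have one entry per target")


@dataclass(frozen=True)
class ReconstructionResult:
    table: JointTable
    unique: bool
    n_candidates: int
    n_matches: int
    residual: float  # max |recomputed - target| of the winning candidate


def candidate_tables(m: MarginalSummary) -> Iterator[tuple[int, int, JointTable]]:
    """Enumerate all integer tables consistent with the marginals.

    x = cases(B27+,B60+) ranges over [max(0, b27pos+b60pos-n), min(b27pos,
    b60pos)]; y likewise for controls; every other cell follows from the
    margins.
    """
    x_lo = max(0, m.cases_b27pos + m.cases_b60pos - m.n_cases)
    x_hi = min(m.cases_b27pos, m.cases_b60pos)
    y_lo = max(0, m.controls_b27pos + m.controls_b60pos - m.n_controls)
    y_hi = min(m.controls_b27pos, m.controls_b60pos)
    for x in range(x_lo, x_hi + 1):
        cases = np.array(
            [[x, m.cases_b27pos - x],
             [m.cases_b60pos - x, m.n_cases - m.cases_b27pos - m.cases_b60pos + x]]
        )
        for y in range(y_lo, y_hi + 1):
            controls = np.array(
                [[y, m.controls_b27pos - y],
                 [m.controls_b60pos - y,
                  m.n_controls - m.controls_b27pos - m.controls_b60pos + y]]
            )
            yield x, y, JointTable(cases, controls)


def _cross_product_ors(table: JointTable) -> tuple[float, float, float] | None:
    a, b = table.cases.astype(float), table.controls.astype(float)
    if np.any(a == 0) or np.any(b == 0):
        return None
    return tuple((a[s] * b[3]) / (a[3] * b[s]) for s in (0, 1, 2))  # type: ignore[return-value]


def _main_effects_coefs(table: JointTable) -> tuple[float, float, float] | None:
    try:
        fit = fit_logistic(table, "main_effects")
    except SeparationError:
        return None
    return tuple(fit.coefficients)  # type: ignore[return-value]


def _candidate_stats(table: JointTable, mode: str) -> tuple[float, ...] | None:
    """The statistics to match, or None when undefined on this candidate."""
    if mode == "stratum_odds_ratios":
        return _cross_product_ors(table)
    if mode == "logistic_coefficients":
        return _main_effects_coefs(table)
    coefs, ors = _main_effects_coefs(table), _cross_product_ors(table)
    if coefs is None or ors is None:
        return None
    return coefs + ors


def _matches(stats: tuple[float, ...], targets: tuple[float, ...],
             rounding: tuple[int | None, ...]) -> bool:
    for s, t, r in zip(stats, targets, rounding):
        if r is None:
            if abs(s - t) > 1e-9:
                return False
        elif round(s, r) != round(t, r):
            return False
    return True


def enumerate_matches(
    problem: ReconstructionProblem,
) -> tuple[list[tuple[int, int, JointTable, float]], int, list[tuple[float, int, int]]]:
    """All matching candidates as (x, y, table, max residual), plus the
    candidate count and the residual-sorted near-miss list."""
    matches: list[tuple[int, int, JointTable, float]] = []
    near: list[tuple[float, int, int]] = []
    n_cand = 0
    for x, y, table in candidate_tables(problem.marginals):
        n_cand += 1
        stats = _candidate_stats(table, problem.matching_mode)
        if stats is None:
            continue
        resid = max(abs(s - t) for s, t in zip(stats, problem.targets))
        near.append((resid, x, y))
        if _matches(stats, problem.targets, problem.rounding):
            matches.append((x, y, table, resid))
    near.sort()
    return matches, n_cand, near


def reconstruct_joint_table(problem: ReconstructionProblem) -> ReconstructionResult:
    """Exhaustive search for the table matching the printed statistics.

    Raises if no candidate matches (reporting the closest candidates) or
    if the match is not unique (the caller must tighten the targets).
    """
    matches, n_cand, near = enumerate_matches(problem)
    if n_cand == 0:
        raise ValueError("marginals admit no integer table")
    if not matches:
        txt = ", ".join(f"(x={x}, y={y}, max residual {r:.4g})" for r, x, y in near[:3])
        raise LookupError(
            f"no candidate among {n_cand} matches the targets under mode "
            f"{problem.matching_mode!r}; closest: {txt}"
        )
    if len(matches) > 1:
        cells = ", ".join(f"(x={x}, y={y})" for x, y, _, _ in matches)
        raise LookupError(
            f"{len(matches)} candidates match — targets too loose to identify the table: {cells}"
        )
    x, y, table, resid = matches[0]
    assert table.marginals() == problem.marginals  # marginals hold by construction
    return ReconstructionResult(
        table=table, unique=True, n_candidates=n_cand, n_matches=1, residual=resid
    )
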