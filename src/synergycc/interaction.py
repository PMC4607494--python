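"""Additive-scale interaction measures: RERI, AP and the synergy index.

For two binary exposures with stratum-vs-reference odds ratios OR11, OR10
and OR01 (odds ratios substituting for relative risks under the
rare-disease assumption):

* ``RERI = OR11 - OR10 - OR01 + 1`` — relative excess risk due to
  interaction (0 under additivity of risk effects);
* ``AP = RERI / OR11`` — proportion of double-exposure disease
  attributable to interaction (0 under additivity);
* ``S = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))`` — synergy index (1 under
  additivity).

Confidence intervals use the delta method on the covariance of the three
log odds ratios from the saturated logistic fit (Hosmer–Lemeshow
construction): RERI and AP intervals are symmetric on the natural scale,
the S interval is formed on the log scale and exponentiated. A percentile
bootstrap (independent multinomial resampling of the case and control
arms) is provided as a model-free alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import JointTable, STRATUM_LABELS
from .logistic import LogisticFit, fit_logistic

# (b1, b2, b3) -> (L11, L10, L01)
_BETA_TO_L = np.array([[1.0, 1.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class MeasureEstimate:
    value: float
    ci_lower: float
    ci_upper: float
    se: float | None = None


@dataclass(frozen=True)
class InteractionMeasures:
    reri: MeasureEstimate
    ap: MeasureEstimate
    s: MeasureEstimate
    or11: float
    or10: float
    or01: float
    confidence_level: float
    method: str  # "delta" | "bootstrap"
    n_boot: int | None = None
    n_excluded_replicates: int | None = None


def _point_measures(or11: float, or10: float, or01: float) -> tuple[float, float, float]:
    reri = or11 - or10 - or01 + 1.0
    ap = reri / or11
    denom = (or10 - 1.0) + (or01 - 1.0)
    if denom <= 0:
        raise ValueError(
            f"synergy index undefined: (OR10-1)+(OR01-1) = {denom:.6g} <= 0 "
            "(at least one single-exposure OR must exceed 1 on balance)"
        )
    s = (or11 - 1.0) / denom
    return reri, ap, s


def interaction_measures(fit: LogisticFit, confidence_level: float = 0.95) -> InteractionMeasures:
    """RERI/AP/S with delta-method CIs from a converged saturated fit.

    Variances are g'Vg with V the covariance of (log OR11, log OR10,
    log OR01) and g the gradient of each measure in those log ORs.
    """
    if fit.model != "saturated":
        raise ValueError("interaction measures require the saturated model fit")
    if not fit.converged:
        raise ValueError("logistic fit did not converge")
    b = fit.coefficients[1:4]
    L = _BETA_TO_L @ b  # (L11, L10, L01)
    V = _BETA_TO_L @ fit.covariance[1:4, 1:4] @ _BETA_TO_L.T
    or11, or10, or01 = np.exp(L)
    reri, ap, s = _point_measures(or11, or10, or01)
    if or11 <= 1.0:
        import warnings

        warnings.warn(
            "OR11 <= 1: the synergy index is not meaningful for a protective joint effect",
            stacklevel=2,
        )
    z = stats.norm.ppf(0.5 + confidence_level / 2)

    g_reri = np.array([or11, -or10, -or01])
    se_reri = math.sqrt(g_reri @ V @ g_reri)

    g_ap = np.array([(or10 + or01 - 1.0) / or11, -or10 / or11, -or01 / or11])
    se_ap = math.sqrt(g_ap @ V @ g_ap)

    if s > 0:
        denom = (or10 - 1.0) + (or01 - 1.0)
        g_logs = np.array([or11 / (or11 - 1.0), -or10 / denom, -or01 / denom])
        se_logs = math.sqrt(g_logs @ V @ g_logs)
        log_s = math.log(s)
        s_est = MeasureEstimate(
            s, math.exp(log_s - z * se_logs), math.exp(log_s + z * se_logs), se_logs
        )
    else:
        # S < 0 (protective joint effect over a positive denominator): the
        # log-scale interval does not exist
        s_est = MeasureEstimate(s, math.nan, math.nan, None)

    return InteractionMeasures(
        reri=MeasureEstimate(reri, reri - z * se_reri, reri + z * se_reri, se_reri),
        ap=MeasureEstimate(ap, ap - z * se_ap, ap + z * se_ap, se_ap),
        s=s_est,
        or11=float(or11), or10=float(or10), or01=float(or01),
        confidence_level=confidence_level, method="delta",
    )


def measures_from_table(table: JointTable, confidence_level: float = 0.95) -> InteractionMeasures:
    """Convenience: saturated fit then :func:`interaction_measures`."""
    return interaction_measures(fit_logistic(table, "saturated"), confidence_level)


def _replicate_ors(case_draws: np.ndarray, control_draws: np.ndarray) -> np.ndarray:
    """Stratum-vs-reference cross-product ORs per bootstrap replicate;
    rows with any required zero cell become NaN."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ors = (case_draws[:, :3] * control_draws[:, 3:4]) / (
            case_draws[:, 3:4] * control_draws[:, :3]
        )
    ors[~np.isfinite(ors)] = np.nan
    ors[ors == 0] = np.nan
    return ors  # columns (OR11, OR10, OR01)


def interaction_bootstrap(
    table: JointTable,
    n_boot: int = 10_000,
    seed: int | None = None,
    confidence_level: float = 0.95,
) -> InteractionMeasures:
    """Percentile-bootstrap CIs for RERI/AP/S.

    Cases and controls are resampled independently as multinomials over
    the four strata (the retrospective sampling design). Replicates with
    an undefined measure (zero cell or non-positive S denominator) are
    excluded with a warning; more than 10% undefined is an error.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for a reproducible bootstrap")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    bad = (table.cases == 0) | (table.controls == 0)
    if np.any(bad):
        lab = STRATUM_LABELS[int(np.argmax(bad))]
        raise ValueError(f"stratum {lab} empty in one arm: bootstrap measures undefined")
    rng = np.random.default_rng(seed)
    pc = table.cases / table.n_cases
    pk = table.controls / table.n_controls
    case_draws = rng.multinomial(table.n_cases, pc, size=n_boot).astype(float)
    ctrl_draws = rng.multinomial(table.n_controls, pk, size=n_boot).astype(float)
    ors = _replicate_ors(case_draws, ctrl_draws)

    or11, or10, or01 = ors[:, 0], ors[:, 1], ors[:, 2]
    reri = or11 - or10 - or01 + 1.0
    ap = reri / or11
    denom = (or10 - 1.0) + (or01 - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, (or11 - 1.0) / denom, np.nan)

    ok = np.isfinite(reri) & np.isfinite(ap) & np.isfinite(s)
    n_excl = int(n_boot - ok.sum())
    if n_excl > 0.10 * n_boot:
        raise RuntimeError(
            f"{n_excl}/{n_boot} bootstrap replicates undefined: measures unstable on this table"
        )
    if n_excl:
        import warnings

        warnings.warn(f"excluded {n_excl} bootstrap replicate(s) with undefined measures",
                      stacklevel=2)
    alpha = 1.0 - confidence_level
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))

    o11, o10, o01 = (float(x) for x in _observed_ors(table))
    reri0, ap0, s0 = _point_measures(o11, o10, o01)

    def _ci(arr: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(arr[ok], qs)
        return float(lo), float(hi)

    return InteractionMeasures(
        reri=MeasureEstimate(reri0, *_ci(reri)),
        ap=MeasureEstimate(ap0, *_ci(ap)),
        s=MeasureEstimate(s0, *_ci(s)),
        or11=o11, or10=o10, or01=o01,
        confidence_level=confidence_level, method="bootstrap",
        n_boot=n_boot, n_excluded_replicates=n_excl,
    )


def _observed_ors(table: JointTable) -> tuple[float, float, float]:
    a, b = table.cases.astype(float), table.controls.astype(float)
    return tuple((a[s] * b[3]) / (a[3] * b[s]) for s in (0, 1, 2))  # type: ignore[return-value]
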