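"""Grouped binomial-logit maximum likelihood on the four carrier strata.

The four covariate patterns (B27 x B60 carrier indicators) are fitted as a
grouped binomial GLM with logit link by Newton iteration (IRLS), which is
the same MLE as a subject-level fit but numerically cleaner. Two designs
are supported:

* ``main_effects`` — intercept + B27 + B60 (the published coefficient
  table's model);
* ``saturated`` — adds the B27xB60 product term; its fitted stratum
  probabilities equal the empirical proportions exactly, so
  ``exp(b1) = OR10``, ``exp(b2) = OR01`` and ``exp(b1+b2+b3) = OR11``.

The coefficient covariance is the inverse observed information at the
optimum (equal to expected information for the canonical link). For the
saturated model the covariance of the three stratum log-ORs also has a
closed form in reciprocal cell counts, used as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .cohort import JointTable, STRATUM_LABELS

MAX_ITER = 50
COEF_TOL = 1e-10
LL_REL_TOL = 1e-12

#: design rows in fixed stratum order; columns (intercept, b27, b60, b27*b60)
_DESIGN = np.array(
    [[1.0, 1.0, 1.0, 1.0],
     [1.0, 1.0, 0.0, 0.0],
     [1.0, 0.0, 1.0, 0.0],
     [1.0, 0.0, 0.0, 0.0]]
)

COEF_NAMES = {
    "main_effects": ("intercept", "b27", "b60"),
    "saturated": ("intercept", "b27", "b60", "b27_x_b60"),
}


@dataclass(frozen=True)
class LogisticFit:
    model: str
    coefficients: np.ndarray
    covariance: np.ndarray
    converged: bool
    n_iterations: int
    log_likelihood: float

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def coef_names(self) -> tuple[str, ...]:
        return COEF_NAMES[self.model]

    def wald_z(self) -> np.ndarray:
        return self.coefficients / self.standard_errors

    def wald_p(self) -> np.ndarray:
        from scipy import stats

        return 2 * stats.norm.sf(np.abs(self.wald_z()))


class SeparationError(RuntimeError):
    """Raised when the MLE does not exist (empty or one-armed stratum)."""


def _binom_loglik(y, n, eta) -> float:
    # log C(n,y) + y*eta - n*log(1+exp(eta)), stable for large |eta|
    return float(
        np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
               + y * eta - n * np.logaddexp(0.0, eta))
    )


def fit_logistic(table: JointTable, model: str = "main_effects") -> LogisticFit:
    """Fit the grouped binomial-logit model by Newton/IRLS from beta = 0.

    Carrier status is coded 1, non-carrier 0. Convergence requires the max
    absolute coefficient change < 1e-10 or relative log-likelihood change
    < 1e-12 within 50 iterations.
    """
    if model not in COEF_NAMES:
        raise ValueError(f"model must be 'main_effects' or 'saturated', got {model!r}")
    y = table.cases.astype(float)
    n = (table.cases + table.controls).astype(float)
    if np.any(n == 0):
        empty = STRATUM_LABELS[int(np.argmax(n == 0))]
        raise SeparationError(f"stratum {empty} has no subjects in either arm")
    if model == "saturated":
        bad = (table.cases == 0) | (table.controls == 0)
        if np.any(bad):
            lab = STRATUM_LABELS[int(np.argmax(bad))]
            raise SeparationError(
                f"stratum {lab} has zero cases or zero controls: the saturated MLE diverges"
            )
    X = _DESIGN[:, :3] if model == "main_effects" else _DESIGN

    beta = np.zeros(X.shape[1])
    ll = _binom_loglik(y, n, X @ beta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1.0 - p)
        info = X.T @ (w[:, None] * X)
        score = X.T @ (y - n * p)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError("singular information matrix: model not identified") from None
        beta = beta + step
        ll_new = _binom_loglik(y, n, X @ beta)
        if np.max(np.abs(step)) < COEF_TOL or abs(ll_new - ll) <= LL_REL_TOL * (abs(ll) + 1e-300):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        raise SeparationError(f"IRLS did not converge in {MAX_ITER} iterations")

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = n * p * (1.0 - p)
    info = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2
    return LogisticFit(
        model=model,
        coefficients=beta,
        covariance=cov,
        converged=converged,
        n_iterations=it,
        log_likelihood=ll,
    )


def stratum_logor_covariance(table: JointTable) -> np.ndarray:
    """Closed-form 3x3 covariance of (log OR11, log OR10, log OR01).

    Each variance is the reciprocal-cell sum of that stratum's 2x2; every
    off-diagonal covariance is 1/(reference cases) + 1/(reference
    controls), the shared reference cells. Requires all 8 cells positive.
    """
    a, b = table.cases.astype(float), table.controls.astype(float)
    if np.any(a == 0) or np.any(b == 0):
        raise ValueError("closed-form log-OR covariance requires all 8 cells positive")
    shared = 1 / a[3] + 1 / b[3]
    var = np.array([1 / a[s] + 1 / a[3] + 1 / b[s] + 1 / b[3] for s in (0, 1, 2)])
    V = np.full((3, 3), shared)
    np.fill_diagonal(V, var)
    return V


# (L11, L10, L01) -> (b1, b2, b3): b1 = L10, b2 = L01, b3 = L11 - L10 - L01
_L_TO_BETA = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, -1.0, -1.0]])


def coefficient_covariance_closed_form(table: JointTable) -> np.ndarray:
    """Closed-form covariance of the saturated model's (b1, b2, b3),
    transformed from the stratum log-OR covariance. Cross-check for the
    inverse-information covariance of :func:`fit_logistic`."""
    V = stratum_logor_covariance(table)
    return _L_TO_BETA @ V @ _L_TO_BETA.T
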