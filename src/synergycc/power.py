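"""One-stage case-control power for a carrier-based association test.

Normal-approximation power of the two-sided two-proportion test comparing
carrier frequency in cases against controls (dominant/carrier coding).
The expected case-arm carrier frequency follows from the control-arm
frequency and the carrier odds ratio,

    p_case = OR * p / (1 + p * (OR - 1)),

which is exact for odds and serves as the rare-disease approximation for
relative risks. The critical value uses the null-pooled variance; the
noncentrality uses the variances under the alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    n_cases: int
    n_controls: int
    alpha: float = 0.05
    prevalence: float = 0.00167
    carrier_freq_controls: float = 0.5
    effect: float = 1.0  # carrier odds ratio
    test: str = "two_proportion_carrier"

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both arms need at least one subject")
        for name in ("alpha", "prevalence", "carrier_freq_controls"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.effect <= 0:
            raise ValueError("effect (odds ratio) must be positive")
        if self.test != "two_proportion_carrier":
            raise ValueError(f"unsupported test {self.test!r}")


def case_carrier_frequency(p_controls: float, odds_ratio: float) -> float:
    """Expected carrier frequency among cases given the control frequency
    and the carrier OR (odds transform; rare-disease RR surrogate)."""
    return odds_ratio * p_controls / (1.0 + p_controls * (odds_ratio - 1.0))


def one_stage_power(spec: PowerSpec) -> float:
    """Power of the two-sided two-proportion z test, clipped to [0, 1]."""
    p0 = spec.carrier_freq_controls
    p1 = case_carrier_frequency(p0, spec.effect)
    n1, n0 = spec.n_cases, spec.n_controls
    if spec.effect == 1.0 and spec.alpha == 0.0:
        raise ValueError("degenerate spec: null effect with zero significance level")
    pbar = (n1 * p1 + n0 * p0) / (n1 + n0)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    d = p1 - p0
    power = stats.norm.cdf((-z * se0 - d) / se1) + stats.norm.sf((z * se0 - d) / se1)
    return float(min(max(power, 0.0), 1.0))
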