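"""Synthetic two-locus carrier case-control cohorts.

The generator emulates the retrospective design the analysis assumes:
control stratum membership is multinomial over a specified joint carrier
frequency; case stratum probabilities are the control frequencies weighted
by the stratum odds ratios (reference weight 1) and renormalised, which
makes the expected stratum-vs-reference ORs equal the specified ones.
Carriers of the tag allele are emitted as GG or AG with equal probability
(the analysis only uses carrier status); non-carriers are AA. Severity
scores, when requested, are truncated-normal draws on the 0-10 instrument
scale per stratum. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import Carrier, Genotype, JointTable, Status, SubjectRecord, STRATUM_LABELS

#: per-stratum (mean, sd) for each score, strata in fixed order
SeverityMoments = Mapping[str, Sequence[tuple[float, float]]]


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for a synthetic cohort.

    ``control_joint_freq`` is over the fixed stratum order (B27+/B60+,
    B27+/B60-, B27-/B60+, B27-/B60-); ``stratum_ors`` is (OR11, OR10,
    OR01) versus the reference. ``prevalence`` is carried only for
    documentation and the power-calculation linkage; retrospective
    sampling never uses it.
    """

    n_cases: int
    n_controls: int
    control_joint_freq: tuple[float, float, float, float]
    stratum_ors: tuple[float, float, float]
    seed: int
    prevalence: float = 0.00167
    severity_moments: SeverityMoments | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.control_joint_freq, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("control_joint_freq must be 4 probabilities summing to 1")
        ors = np.asarray(self.stratum_ors, dtype=float)
        if ors.shape != (3,) or np.any(ors <= 0):
            raise ValueError("stratum_ors must be three positive odds ratios")
        if np.any((f[:3] == 0) & (ors != 1.0)):
            raise ValueError("a zero-frequency stratum cannot carry a non-unit OR weight")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both arms need at least one subject")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def case_joint_freq(self) -> np.ndarray:
        w = np.append(np.asarray(self.stratum_ors, dtype=float), 1.0)
        p = np.asarray(self.control_joint_freq, dtype=float) * w
        return p / p.sum()


def true_measures(spec: SimulationSpec) -> dict[str, float]:
    """The interaction measures implied by the generating stratum ORs."""
    or11, or10, or01 = spec.stratum_ors
    reri = or11 - or10 - or01 + 1.0
    return {
        "or11": or11, "or10": or10, "or01": or01,
        "reri": reri, "ap": reri / or11,
        "s": (or11 - 1.0) / ((or10 - 1.0) + (or01 - 1.0)),
    }


def simulate_table(spec: SimulationSpec, rng: np.random.Generator | None = None) -> JointTable:
    """Fast path: draw only the 2x2x2 stratum counts (no per-subject rows)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    cases = rng.multinomial(spec.n_cases, spec.case_joint_freq)
    controls = rng.multinomial(spec.n_controls, np.asarray(spec.control_joint_freq))
    return JointTable(cases.reshape(2, 2), controls.reshape(2, 2))


from functools import lru_cache


@lru_cache(maxsize=None)
def _match_truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (loc, scale) whose [0, 10]-truncated normal matches the
    target mean exactly and the target sd as closely as feasible.

    Naively truncating a normal with the target moments biases the
    realised mean away from the target whenever it sits within ~2 sd of a
    bound (severity instruments near 2 on a 0-10 scale shift up by ~0.7),
    so the parent parameters are solved for instead. The mean is always
    attainable (it is monotone in the parent location); the sd is capped
    by the shape family (CV <= ~1 near a bound), so it is minimised in
    absolute error rather than required.
    """
    from scipy.optimize import brentq, minimize_scalar

    def realised(loc: float, scale: float) -> tuple[float, float]:
        a, b = (0.0 - loc) / scale, (10.0 - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return float(m), float(np.sqrt(v))

    def loc_for_mean(scale: float) -> float:
        # realised mean is continuous and strictly increasing in loc with
        # range (0, 10); expand the bracket until it straddles the target
        lo, hi = -12.0 * scale, 10.0 + 12.0 * scale
        for _ in range(60):
            if realised(lo, scale)[0] < mean:
                break
            lo *= 2.0
        for _ in range(60):
            if realised(hi, scale)[0] > mean:
                break
            hi *= 2.0
        return brentq(lambda L: realised(L, scale)[0] - mean, lo, hi, xtol=1e-10)

    def sd_err(log_scale: float) -> float:
        scale = np.exp(log_scale)
        return abs(realised(loc_for_mean(scale), scale)[1] - sd)

    res = minimize_scalar(sd_err, bounds=(np.log(0.05), np.log(60.0)), method="bounded",
                          options={"xatol": 1e-8})
    scale = float(np.exp(res.x))
    return loc_for_mean(scale), scale


def _truncnorm_draws(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return np.full(size, min(max(mean, 0.0), 10.0))
    loc, scale = _match_truncnorm_params(mean, sd)
    a, b = (0.0 - loc) / scale, (10.0 - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def draw_severity(
    moments: SeverityMoments,
    strata: np.ndarray,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> dict[str, np.ndarray]:
    """Truncated-normal severity draws per stratum; optional
    missing-at-random mask (scores set to NaN)."""
    n = strata.size
    out: dict[str, np.ndarray] = {}
    for score, per_stratum in moments.items():
        col = np.empty(n)
        for s in range(4):
            idx = np.flatnonzero(strata == s)
            if idx.size:
                mean, sd = per_stratum[s]
                col[idx] = _truncnorm_draws(mean, sd, idx.size, rng)
        if missing_rate > 0.0:
            col[rng.random(n) < missing_rate] = np.nan
        out[score] = col
    return out


def simulate_cohort(spec: SimulationSpec) -> list[SubjectRecord]:
    """Draw a full synthetic cohort of :class:`SubjectRecord` objects.

    Severity scores are attached to cases only (the study design collects
    disease-activity instruments from patients) when
    ``spec.severity_moments`` is present.
    """
    rng = np.random.default_rng(spec.seed)
    case_strata = rng.choice(4, size=spec.n_cases, p=spec.case_joint_freq)
    ctrl_strata = rng.choice(4, size=spec.n_controls, p=np.asarray(spec.control_joint_freq))

    severity: dict[str, np.ndarray] = {}
    if spec.severity_moments is not None:
        severity = draw_severity(spec.severity_moments, case_strata, rng)

    records: list[SubjectRecord] = []
    for arm, strata, status in (
        ("case", case_strata, Status.CASE),
        ("ctrl", ctrl_strata, Status.CONTROL),
    ):
        # carriers split 50/50 between GG and AG; the analysis only uses carriership
        gg = rng.random(strata.size) < 0.5
        for i, s in enumerate(strata):
            b27_carrier = s in (0, 1)
            geno = (Genotype.GG if gg[i] else Genotype.AG) if b27_carrier else Genotype.AA
            b60 = Carrier.CARRIER if s in (0, 2) else Carrier.NONCARRIER
            kwargs = {}
            if status is Status.CASE and severity:
                for score, col in severity.items():
                    v = col[i]
                    kwargs[score] = None if np.isnan(v) else float(v)
            records.append(
                SubjectRecord(f"{arm}{i + 1:05d}", status, geno, b60, **kwargs)
            )
    return records


def load_severity_fixture() -> list[SubjectRecord]:
    """Read the synthetic severity cohort shipped with the package
    (the frozen output of :func:`make_severity_fixture` at seed 20150)."""
    from importlib import resources

    from .cohort import read_subjects

    with resources.as_file(
        resources.files("synergycc") / "data" / "synthetic_severity_cases.csv"
    ) as path:
        return read_subjects(path)


#: severity moments matching the published per-stratum means +/- SDs
STUDY_SEVERITY_MOMENTS: SeverityMoments = {
    "basdai": [(4.37, 2.20), (4.28, 2.16), (4.72, 1.61), (4.94, 2.58)],
    "basfi": [(2.17, 2.33), (2.02, 2.19), (1.64, 1.40), (2.60, 2.32)],
    "basg": [(4.17, 2.79), (4.30, 2.73), (3.65, 2.26), (4.91, 3.05)],
}

#: published per-stratum case counts with complete severity scores
STUDY_SEVERITY_GROUP_SIZES = (88, 334, 12, 25)


def make_severity_fixture(seed: int = 20150) -> list[SubjectRecord]:
    """Synthetic severity cohort with the published group sizes exactly.

    459 cases in fixed stratum order (88, 334, 12, 25), each with
    truncated-normal BASDAI/BASFI/BAS-G draws at the published moments.
    Group sizes are fixed, not sampled, so tabulated counts are exact.
    """
    rng = np.random.default_rng(seed)
    strata = np.repeat(np.arange(4), STUDY_SEVERITY_GROUP_SIZES)
    scores = draw_severity(STUDY_SEVERITY_MOMENTS, strata, rng)
    gg = rng.random(strata.size) < 0.5
    records = []
    for i, s in enumerate(strata):
        b27_carrier = s in (0, 1)
        geno = (Genotype.GG if gg[i] else Genotype.AG) if b27_carrier else Genotype.AA
        b60 = Carrier.CARRIER if s in (0, 2) else Carrier.NONCARRIER
        records.append(
            SubjectRecord(
                f"case{i + 1:05d}", Status.CASE, geno, b60,
                basdai=float(scores["basdai"][i]),
                basfi=float(scores["basfi"][i]),
                basg=float(scores["basg"][i]),
            )
        )
    return records
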