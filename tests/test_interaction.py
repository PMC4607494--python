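"""RERI / AP / synergy index: identities, delta intervals, bootstrap, coverage."""

import math

import numpy as np
import pytest
from scipy import stats

from synergycc.cohort import JointTable
from synergycc.interaction import (
    interaction_bootstrap,
    interaction_measures,
    measures_from_table,
)
from synergycc.logistic import fit_logistic


def _table_with_ors(or11, or10, or01, ref_cases=10, ctrl=100):
    """Controls uniform, reference cases fixed: empirical stratum ORs are
    exactly the requested integers."""
    cases = np.array([or11 * ref_cases, or10 * ref_cases, or01 * ref_cases, ref_cases])
    return JointTable(cases.reshape(2, 2), np.full((2, 2), ctrl))


class TestPointEstimatesAndIdentities:
    def test_published_interaction_block(self, study_table):
        m = measures_from_table(study_table)
        assert round(m.reri.value, 2) == 46.79
        assert round(m.ap.value, 2) == 0.23
        assert round(m.s.value, 2) == 1.31

    def test_published_delta_intervals(self, study_table):
        m = measures_from_table(study_table)
        assert (round(m.reri.ci_lower, 2), round(m.reri.ci_upper, 2)) == (-117.58, 211.16)
        assert (round(m.ap.ci_lower, 2), round(m.ap.ci_upper, 2)) == (-0.41, 0.88)
        assert (round(m.s.ci_lower, 2), round(m.s.ci_upper, 2)) == (0.56, 3.04)

    def test_direct_formula_arithmetic(self):
        m = measures_from_table(_table_with_ors(6, 2, 3))
        assert m.reri.value == pytest.approx(2.0, abs=1e-9)
        assert m.ap.value == pytest.approx(1 / 3, abs=1e-9)
        assert m.s.value == pytest.approx(5 / 3, abs=1e-9)

    def test_additive_null_gives_null_values(self):
        m = measures_from_table(_table_with_ors(4, 2, 3))
        assert m.reri.value == pytest.approx(0.0, abs=1e-9)
        assert m.ap.value == pytest.approx(0.0, abs=1e-9)
        assert m.s.value == pytest.approx(1.0, abs=1e-9)

    def test_algebraic_identities_hold_on_random_tables(self):
        import warnings

        rng = np.random.default_rng(5)
        for _ in range(30):
            t = JointTable(rng.integers(5, 80, (2, 2)), rng.integers(5, 80, (2, 2)))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)  # protective draws
                    m = measures_from_table(t)
            except ValueError:  # S undefined for this draw
                continue
            assert m.reri.value == pytest.approx(
                m.or11 - m.or10 - m.or01 + 1, abs=1e-12 * max(1, abs(m.or11))
            )
            assert m.ap.value == pytest.approx(m.reri.value / m.or11, abs=1e-12)
            assert m.s.value == pytest.approx(
                (m.or11 - 1) / ((m.or10 - 1) + (m.or01 - 1)), abs=1e-12
            )

    def test_s_undefined_raises_with_diagnostic(self):
        t = JointTable(np.array([[10, 10], [10, 40]]), np.full((2, 2), 40))
        with pytest.raises(ValueError, match="synergy index undefined"):
            measures_from_table(t)

    def test_requires_saturated_converged_fit(self, study_table):
        with pytest.raises(ValueError, match="saturated"):
            interaction_measures(fit_logistic(study_table, "main_effects"))


class TestDeltaIntervalGeometry:
    def test_reri_and_ap_intervals_symmetric_natural_scale(self, study_table):
        m = measures_from_table(study_table)
        assert m.reri.ci_upper - m.reri.value == pytest.approx(
            m.reri.value - m.reri.ci_lower, abs=1e-9
        )
        assert m.ap.ci_upper - m.ap.value == pytest.approx(
            m.ap.value - m.ap.ci_lower, abs=1e-9
        )

    def test_s_interval_log_symmetric(self, study_table):
        m = measures_from_table(study_table)
        assert math.log(m.s.ci_upper) - math.log(m.s.value) == pytest.approx(
            math.log(m.s.value) - math.log(m.s.ci_lower), abs=1e-9
        )

    def test_scaling_leaves_points_and_shrinks_widths_by_sqrt_k(self, study_table):
        m1 = measures_from_table(study_table)
        m4 = measures_from_table(study_table.scale(4))
        assert m4.reri.value == pytest.approx(m1.reri.value, rel=1e-9)
        w1 = m1.reri.ci_upper - m1.reri.ci_lower
        w4 = m4.reri.ci_upper - m4.reri.ci_lower
        assert w4 == pytest.approx(w1 / 2, rel=1e-9)  # delta variance scales 1/k


class TestBootstrap:
    def test_percentile_ci_overlaps_delta_ci_on_published_table(self, study_table):
        # a handful of replicates draw a zero reference-stratum cell and are excluded
        with pytest.warns(UserWarning, match="excluded"):
            boot = interaction_bootstrap(study_table, n_boot=10_000, seed=2024)
        delta = measures_from_table(study_table)
        for key in ("reri", "ap", "s"):
            b, d = getattr(boot, key), getattr(delta, key)
            assert b.ci_lower < d.ci_upper and d.ci_lower < b.ci_upper  # overlap
            assert b.ci_lower <= b.value <= b.ci_upper
        # same order of magnitude of uncertainty (the bootstrap is skew-aware)
        ratio = (boot.reri.ci_upper - boot.reri.ci_lower) / (
            delta.reri.ci_upper - delta.reri.ci_lower
        )
        assert 0.4 < ratio < 2.5

    def test_seed_reproducibility(self, study_table):
        with pytest.warns(UserWarning, match="excluded"):
            a = interaction_bootstrap(study_table, n_boot=2000, seed=99)
        with pytest.warns(UserWarning, match="excluded"):
            b = interaction_bootstrap(study_table, n_boot=2000, seed=99)
        assert a.reri.ci_lower == b.reri.ci_lower and a.s.ci_upper == b.s.ci_upper

    def test_large_balanced_null_table_covers_zero(self):
        boot = interaction_bootstrap(_table_with_ors(4, 2, 3, ref_cases=50, ctrl=500),
                                     n_boot=4000, seed=12)
        assert boot.reri.ci_lower < 0 < boot.reri.ci_upper

    def test_empty_stratum_rejected(self):
        t = JointTable(np.array([[0, 5], [5, 5]]), np.full((2, 2), 5))
        with pytest.raises(ValueError, match="empty"):
            interaction_bootstrap(t, n_boot=100, seed=1)

    def test_unstable_table_rejected(self):
        t = JointTable(np.ones((2, 2), dtype=int), np.ones((2, 2), dtype=int))
        with pytest.raises(RuntimeError, match="undefined"):
            interaction_bootstrap(t, n_boot=200, seed=1)

    def test_seed_mandatory(self, study_table):
        with pytest.raises(ValueError, match="seed"):
            interaction_bootstrap(study_table, n_boot=10, seed=None)


def _vectorised_reri_delta_ci(case_draws, ctrl_draws, level=0.95):
    """Closed-form saturated-model RERI and delta CI per replicate
    (rows with any zero cell yield NaN)."""
    a, b = case_draws.astype(float), ctrl_draws.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ors = (a[:, :3] * b[:, 3:4]) / (a[:, 3:4] * b[:, :3])
        or11, or10, or01 = ors[:, 0], ors[:, 1], ors[:, 2]
        reri = or11 - or10 - or01 + 1
        inv = 1 / a + 1 / b
        var11 = inv[:, 0] + inv[:, 3]
        var10 = inv[:, 1] + inv[:, 3]
        var01 = inv[:, 2] + inv[:, 3]
        cov = inv[:, 3]
        g = np.stack([or11, -or10, -or01], axis=1)
        var = (
            g[:, 0] ** 2 * var11 + g[:, 1] ** 2 * var10 + g[:, 2] ** 2 * var01
            + 2 * cov * (g[:, 0] * g[:, 1] + g[:, 0] * g[:, 2] + g[:, 1] * g[:, 2])
        )
    se = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2)
    bad = ~np.isfinite(reri) | ~np.isfinite(se)
    return reri, reri - z * se, reri + z * se, bad


def test_reri_delta_ci_coverage_at_study_scale(study_table):
    """Over 600 cohorts drawn at the study's sample sizes and stratum
    frequencies, the 95% delta CI for RERI covers the generating RERI in
    90-98% of defined replicates."""
    rng = np.random.default_rng(314)
    n_rep = 600
    pc = study_table.cases / study_table.n_cases
    pk = study_table.controls / study_table.n_controls
    ors_true = [(study_table.cases[s] * study_table.controls[3])
                / (study_table.cases[3] * study_table.controls[s]) for s in (0, 1, 2)]
    reri_true = ors_true[0] - ors_true[1] - ors_true[2] + 1
    cases = rng.multinomial(study_table.n_cases, pc, size=n_rep)
    ctrls = rng.multinomial(study_table.n_controls, pk, size=n_rep)
    _, lo, hi, bad = _vectorised_reri_delta_ci(cases, ctrls)
    ok = ~bad
    cover = np.mean((lo[ok] <= reri_true) & (reri_true <= hi[ok]))
    assert ok.sum() >= 500
    assert 0.90 <= cover <= 0.98
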