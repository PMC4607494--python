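"""Synthetic cohort generator: determinism, parameter recovery, coverage."""

import warnings

import numpy as np
import pytest
from scipy import stats

from synergycc.cohort import Carrier, Genotype, Status, read_subjects, tabulate, write_subjects
from synergycc.interaction import measures_from_table
from synergycc.simulate import (
    STUDY_SEVERITY_MOMENTS,
    SimulationSpec,
    draw_severity,
    simulate_cohort,
    simulate_table,
    true_measures,
)

STUDY_CONTROL_FREQ = (7 / 557, 36 / 557, 66 / 557, 448 / 557)
STUDY_ORS = (201.14285714285714, 152.44444444444446, 2.909090909090909)


def _study_spec(scale=1, seed=0, **kw):
    return SimulationSpec(
        n_cases=471 * scale,
        n_controls=557 * scale,
        control_joint_freq=STUDY_CONTROL_FREQ,
        stratum_ors=STUDY_ORS,
        seed=seed,
        **kw,
    )


class TestSpecValidation:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="summing to 1"):
            SimulationSpec(10, 10, (0.3, 0.3, 0.3, 0.3), (1, 1, 1), seed=0)

    def test_zero_frequency_stratum_with_or_weight_rejected(self):
        with pytest.raises(ValueError, match="zero-frequency"):
            SimulationSpec(10, 10, (0.0, 0.4, 0.3, 0.3), (2.0, 1.0, 1.0), seed=0)

    def test_case_distribution_is_or_weighted_renormalisation(self):
        spec = SimulationSpec(10, 10, (0.1, 0.2, 0.3, 0.4), (5, 2, 3), seed=0)
        w = np.array([0.1 * 5, 0.2 * 2, 0.3 * 3, 0.4])
        assert spec.case_joint_freq == pytest.approx(w / w.sum())

    def test_true_measures_follow_the_generating_ors(self):
        tm = true_measures(_study_spec())
        # exact fractions: 1408/7 - 1372/9 - 32/11 + 1
        assert tm["reri"] == pytest.approx(1408 / 7 - 1372 / 9 - 32 / 11 + 1, rel=1e-12)
        assert tm["ap"] == pytest.approx(tm["reri"] / STUDY_ORS[0])


class TestDeterminismAndFormat:
    def test_same_seed_gives_byte_identical_csv(self, tmp_path):
        spec = _study_spec(seed=21)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_subjects(simulate_cohort(spec), p1)
        write_subjects(simulate_cohort(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_emitted_csv_parses_without_warnings_and_recounts(self, tmp_path):
        spec = _study_spec(seed=8)
        records = simulate_cohort(spec)
        path = tmp_path / "cohort.csv"
        write_subjects(records, path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            back = read_subjects(path)
        table = tabulate(back)
        # independent hand count of the emitted file
        import csv

        counts = {(s, g, b): 0 for s in ("case", "control")
                  for g in ("AA", "AG", "GG") for b in ("carrier", "noncarrier")}
        with open(path) as fh:
            for row in csv.DictReader(fh):
                counts[(row["status"], row["rs13202464"], row["hla_b60"])] += 1

        def cell(status, b27, b60):
            genos = ("AG", "GG") if b27 else ("AA",)
            return sum(counts[(status, g, b60)] for g in genos)

        assert table.cases.tolist() == [
            cell("case", True, "carrier"), cell("case", True, "noncarrier"),
            cell("case", False, "carrier"), cell("case", False, "noncarrier"),
        ]
        assert table.controls.tolist() == [
            cell("control", True, "carrier"), cell("control", True, "noncarrier"),
            cell("control", False, "carrier"), cell("control", False, "noncarrier"),
        ]

    def test_carriers_get_gg_or_ag_noncarriers_aa(self):
        records = simulate_cohort(_study_spec(seed=3))
        genos_carrier = {r.rs13202464 for r in records if r.b27 is Carrier.CARRIER}
        genos_non = {r.rs13202464 for r in records if r.b27 is Carrier.NONCARRIER}
        assert genos_carrier == {Genotype.AG, Genotype.GG}
        assert genos_non == {Genotype.AA}


class TestParameterRecovery:
    def test_null_spec_recovers_unit_ors(self):
        from synergycc.logistic import stratum_logor_covariance

        spec = SimulationSpec(20_000, 20_000, (0.1, 0.2, 0.3, 0.4), (1.0, 1.0, 1.0),
                              seed=17)
        t = simulate_table(spec)
        a, b = t.cases.astype(float), t.controls.astype(float)
        V = stratum_logor_covariance(t)
        for i, s in enumerate((0, 1, 2)):
            logor = np.log((a[s] * b[3]) / (a[3] * b[s]))
            assert abs(logor) < 3 * np.sqrt(V[i, i])

    def test_study_scale_x100_recovers_generating_ors(self):
        """At 100x the study's sample sizes the estimated stratum ORs land
        within 10% of the generating values and RERI within its delta CI."""
        spec = _study_spec(scale=100, seed=1234)
        t = simulate_table(spec)
        m = measures_from_table(t)
        for est, true in zip((m.or11, m.or10, m.or01), STUDY_ORS):
            assert abs(est - true) / true < 0.10
        tm = true_measures(spec)
        assert m.reri.ci_lower <= tm["reri"] <= m.reri.ci_upper

    def test_log_or_consistency_over_replicates(self):
        """Mean estimated log OR per stratum over 200 replicates at 10x
        scale is within 2 Monte-Carlo SEs of the generating log ORs after
        allowing for the estimator's first-order small-sample bias
        (E[log X] = log mu - 1/(2 mu) + O(mu^-2) per cell); the bias
        vanishes as n grows but is not negligible against the Monte-Carlo
        SE at this replicate count."""
        rng = np.random.default_rng(55)
        spec = _study_spec(scale=10, seed=0)
        logors = []
        for _ in range(200):
            t = simulate_table(spec, rng=rng)
            a, b = t.cases.astype(float), t.controls.astype(float)
            if np.any(a == 0) or np.any(b == 0):
                continue
            logors.append([np.log((a[s] * b[3]) / (a[3] * b[s])) for s in (0, 1, 2)])
        logors = np.array(logors)
        mean = logors.mean(axis=0)
        mc_se = logors.std(axis=0, ddof=1) / np.sqrt(len(logors))
        mu_case = spec.case_joint_freq * spec.n_cases
        mu_ctrl = np.asarray(spec.control_joint_freq) * spec.n_controls
        for i, (m_est, se, true) in enumerate(zip(mean, mc_se, np.log(STUDY_ORS))):
            bias_bound = 0.5 * (1 / mu_case[i] + 1 / mu_case[3]
                                + 1 / mu_ctrl[i] + 1 / mu_ctrl[3])
            assert abs(m_est - true) <= 2 * se + bias_bound


def test_additive_null_reri_delta_coverage():
    """Under an additive-null generator (OR11 = OR10 + OR01 - 1) the 95%
    delta CI for RERI covers 0 in 93-97% of 600 replicates."""
    from tests.test_interaction import _vectorised_reri_delta_ci

    spec = SimulationSpec(2000, 2000, (0.06, 0.16, 0.14, 0.64), (4.0, 2.0, 3.0),
                          seed=0)
    rng = np.random.default_rng(77)
    n_rep = 600
    cases = rng.multinomial(spec.n_cases, spec.case_joint_freq, size=n_rep)
    ctrls = rng.multinomial(spec.n_controls, np.asarray(spec.control_joint_freq),
                            size=n_rep)
    _, lo, hi, bad = _vectorised_reri_delta_ci(cases, ctrls)
    ok = ~bad
    assert ok.sum() >= 500
    cover = np.mean((lo[ok] <= 0.0) & (0.0 <= hi[ok]))
    assert 0.93 <= cover <= 0.97


class TestSeverity:
    def test_zero_sd_gives_constant_scores(self):
        rng = np.random.default_rng(0)
        out = draw_severity({"basdai": [(4.0, 0.0)] * 4}, np.array([0, 1, 2, 3]), rng)
        assert out["basdai"] == pytest.approx([4.0] * 4)

    def test_moments_recovered_at_large_n(self):
        """Per-stratum sample means at ~100x the study group sizes land
        within 3 SE of the specified means."""
        rng = np.random.default_rng(9)
        sizes = np.array([88, 334, 12, 25]) * 100
        strata = np.repeat(np.arange(4), sizes)
        out = draw_severity(STUDY_SEVERITY_MOMENTS, strata, rng)
        for score, moms in STUDY_SEVERITY_MOMENTS.items():
            for s, (mu, sd) in enumerate(moms):
                x = out[score][strata == s]
                assert abs(x.mean() - mu) <= 3 * sd / np.sqrt(x.size)

    def test_missing_at_random_mask(self):
        rng = np.random.default_rng(4)
        strata = np.zeros(5000, dtype=int)
        out = draw_severity({"basfi": [(2.0, 1.0)] * 4}, strata, rng, missing_rate=0.1)
        frac = np.mean(np.isnan(out["basfi"]))
        assert 0.07 < frac < 0.13

    def test_severity_seed_determinism(self):
        spec = _study_spec(seed=31, severity_moments=STUDY_SEVERITY_MOMENTS)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        assert all(x.basdai == y.basdai for x, y in zip(a, b)
                   if x.status is Status.CASE)

    def test_scores_respect_instrument_bounds(self):
        rng = np.random.default_rng(6)
        out = draw_severity(STUDY_SEVERITY_MOMENTS, np.repeat(np.arange(4), 500), rng)
        for col in out.values():
            assert np.all((col >= 0) & (col <= 10))
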