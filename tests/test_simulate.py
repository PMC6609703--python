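"""Shared-frailty competing-risks simulator: determinism, analytic
oracles, calibration, and the dependence mechanism."""

import numpy as np
import pytest

from cifbias import (
    CauseCategory,
    SimConfig,
    aalen_johansen,
    analytic_cif,
    build_bias_report,
    cause_fraction,
    load_preset,
    naive_analytic_cif,
    simulate_cohort,
    summarize_cohort,
)

C = CauseCategory

EQUAL_HAZARDS = {
    C.CANCER: 0.01, C.CVD: 0.01, C.OTHER_NATURAL: 0.005, C.EXTERNAL: 0.005,
}


def config(**kw):
    defaults = dict(n=100, hazards=EQUAL_HAZARDS, censor_time=55.0, seed=42)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestAnalyticOracles:
    def test_single_cause_long_horizon(self):
        assert analytic_cif({C.CANCER: 0.02}, C.CANCER, 1e6) == pytest.approx(1.0)

    def test_two_equal_hazards(self):
        hz = {C.CANCER: 0.01, C.CVD: 0.01}
        assert analytic_cif(hz, C.CANCER, 55.0) == pytest.approx(
            0.5 * (1 - np.exp(-1.1))
        )
        assert naive_analytic_cif(hz, C.CANCER, 55.0) == pytest.approx(
            1 - np.exp(-0.55)
        )
        # marginal (naive) exceeds the true cumulative incidence
        assert naive_analytic_cif(hz, C.CANCER, 55.0) > analytic_cif(hz, C.CANCER, 55.0)

    def test_zero_time_and_zero_total(self):
        assert analytic_cif(EQUAL_HAZARDS, C.CVD, 0.0) == 0.0
        assert analytic_cif({C.CVD: 0.0}, C.CVD, 10.0) == 0.0

    def test_cause_fraction_symmetry(self):
        hz = {c: 0.01 for c in (C.CANCER, C.CVD, C.OTHER_NATURAL, C.EXTERNAL)}
        fr = cause_fraction(hz, 500.0)
        for v in fr.values():
            assert v == pytest.approx(0.25, abs=1e-6)
        assert cause_fraction({**hz, C.CVD: 0.0}, 55.0)[C.CVD] == 0.0

    def test_cause_fraction_against_quadrature(self):
        """CIF_j(tau) = integral of lambda_j exp(-L t) dt, checked numerically."""
        from scipy.integrate import quad

        hz = {C.CANCER: 0.004, C.CVD: 0.002, C.OTHER_NATURAL: 0.0015, C.EXTERNAL: 0.005}
        total = sum(hz.values())
        fr = cause_fraction(hz, 55.0)
        for cause, lam in hz.items():
            expected, _ = quad(lambda t: lam * np.exp(-total * t), 0.0, 55.0)
            assert fr[cause] == pytest.approx(expected, abs=1e-10)


class TestSimulateCohort:
    def test_same_seed_identical(self):
        assert simulate_cohort(config()) == simulate_cohort(config())

    def test_different_seed_differs(self):
        assert simulate_cohort(config(seed=1)) != simulate_cohort(config(seed=2))

    def test_all_hazards_zero_all_censored(self):
        cfg = config(hazards={c: 0.0 for c in EQUAL_HAZARDS}, censor_time=30.0)
        cohort = simulate_cohort(cfg)
        assert all(not r.event and r.time_years == 30.0 for r in cohort)

    def test_negative_frailty_variance_rejected(self):
        with pytest.raises(ValueError, match="frailty"):
            config(frailty_variance=-0.5)

    def test_death_fractions_match_analytic(self):
        cfg = config(n=5000, seed=3)
        s = summarize_cohort(simulate_cohort(cfg))
        fr = cause_fraction(EQUAL_HAZARDS, 55.0)
        for cause, p in fr.items():
            observed = s.deaths_by_cause[cause]
            se = np.sqrt(p * (1 - p) * cfg.n)
            assert abs(observed - p * cfg.n) < 3 * se

    def test_total_hazard_recovery(self):
        """deaths / person-years estimates the configured total hazard."""
        cfg = config(n=20_000, censor_time=30.0, seed=11)
        s = summarize_cohort(simulate_cohort(cfg))
        total = sum(EQUAL_HAZARDS.values())
        est = s.total_deaths / s.total_person_years
        se = np.sqrt(s.total_deaths) / s.total_person_years
        assert abs(est - total) < 3 * se

    def test_frailty_survival_matches_laplace_transform(self):
        """Under gamma frailty on the dependent causes, overall survival has
        the closed form S(t) = exp(-Li t) (1 + theta Ld t)^(-1/theta) with
        Ld / Li the dependent / independent total hazards."""
        theta, t_check = 1.0, 30.0
        cfg = config(n=20_000, seed=13, frailty_variance=theta)
        cohort = simulate_cohort(cfg)
        ld = sum(v for c, v in EQUAL_HAZARDS.items() if c in cfg.dependent_causes)
        li = sum(v for c, v in EQUAL_HAZARDS.items() if c not in cfg.dependent_causes)
        expected = np.exp(-li * t_check) * (1 + theta * ld * t_check) ** (-1 / theta)
        alive = np.mean([r.time_years > t_check for r in cohort])
        se = np.sqrt(expected * (1 - expected) / cfg.n)
        assert abs(alive - expected) < 3 * se

    def test_frailty_cause_fractions_match_quadrature(self):
        """Per-cause death probabilities under gamma frailty, against exact
        quadrature of the population-level sub-density; mean-1 frailty keeps
        the frailty-independent causes calibrated and shrinks the dependent
        ones only by the second-order selection attenuation."""
        from scipy.integrate import quad

        theta, horizon = 1.0, 55.0
        cfg = config(n=20_000, seed=17, frailty_variance=theta)
        s = summarize_cohort(simulate_cohort(cfg))
        ld = sum(v for c, v in EQUAL_HAZARDS.items() if c in cfg.dependent_causes)
        li = sum(v for c, v in EQUAL_HAZARDS.items() if c not in cfg.dependent_causes)
        for cause, lam in EQUAL_HAZARDS.items():
            if cause in cfg.dependent_causes:
                # E[Z exp(-Z Ld t)] = (1 + theta Ld t)^-(1/theta + 1)
                f = lambda t: lam * (1 + theta * ld * t) ** -(1 / theta + 1) * np.exp(-li * t)
            else:
                f = lambda t: lam * np.exp(-li * t) * (1 + theta * ld * t) ** (-1 / theta)
            p, _ = quad(f, 0.0, horizon)
            se = np.sqrt(p * (1 - p) * cfg.n)
            assert abs(s.deaths_by_cause[cause] - p * cfg.n) < 3 * se

    def test_estimated_cif_matches_analytic_at_horizon(self):
        cfg = config(n=10_000, seed=8)
        cs = aalen_johansen(simulate_cohort(cfg))
        for cause in (C.CANCER, C.EXTERNAL):
            p = analytic_cif(EQUAL_HAZARDS, cause, 55.0)
            se = np.sqrt(p * (1 - p) / cfg.n)
            est = cs.cif_by_cause[cause].value_at(54.999)
            assert abs(est - p) < 3 * se


class TestPresets:
    @pytest.mark.parametrize(
        "name, n, deaths, mean_fu",
        [("astronaut_like", 301, 53, 24.2), ("cosmonaut_like", 117, 36, 25.4)],
    )
    def test_preset_calibration(self, name, n, deaths, mean_fu):
        """Across replicates the presets reproduce the target cohort size,
        expected death count and mean follow-up."""
        cfg = load_preset(name)
        assert cfg.n == n
        reps = 100
        totals, fus = [], []
        for seed in range(reps):
            s = summarize_cohort(simulate_cohort(load_preset(name, seed=seed)))
            totals.append(s.total_deaths)
            fus.append(s.mean_follow_up)
        se_deaths = np.std(totals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(totals) - deaths) < 3 * se_deaths + 0.5
        assert np.mean(fus) == pytest.approx(mean_fu, abs=0.5)

    def test_preset_seed_override(self):
        a = load_preset("astronaut_like", seed=1)
        assert a.seed == 1 and a.frailty_variance == 0.0

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            load_preset("mars_colonist_like")

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = dict(
            label="y", n=50,
            hazards={"cancer": 0.01, "cvd": 0.02, "other_natural": 0.0, "external": 0.005},
            censor_time=[5.0, 30.0], frailty_variance=0.5, seed=9,
        )
        p = tmp_path / "sim.yaml"
        p.write_text(yaml.safe_dump(cfg))
        loaded = SimConfig.from_yaml(p)
        assert loaded.n == 50
        assert loaded.censor_time == (5.0, 30.0)
        assert loaded.hazards[C.CVD] == 0.02


class TestDependenceSignature:
    def test_frailty_shifts_dependent_cause_deaths_early(self):
        """The observable signature of the shared frailty: high-frailty
        subjects die early of the dependent causes, so the cancer+CVD share
        of deaths declines from the early to the late half of the death-time
        distribution; under independence the share is flat."""

        def share_by_half(theta):
            cohort = simulate_cohort(config(n=20_000, seed=7, frailty_variance=theta))
            deaths = sorted((r.time_years, r.cause) for r in cohort if r.event)
            half = len(deaths) // 2
            dep = lambda rows: np.mean([c in (C.CANCER, C.CVD) for _, c in rows])
            return dep(deaths[:half]), dep(deaths[half:])

        early0, late0 = share_by_half(0.0)
        early2, late2 = share_by_half(2.0)
        assert abs(early0 - late0) < 0.05
        assert late2 < early2 - 0.05

    def test_frailty_selection_raises_auc_ratios(self):
        """Frailty selection attenuates the observed hazards of the
        dependent causes, lowering total mortality over the window and
        pulling both cancer and CVD AUC ratios toward 1 relative to the
        matched independent configuration."""
        r0 = build_bias_report(simulate_cohort(config(n=5000, seed=0)))
        r2 = build_bias_report(
            simulate_cohort(config(n=5000, seed=0, frailty_variance=2.0))
        )
        for cause in (C.CANCER, C.CVD):
            assert r2.record_for(cause).ratio > r0.record_for(cause).ratio
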