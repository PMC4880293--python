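"""Maximum-likelihood estimation of pi(0) and the efficiency functions."""

import numpy as np
import pytest
from sklearn.base import clone

from dyadhmm import (
    DyadMethylationHMM,
    EfficiencyEstimator,
    EfficiencyModel,
    InitialDistributionEstimator,
    SimulationConfig,
    generate_dataset,
    predict_timecourse,
)
from dyadhmm.likelihood import neg_log_likelihood_dynamics
from conftest import STATE_INDEX, make_dataset, point_mass


class TestInitialDistribution:
    def test_unique_ideal_preimage_hh(self):
        """BS all CC + oxBS all TT is only explained by a pure (hh) population."""
        data = make_dataset({(0, "bs"): [0, 0, 0, 200], (0, "ox"): [200, 0, 0, 0]})
        est = InitialDistributionEstimator(n_starts=10, random_state=0).fit(data)
        assert est.pi0_[STATE_INDEX["hh"]] == pytest.approx(1.0, abs=1e-4)

    def test_unique_ideal_preimage_uu(self):
        data = make_dataset({(0, "bs"): [200, 0, 0, 0], (0, "ox"): [200, 0, 0, 0]})
        est = InitialDistributionEstimator(n_starts=10, random_state=0).fit(data)
        assert est.pi0_[STATE_INDEX["uu"]] == pytest.approx(1.0, abs=1e-4)

    def test_recovery_from_deep_day0_counts(self):
        """A 5hmC-free symmetric pi(0) is recovered within 0.02 per entry.

        Day-0 counts constrain fewer degrees of freedom than the simplex
        has, leaving one exactly flat likelihood ridge under strand
        symmetry; a hydroxylation-free baseline pins that ridge at the
        simplex boundary, making every entry identifiable.
        """
        pi0 = np.array([0.2, 0.1, 0.1, 0.0, 0.0, 0.6, 0.0, 0.0, 0.0])
        cfg = SimulationConfig(coverage=100_000, days=(0,), seed=3, pi0=pi0,
                               model=EfficiencyModel())
        data, truth = generate_dataset(cfg)
        est = InitialDistributionEstimator(n_starts=20, symmetric=True,
                                           random_state=1).fit(data)
        np.testing.assert_allclose(est.pi0_, pi0, atol=0.02)

    def test_observable_projection_identified_despite_ridge(self):
        """With 5hmC present only the emission image of pi(0) is identified.

        The fitted pi(0) may drift along the flat ridge, but its implied
        day-0 read-pair distributions must match the truth closely.
        """
        from dyadhmm import observable_distribution

        cfg = SimulationConfig(coverage=100_000, days=(0,), seed=3,
                               model=EfficiencyModel())
        data, _ = generate_dataset(cfg)
        est = InitialDistributionEstimator(n_starts=20, symmetric=True,
                                           random_state=1).fit(data)
        for tr in ("bs", "ox"):
            prof = cfg.profiles[(0, tr)]
            np.testing.assert_allclose(
                observable_distribution(est.pi0_, prof),
                observable_distribution(cfg.pi0, prof), atol=0.01)

    def test_reports_multistart_spread(self, day0_dataset):
        est = InitialDistributionEstimator(n_starts=12, random_state=0).fit(day0_dataset)
        assert est.spread_ >= 0.0
        assert len(est.optima_) == est.n_converged_ >= 1

    def test_sklearn_protocol(self):
        est = InitialDistributionEstimator(n_starts=5, symmetric=True)
        assert clone(est).get_params()["symmetric"] is True


@pytest.fixture(scope="module")
def sloped_dataset():
    cfg = SimulationConfig(seed=11)
    data, truth = generate_dataset(cfg)
    return data, cfg


class TestEfficiencyEstimator:
    def test_requires_pi0(self, sloped_dataset):
        data, _ = sloped_dataset
        with pytest.raises(ValueError, match="pi0"):
            EfficiencyEstimator(n_starts=2).fit(data)

    def test_recovers_generating_parameters(self, sloped_dataset):
        data, cfg = sloped_dataset
        est = EfficiencyEstimator(n_starts=6, random_state=0).fit(data, pi0=cfg.pi0)
        truth = cfg.model.to_array()
        np.testing.assert_allclose(est.v_[:6], truth[:6], atol=0.05)
        assert est.v_[6] > 0.8  # p near its true boundary value 1

    def test_optimum_dominates_every_start(self, sloped_dataset):
        """The selected optimum is no worse than the objective at any start point."""
        data, cfg = sloped_dataset
        est = EfficiencyEstimator(n_starts=6, random_state=4).fit(data, pi0=cfg.pi0)
        for v0 in est.start_points_:
            start_nll = neg_log_likelihood_dynamics(
                EfficiencyModel.from_array(v0), cfg.pi0, data)
            assert est.nll_ <= start_nll + 1e-9

    def test_more_starts_never_hurt(self, sloped_dataset):
        data, cfg = sloped_dataset
        one = EfficiencyEstimator(n_starts=1, random_state=5).fit(data, pi0=cfg.pi0)
        many = EfficiencyEstimator(n_starts=8, random_state=5).fit(data, pi0=cfg.pi0)
        assert many.nll_ <= one.nll_ + 1e-6

    def test_null_hydroxylation_recovered(self):
        model = EfficiencyModel(mu_m_intercept=0.8, mu_d_intercept=0.2, p=0.0)
        cfg = SimulationConfig(model=model, seed=21)
        data, _ = generate_dataset(cfg)
        est = EfficiencyEstimator(n_starts=6, random_state=0).fit(data, pi0=cfg.pi0)
        for t in (1, 3, 6):
            assert est.model_.eta(t) <= 0.02

    def test_stable_fully_methylated_locus_keeps_total_efficiency_one(self):
        """An imprinted-gene-like locus keeps lambda(t) at 1 (Snrpn behaviour).

        With essentially no unmethylated dyads in the pool, only the total
        hemimethylation efficiency lambda = mu_m + mu_d - mu_m*mu_d is
        identified ((1-mu_m)(1-mu_d) is what the data pins down); stable
        full methylation forces it to 1 at every division.
        """
        model = EfficiencyModel(mu_m_intercept=1.0, mu_d_intercept=0.0, p=0.0)
        pi0 = point_mass("mm")
        cfg = SimulationConfig(model=model, pi0=pi0, seed=22)
        data, _ = generate_dataset(cfg)
        est = EfficiencyEstimator(n_starts=6, random_state=0).fit(data, pi0=pi0)
        for t in (1, 3, 6):
            assert est.model_.lam(t) == pytest.approx(1.0, abs=0.02)
            assert est.model_.mu_m(t) > 0.9

    def test_constant_model_fixes_slopes(self, sloped_dataset):
        data, cfg = sloped_dataset
        est = EfficiencyEstimator(n_starts=4, constant=True,
                                  random_state=0).fit(data, pi0=cfg.pi0)
        assert est.model_.mu_m_slope == est.model_.mu_d_slope == est.model_.eta_slope == 0.0
        assert "mu_m_slope" not in est.free_names_

    def test_sd_shrinks_with_root_coverage(self):
        """Quadrupling the coverage roughly halves the standard deviations."""
        model = EfficiencyModel(mu_m_intercept=0.7, mu_d_intercept=0.2,
                                eta_intercept=0.1, eta_slope=0.02, p=1.0)
        sds = {}
        for cov in (2_500, 10_000):
            cfg = SimulationConfig(model=model, coverage=cov, seed=9)
            data, _ = generate_dataset(cfg)
            est = EfficiencyEstimator(n_starts=6, random_state=1).fit(data, pi0=cfg.pi0)
            sds[cov] = np.array([est.sd_[n] for n in
                                 ("mu_m_intercept", "mu_d_intercept", "eta_slope")])
        ratio = sds[2_500] / sds[10_000]
        assert np.all(ratio > 1.4) and np.all(ratio < 2.9)

    def test_boundary_parameter_flagged_and_ci_truncated(self, sloped_dataset):
        data, cfg = sloped_dataset
        est = EfficiencyEstimator(n_starts=6, random_state=0).fit(data, pi0=cfg.pi0)
        if est.boundary_flags_["p"]:
            lo, hi = est.ci_["p"]
            assert 0.0 <= lo <= hi <= 1.0

    def test_sklearn_protocol(self):
        est = EfficiencyEstimator(n_starts=3, constant=True)
        params = clone(est).get_params()
        assert params["n_starts"] == 3 and params["constant"] is True


class TestDyadMethylationHMM:
    def test_two_stage_fit_and_prediction(self, sloped_dataset):
        data, cfg = sloped_dataset
        est = DyadMethylationHMM(n_starts=6, symmetric_initial=True,
                                 random_state=2).fit(data)
        tc = est.predict_timecourse()
        assert list(tc["day"]) == [0, 1, 3, 6]
        # day 0 summaries are pi(0) itself
        assert tc.loc[0, "fully_methylated"] == pytest.approx(
            est.pi0_[STATE_INDEX["mm"]])
        # complement identity for total hydroxylation
        unhydrox = tc[["pi_uu", "pi_um", "pi_mu", "pi_mm"]].sum(axis=1)
        np.testing.assert_allclose(tc["total_hydroxylated"], 1 - unhydrox, atol=1e-12)
        # lambda column reproduces mu_m + mu_d - mu_m*mu_d
        m = est.model_
        for _, row in tc[tc["day"] > 0].iterrows():
            t = row["divisions"]
            assert row["lambda"] == pytest.approx(
                m.mu_m(t) + m.mu_d(t) - m.mu_m(t) * m.mu_d(t), abs=1e-12)

    def test_stationary_fully_methylated_prediction(self):
        model = EfficiencyModel(mu_m_intercept=1.0)
        tc = predict_timecourse(model, point_mass("mm"), days=range(7))
        np.testing.assert_allclose(tc["fully_methylated"], 1.0, atol=1e-12)

    def test_reproducible_under_fixed_seed(self, sloped_dataset):
        data, _ = sloped_dataset
        a = DyadMethylationHMM(n_starts=3, random_state=7).fit(data)
        b = DyadMethylationHMM(n_starts=3, random_state=7).fit(data)
        np.testing.assert_array_equal(a.v_, b.v_)
        np.testing.assert_array_equal(a.pi0_, b.pi0_)
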