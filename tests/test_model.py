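"""MFA regression: DOF accounting, fitting, profile CIs, precision
scores and residual diagnostics."""

import numpy as np
import pytest

import ketoflux as kf

from conftest import random_flux_state


class TestDegreesOfFreedom:
    def test_standard_dual_tracer_design_is_exactly_determined(self):
        assert kf.count_degrees_of_freedom() == 0

    def test_missing_acac_rate_measurement_underdetermined(self):
        assert kf.count_degrees_of_freedom(n_rate_measurements=1) == -1

    def test_two_replicate_mids_overdetermined(self):
        assert kf.count_degrees_of_freedom(n_replicate_mids=2) == 5


class TestPrecisionScore:
    def test_zero_width_interval_scores_one(self):
        assert kf.precision_score(10.0, 10.0, 10.0) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert kf.precision_score(10.0, 8.0, 12.0) == \
            pytest.approx(np.exp(-0.4 / 3), abs=1e-4)

    def test_floor_for_nonnegative_flux(self):
        # CI [0, 2v] caps both terms of the normalized range at 1
        assert kf.precision_score(5.0, 0.0, 10.0) == \
            pytest.approx(np.exp(-2 / 3), abs=1e-4)
        assert kf.precision_score(5.0, 0.0, 50.0) == \
            pytest.approx(np.exp(-2 / 3), abs=1e-4)

    def test_strictly_decreasing_in_width(self):
        widths = np.linspace(0.0, 1.0, 8)
        scores = [kf.precision_score(10.0, 10.0 - w, 10.0 + w)
                  for w in widths]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_zero_flux_undefined(self):
        with pytest.raises(ValueError):
            kf.precision_score(0.0, -1.0, 1.0)


class TestFit:
    def test_noise_free_recovery(self, recovery_preset, fast_fit_config):
        exp = kf.generate_experiment(
            recovery_preset, kf.NoiseConfig(mid_sigma=0.0,
                                            rinf_sigma_rel=0.0))
        res = kf.KetoneFluxModel(exp.measured_mid, exp.reported_protocol,
                                 fast_fit_config).fit()
        assert res.ssr < 1e-12
        assert np.allclose(res.flux.as_array(), exp.truth.as_array(),
                           rtol=1e-6)

    def test_matches_matrix_solution(self, fast_fit_config):
        rng = np.random.default_rng(17)
        for _ in range(5):
            state = random_flux_state(rng)
            proto = kf.TracerProtocol()
            mid = kf.simulate_combined_mid(state, proto)
            res = kf.KetoneFluxModel(mid, proto, fast_fit_config).fit()
            e = kf.enrichments_from_decoded(kf.decode_combined_mid(mid))
            sol = kf.solve_two_pool(e, proto.rinf_acac, proto.rinf_bhb,
                                    cond_warn=np.inf).flux
            assert np.allclose(res.flux.as_array(), sol.as_array(),
                               rtol=1e-6)

    def test_zero_interconversion_truth_lands_on_bound(self,
                                                       fast_fit_config):
        proto = kf.TracerProtocol()
        state = kf.FluxState.from_free(20.0, 10.0, 0.0, 0.0,
                                       proto.rinf_acac, proto.rinf_bhb, 0.4)
        mid = kf.simulate_combined_mid(state, proto)
        res = kf.KetoneFluxModel(mid, proto, fast_fit_config).fit()
        assert res.flux.ri_acac == pytest.approx(0.0, abs=1e-6)
        assert res.flux.ri_bhb == pytest.approx(0.0, abs=1e-6)
        lo_a, _ = res.conf_int("ri_acac")
        lo_b, _ = res.conf_int("ri_bhb")
        assert lo_a == pytest.approx(0.0, abs=1e-9)
        assert lo_b == pytest.approx(0.0, abs=1e-9)

    def test_no_flux_below_bound(self, reference_preset, fast_fit_config):
        rng = np.random.default_rng(23)
        noise = kf.NoiseConfig(mid_sigma=0.005, rinf_sigma_rel=0.02)
        for i in range(5):
            exp = kf.generate_experiment(reference_preset, noise, rng)
            res = kf.KetoneFluxModel(exp.measured_mid,
                                     exp.reported_protocol,
                                     fast_fit_config).fit()
            assert (res.flux.as_array() >= -1e-12).all()

    def test_determinism(self, recovery_preset):
        noise = kf.NoiseConfig(mid_sigma=0.003, seed=4)
        exp = kf.generate_experiment(recovery_preset, noise)
        cfg = kf.FitConfig(multistart=4, seed=9)
        r1 = kf.KetoneFluxModel(exp.measured_mid, exp.reported_protocol,
                                cfg).fit()
        r2 = kf.KetoneFluxModel(exp.measured_mid, exp.reported_protocol,
                                cfg).fit()
        assert np.array_equal(r1.theta, r2.theta)
        assert r1.ssr == r2.ssr


class TestProfileCI:
    def test_interval_brackets_estimate(self, recovery_preset,
                                        fast_fit_config):
        exp = kf.generate_experiment(
            recovery_preset,
            kf.NoiseConfig(mid_sigma=0.003, seed=2))
        res = kf.KetoneFluxModel(exp.measured_mid, exp.reported_protocol,
                                 fast_fit_config).fit()
        for name in ("ra_acac", "rd_bhb"):
            lo, hi = res.conf_int(name)
            v = getattr(res.flux, name)
            assert lo <= v + 1e-9
            assert hi >= v - 1e-9

    def test_width_shrinks_with_mid_sigma(self, recovery_preset):
        exp = kf.generate_experiment(
            recovery_preset, kf.NoiseConfig(mid_sigma=0.0,
                                            rinf_sigma_rel=0.0))
        widths = []
        for sigma in (0.003, 0.0003):
            cfg = kf.FitConfig(mid_sigma=sigma, multistart=2, seed=1)
            res = kf.KetoneFluxModel(exp.measured_mid,
                                     exp.reported_protocol, cfg).fit()
            lo, hi = res.conf_int("ra_acac")
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestResidualReport:
    def test_clean_data_consistent(self, clean_experiment, fast_fit_config):
        res = kf.KetoneFluxModel(clean_experiment.measured_mid,
                                 clean_experiment.reported_protocol,
                                 fast_fit_config).fit()
        rep = res.residual_report()
        assert rep["verdict"] == "consistent"
        assert all(abs(r) < 1e-6 for r in rep["weighted_residuals"].values())

    def test_tracer_loss_flagged_with_odd_mass_residuals(
            self, reference_preset):
        noise = kf.NoiseConfig(mid_sigma=0.0, rinf_sigma_rel=0.0,
                               tracer_loss_acac=0.25)
        exp = kf.generate_experiment(reference_preset, noise)
        cfg = kf.FitConfig(multistart=5, seed=1)
        res = kf.KetoneFluxModel(exp.measured_mid, exp.reported_protocol,
                                 cfg).fit()
        rep = res.residual_report()
        assert rep["verdict"] == "inconsistent"
        # the infusion-rate conflict surfaces in the AcAc-derived
        # (odd-mass) channels or the rate measurements themselves
        assert rep["worst_measurements"][0] in \
            {"m1", "m3", "m5", "rinf_acac"}

    def test_m5_dropout_is_absorbed_at_the_ri_bound(self,
                                                    reference_preset):
        # a zeroed, renormalized M+5 channel is observationally
        # equivalent to a consistent experiment with Ri BHB = 0, so the
        # regression interpolates it; the boundary flux is the only trace
        noise = kf.NoiseConfig(mid_sigma=0.0, rinf_sigma_rel=0.0,
                               zero_channels=(5,))
        exp = kf.generate_experiment(reference_preset, noise)
        cfg = kf.FitConfig(multistart=5, seed=1)
        res = kf.KetoneFluxModel(exp.measured_mid, exp.reported_protocol,
                                 cfg).fit()
        rep = res.residual_report()
        assert res.flux.ri_bhb == pytest.approx(0.0, abs=1e-9)
        assert "ri_bhb" in rep["boundary_fluxes"]

    def test_summary_renders(self, clean_experiment, fast_fit_config):
        res = kf.KetoneFluxModel(clean_experiment.measured_mid,
                                 clean_experiment.reported_protocol,
                                 fast_fit_config).fit()
        text = res.summary()
        assert "ra_acac" in text
        assert "consistent" in text
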