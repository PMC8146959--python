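"""Atom-mapped network, forward simulator and derivatization encoding."""

import numpy as np
import pytest

import ketoflux as kf
from ketoflux.network import CARBON_MASSES

from conftest import random_flux_state


class TestNetworkStructure:
    def test_eleven_reactions(self):
        assert len(kf.build_network().reactions) == 11

    def test_acac_interconversion_atom_map(self):
        rxn = kf.build_network().reaction("Ri AcAc")
        assert rxn.educts == ((1, "AcAc.blood", "ABCD"), (1, "H.h2o", "a"))
        assert rxn.products == ((1, "BHB.blood", "AaBCD"),)

    def test_carbon_conservation_everywhere(self):
        net = kf.build_network()
        for rxn in net.reactions:
            if rxn.name == "Sink":
                continue
            assert rxn.carbon_count("educts") == rxn.carbon_count("products")

    def test_sampling_reactions_have_zero_stoichiometry(self):
        net = kf.build_network()
        for name in ("Rs BHB", "Rs AcAc"):
            blood = [c for c, s, _ in net.reaction(name).educts
                     if s.endswith(".blood")]
            assert blood == [0]

    def test_free_flux_dimension_is_seven(self):
        # six net fluxes after the two blood-node balances, plus the
        # sampling (pool-ratio) parameter
        assert kf.build_network().free_flux_dimension() == 7

    def test_derivatization_deuterium_only_in_sampling_path(self):
        net = kf.build_network()
        rs = net.reaction("Rs AcAc")
        assert any(s == "D.h2o" for _, s, _ in rs.educts)
        for rxn in net.reactions:
            if rxn.name == "Rs AcAc":
                continue
            assert all(s != "D.h2o" for _, s, _ in rxn.educts)


class TestForwardSimulator:
    def test_pure_tracer_limit(self, protocol):
        state = kf.FluxState.from_free(0, 0, 0, 0, protocol.rinf_acac,
                                       protocol.rinf_bhb, 0.5)
        x_a, x_b = kf.simulate_steady_state(state, protocol)
        assert np.allclose(x_a.fractions, [0, 1, 0], atol=1e-12)
        assert np.allclose(x_b.fractions, [0, 0, 1], atol=1e-12)

    def test_unlabeled_infusates_give_pure_m0(self):
        proto = kf.TracerProtocol(
            infusate_acac_mid=kf.MID(np.array([1.0, 0.0, 0.0])),
            infusate_bhb_mid=kf.MID(np.array([1.0, 0.0, 0.0])),
        )
        state = kf.FluxState.from_free(10, 5, 8, 4, proto.rinf_acac,
                                       proto.rinf_bhb, 0.3)
        x_a, x_b = kf.simulate_steady_state(state, proto)
        assert np.allclose(x_a.fractions, [1, 0, 0], atol=1e-12)
        assert np.allclose(x_b.fractions, [1, 0, 0], atol=1e-12)

    def test_against_dense_linear_solve(self, protocol):
        """Independent oracle: one dense 6x6 solve over all pool/mass
        unknowns instead of per-mass 2x2 systems."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            state = random_flux_state(rng)
            out_a = state.rd_acac + state.ri_acac
            out_b = state.rd_bhb + state.ri_bhb
            inf_a = protocol.infusate_acac_mid.fractions
            inf_b = protocol.infusate_bhb_mid.fractions
            mat = np.zeros((6, 6))
            rhs = np.zeros(6)
            for i, m in enumerate(CARBON_MASSES):
                mat[i, i] = out_a
                mat[i, 3 + i] = -state.ri_bhb
                rhs[i] = state.rinf_acac * inf_a[i] \
                    + state.ra_acac * (m == 0)
                mat[3 + i, 3 + i] = out_b
                mat[3 + i, i] = -state.ri_acac
                rhs[3 + i] = state.rinf_bhb * inf_b[i] \
                    + state.ra_bhb * (m == 0)
            dense = np.linalg.solve(mat, rhs)
            x_a, x_b = kf.simulate_steady_state(state, protocol)
            assert np.allclose(x_a.fractions, dense[:3], atol=1e-10)
            assert np.allclose(x_b.fractions, dense[3:], atol=1e-10)

    def test_per_mass_label_conservation(self, protocol):
        rng = np.random.default_rng(8)
        state = random_flux_state(rng)
        x_a, x_b = kf.simulate_steady_state(state, protocol)
        inf_a = protocol.infusate_acac_mid.fractions
        inf_b = protocol.infusate_bhb_mid.fractions
        for i, m in enumerate(CARBON_MASSES):
            inflow_a = state.rinf_acac * inf_a[i] \
                + state.ra_acac * (m == 0) + state.ri_bhb * x_b[i]
            outflow_a = (state.rd_acac + state.ri_acac) * x_a[i]
            assert inflow_a == pytest.approx(outflow_a, abs=1e-10)
            inflow_b = state.rinf_bhb * inf_b[i] \
                + state.ra_bhb * (m == 0) + state.ri_acac * x_a[i]
            outflow_b = (state.rd_bhb + state.ri_bhb) * x_b[i]
            assert inflow_b == pytest.approx(outflow_b, abs=1e-10)

    def test_unbalanced_input_rejected(self, protocol):
        bad = kf.FluxState(10, 5, 8, 4, 99.0, 12.08, 1.91, 2.08, 0.3)
        with pytest.raises(ValueError, match="balance"):
            kf.simulate_steady_state(bad, protocol)


class TestCombinedMid:
    def test_pure_tracers_at_half_pool_ratio(self, protocol):
        state = kf.FluxState.from_free(0, 0, 0, 0, protocol.rinf_acac,
                                       protocol.rinf_bhb, 0.5)
        mid = kf.simulate_combined_mid(state, protocol)
        # AcAc tracer (M+2 carbon) appears at M+3 after derivatization;
        # BHB tracer stays at M+4
        assert np.allclose(mid.fractions, [0, 0, 0, 0.5, 0.5, 0],
                           atol=1e-12)

    def test_unlabeled_system_encodes_pool_ratio(self):
        proto = kf.TracerProtocol(
            infusate_acac_mid=kf.MID(np.array([1.0, 0.0, 0.0])),
            infusate_bhb_mid=kf.MID(np.array([1.0, 0.0, 0.0])),
        )
        state = kf.FluxState.from_free(10, 5, 8, 4, proto.rinf_acac,
                                       proto.rinf_bhb, 0.2)
        mid = kf.simulate_combined_mid(state, proto)
        assert np.allclose(mid.fractions, [0.8, 0.2, 0, 0, 0, 0],
                           atol=1e-12)

    def test_decode_inverts_encode(self, protocol):
        rng = np.random.default_rng(13)
        for _ in range(10):
            state = random_flux_state(rng)
            x_a, x_b = kf.simulate_steady_state(state, protocol)
            d = kf.decode_combined_mid(
                kf.simulate_combined_mid(state, protocol))
            assert d.acac_fraction == pytest.approx(
                state.pool_ratio_acac, abs=1e-9)
            assert d.acac_mid.allclose(x_a, atol=1e-9)
            assert d.bhb_mid.allclose(x_b, atol=1e-9)

    def test_degenerate_pool_ratio_rejected(self, protocol):
        state = kf.FluxState.from_free(10, 5, 8, 4, protocol.rinf_acac,
                                       protocol.rinf_bhb, 0.0)
        with pytest.raises(ValueError, match="pool_ratio"):
            kf.simulate_combined_mid(state, protocol)


class TestInfusionAdjustment:
    def test_equal_concentrations_unchanged(self):
        assert kf.adjust_infusion_rate(1.91, 30.0, 30.0) == \
            pytest.approx(1.91)

    def test_forty_percent_loss(self):
        # measured infusate 40% below the theoretical concentration
        assert kf.adjust_infusion_rate(1.91, 18.0, 30.0) == \
            pytest.approx(1.91 * 0.6)

    @pytest.mark.parametrize("measured, theoretical", [(0.0, 30.0),
                                                       (18.0, 0.0)])
    def test_degenerate_concentrations_rejected(self, measured, theoretical):
        with pytest.raises(ValueError):
            kf.adjust_infusion_rate(1.91, measured, theoretical)

    def test_protocol_effective_rate(self):
        proto = kf.TracerProtocol(measured_conc_acac=18.0,
                                  theoretical_conc_acac=30.0)
        assert proto.effective_rinf_acac == pytest.approx(1.91 * 0.6)
        assert proto.effective_rinf_bhb == pytest.approx(2.08)
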