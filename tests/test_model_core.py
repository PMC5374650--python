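import numpy as np
import pytest

from rdhill import (
    Grid1D,
    IllegalTransitionError,
    SmoothingPolicy,
    all_propensities,
    apply_channel,
    build_chain_model,
    build_toy_model,
)
from rdhill.model_core import TOY_DEFAULTS


class TestGrid1D:
    def test_bin_size_times_count_is_domain_length(self):
        g = Grid1D(L=1.0, K=7)
        assert g.h * g.K == pytest.approx(g.L, rel=1e-12)

    @pytest.mark.parametrize("bad", [0, -3])
    def test_rejects_nonpositive_bin_counts(self, bad):
        with pytest.raises(ValueError):
            Grid1D(L=1.0, K=bad)

    def test_single_bin_has_no_neighbors(self):
        assert Grid1D(L=1.0, K=1).neighbors(0) == ()

    def test_reflecting_edges_have_one_neighbor(self):
        g = Grid1D(L=1.0, K=4)
        assert g.neighbors(0) == (1,)
        assert g.neighbors(3) == (2,)
        assert g.neighbors(1) == (0, 2)

    def test_periodic_edges_wrap(self):
        g = Grid1D(L=1.0, K=4, boundary="periodic")
        assert g.neighbors(0) == (3, 1)


class TestBuildToyModel:
    def test_printed_parameter_defaults(self):
        m = build_toy_model(K=100, K_m=25.0)
        assert m.grid.h == pytest.approx(0.01)
        syn = m.reactions[0]
        assert syn.kind == "zeroth_order"
        # a1 = k_s * h = 2.5 * 0.01
        assert syn.rate * m.grid.h == pytest.approx(0.025)
        assert m.reactions[2].hill.n_hill == 4
        assert {s.name: s.D for s in m.species} == {"E": 1.0, "P": 1.0}

    def test_single_bin_is_well_mixed(self):
        m = build_toy_model(K=1, K_m=25.0)
        assert m.grid.h == pytest.approx(1.0)
        # no diffusion channels carry weight: all propensities beyond
        # the four reactions are absent for K=1
        state = m.initial_state({"E": 3, "P": 2})
        props = all_propensities(state, m)
        assert props.shape == (4 + 2 * 1 * 2,)
        assert props[4:].sum() == 0.0

    def test_mean_enzyme_alpha_from_defaults(self):
        p = TOY_DEFAULTS
        assert p.alpha == pytest.approx(25.0)

    @pytest.mark.parametrize("K,K_m", [(0, 25.0), (-1, 25.0), (10, 0.0), (10, -5.0)])
    def test_invalid_arguments(self, K, K_m):
        with pytest.raises(ValueError):
            build_toy_model(K=K, K_m=K_m)

    def test_eq6_propensity_table(self):
        """Every propensity coefficient of the per-bin reaction table."""
        m = build_toy_model(K=10, K_m=25.0)
        h = m.grid.h
        state = m.initial_state()
        state.counts[0, :] = 3   # E_i = 3
        state.counts[1, :] = 5   # P_i = 5
        props = all_propensities(state, m)
        n_rx, K = 4, 10
        p = TOY_DEFAULTS
        for i in range(K):
            assert props[i * n_rx + 0] == pytest.approx(p.k_s * h)          # a1
            assert props[i * n_rx + 1] == pytest.approx(p.k_d * 3)          # a2
            expected_a3 = p.k_syn * h * 3**4 / ((25.0 * h) ** 4 + 3**4)
            assert props[i * n_rx + 2] == pytest.approx(expected_a3)        # a3
            assert props[i * n_rx + 3] == pytest.approx(p.k_deg * 5)        # a4
        base = K * n_rx
        for i in range(1, K - 1):   # interior: two directions sum to 2D/h^2
            left = props[base + i * 2]
            right = props[base + i * 2 + 1]
            assert left + right == pytest.approx(2 * p.D_E / h**2 * 3)      # a5
        assert props[base + 0] == 0.0        # no hop off the left edge
        assert props[base + (K - 1) * 2 + 1] == 0.0

    def test_convergent_smoothing_resolved_at_build(self):
        m = build_toy_model(K=100, K_m=25.0, smoothing="convergent")
        assert m.smoothing.mode == "convergent"
        assert m.smoothing.m == 2
        assert m.smoothing.rho(m.grid.h) == pytest.approx(0.02)


class TestBuildChainModel:
    def test_equilibrium_per_bin_mean(self):
        from rdhill import fast_relaxation_profile

        m = build_chain_model(K=10, D=1.0, f="identity", n_total=5)
        assert fast_relaxation_profile(m, 5) == pytest.approx(np.full(10, 0.5))

    def test_empty_chain_has_zero_propensities(self):
        m = build_chain_model(K=2, D=1.0, f="zero", n_total=0)
        state = m.initial_state()
        assert all_propensities(state, m).sum() == 0.0

    def test_jump_rate_is_D_over_h_squared(self):
        m = build_chain_model(K=4, D=2.0, f="identity", n_total=8)
        h = m.grid.h
        state = m.initial_state({"X": np.array([8, 0, 0, 0])})
        props = all_propensities(state, m)
        base = 4 * 1  # one reaction channel per bin
        # bin 0 holds all 8 molecules; only the rightward hop is allowed
        assert props[base + 1] == pytest.approx(2.0 / h**2 * 8)

    def test_needs_at_least_two_bins(self):
        with pytest.raises(ValueError):
            build_chain_model(K=1, D=1.0, f="zero", n_total=0)


class TestApplyChannel:
    def test_diffusion_hop_conserves_totals(self):
        m = build_toy_model(K=8, K_m=25.0)
        state = m.initial_state({"E": 16, "P": 8})
        before = state.totals().copy()
        new = apply_channel(state, m, channel_index=4, bin_index=3, direction=+1)
        assert new.counts[0, 3] == state.counts[0, 3] - 1
        assert new.counts[0, 4] == state.counts[0, 4] + 1
        np.testing.assert_array_equal(new.totals(), before)

    def test_degradation_of_empty_bin_is_illegal(self):
        m = build_toy_model(K=4, K_m=25.0)
        state = m.initial_state()   # all zeros
        with pytest.raises(IllegalTransitionError):
            apply_channel(state, m, channel_index=1, bin_index=0)

    def test_synthesis_adds_one_product(self):
        m = build_toy_model(K=8, K_m=25.0)
        state = m.initial_state()
        new = apply_channel(state, m, channel_index=2, bin_index=7)
        assert new.counts[1, 7] == 1
        assert new.counts.sum() == 1

    def test_hop_off_reflecting_edge_is_illegal(self):
        m = build_toy_model(K=4, K_m=25.0)
        state = m.initial_state({"E": 4})
        with pytest.raises(IllegalTransitionError):
            apply_channel(state, m, channel_index=4, bin_index=0, direction=-1)


class TestSmoothingPolicy:
    def test_none_mode_requires_unit_window(self):
        with pytest.raises(ValueError):
            SmoothingPolicy("none", 3)

    def test_rho_is_m_times_h(self):
        pol = SmoothingPolicy("fixed", 5)
        assert pol.rho(0.01) == pytest.approx(0.05)

    def test_undeclared_species_rejected(self):
        from rdhill.model_core import (
            ModelDefinition, ReactionChannel, SpeciesSpec,
        )

        with pytest.raises(ValueError, match="undeclared"):
            ModelDefinition(
                grid=Grid1D(L=1.0, K=2),
                species=(SpeciesSpec("A", 0.0),),
                reactions=(ReactionChannel("bad", "first_order", {"B": -1},
                                           rate=1.0, reactant="B"),),
            )
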