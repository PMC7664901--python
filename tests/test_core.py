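"""Kinetic scheme, energetics and strain-dependent rate functions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xbridge import (
    ModelParameters,
    StateId,
    Transition,
    cross_bridge_force,
    elastic_energy,
    free_energy,
    transition_rate,
)
from xbridge.core import CYCLE_ORDER, find_transition, pair_rates


class TestStates:
    def test_every_state_is_attached_or_detached(self):
        attached = {s for s in StateId if s.attached}
        detached = {s for s in StateId if not s.attached}
        assert attached | detached == set(StateId)
        assert not attached & detached
        assert detached == {StateId.MT, StateId.MDP}

    @pytest.mark.parametrize(
        "alias, canonical",
        [("AMD_PP", StateId.AMDP_PP), ("AMDP_PiR", StateId.AMDP_PIR), ("AM", StateId.AM)],
    )
    def test_alias_parsing(self, alias, canonical):
        assert StateId.parse(alias) is canonical

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            StateId.parse("AMX")

    def test_scheme_is_a_single_closed_cycle(self, params):
        # every state has exactly one forward edge in the cycle ordering
        forward = {(t.frm, t.to) for t in params.transitions}
        expected = set(zip(CYCLE_ORDER, CYCLE_ORDER[1:] + (CYCLE_ORDER[0],)))
        assert forward == expected


class TestParameterValidation:
    def test_minima_ordering_enforced(self, params):
        with pytest.raises(ValueError, match="x2 < x11 < x1"):
            params.copy_with(x2=params.x1 + 1.0)

    def test_positive_scalars_enforced(self, params):
        for field in ("ks", "kbt", "site_spacing"):
            with pytest.raises(ValueError):
                params.copy_with(**{field: -1.0})

    def test_sites_per_zone_restricted(self, params):
        with pytest.raises(ValueError):
            params.copy_with(sites_per_zone=2)

    def test_window_forbidden_on_reversible_transition(self):
        with pytest.raises(ValueError, match="window"):
            Transition(StateId.MDP, StateId.AMDP_PP, 100.0, reversible=True, window=(0, 6))

    def test_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "p.yaml"
        params.to_yaml(path)
        back = ModelParameters.from_yaml(path)
        assert back.to_dict() == params.to_dict()

    def test_with_x1_moves_x11_in_parallel(self, params):
        p2 = params.with_x1(6.3)
        assert p2.x1 == 6.3
        assert p2.x11 == pytest.approx(5.8)
        assert p2.x2 == params.x2


class TestElasticEnergyAndForce:
    def test_energy_zero_at_minimum(self, params):
        for s in StateId:
            if s.attached:
                xi = params.minimum_position(s)
                assert elastic_energy(params, s, xi) == 0.0

    def test_parabola_values(self, params):
        # ks = 2.8 pN/nm: 1 nm from the minimum stores 1.4 pN nm
        assert elastic_energy(params, StateId.AMDP_PP, params.x1 + 1.0) == pytest.approx(1.4)
        # rigor minimum is x = 0: 2 nm of strain stores 2.8*4/2 = 5.6 pN nm
        assert elastic_energy(params, StateId.AM, -2.0) == pytest.approx(5.6)

    def test_force_examples(self, params):
        assert cross_bridge_force(params, StateId.AMD_H, params.x2) == 0.0
        assert cross_bridge_force(params, StateId.AM, 1.0) == pytest.approx(2.8)

    def test_detached_states_have_no_elastic_terms(self, params):
        for s in (StateId.MT, StateId.MDP):
            with pytest.raises(ValueError):
                elastic_energy(params, s, 0.0)
            with pytest.raises(ValueError):
                cross_bridge_force(params, s, 0.0)

    @pytest.mark.parametrize("mode", ["linear", "nonlinear"])
    def test_force_is_energy_derivative(self, params, rng, mode):
        """Central difference of elastic energy matches force to 1e-6 relative."""
        p = params.copy_with(elasticity=mode)
        h = 1e-6
        xs = rng.uniform(-15.0, 15.0, 100)
        for s in StateId:
            if not s.attached:
                continue
            num = (elastic_energy(p, s, xs + h) - elastic_energy(p, s, xs - h)) / (2 * h)
            f = cross_bridge_force(p, s, xs)
            assert np.allclose(num, f, rtol=1e-6, atol=1e-6)

    def test_nonlinear_with_equal_stiffness_is_bitwise_linear(self, params, rng):
        p_lin = params.copy_with(elasticity="linear")
        p_non = params.copy_with(elasticity="nonlinear", ks_compliant=params.ks)
        xs = rng.uniform(-18.0, 18.0, 200)
        for s in StateId:
            if not s.attached:
                continue
            assert np.array_equal(
                elastic_energy(p_lin, s, xs), elastic_energy(p_non, s, xs)
            )
            assert np.array_equal(
                cross_bridge_force(p_lin, s, xs), cross_bridge_force(p_non, s, xs)
            )

    def test_nonlinear_mode_softens_compression_only(self, params):
        p = params.copy_with(elasticity="nonlinear")
        # extension identical, compression softened by ks_compliant/ks
        assert cross_bridge_force(p, StateId.AM, 2.0) == pytest.approx(5.6)
        assert cross_bridge_force(p, StateId.AM, -2.0) == pytest.approx(-0.56)


class TestFreeEnergy:
    def test_basal_level_at_minimum(self, params):
        for s in StateId:
            if s.attached:
                xi = params.minimum_position(s)
                assert free_energy(params, s, xi) == pytest.approx(params.basal_energy[s])

    def test_stationary_at_minimum(self, params):
        h = 1e-6
        for s in StateId:
            if not s.attached:
                continue
            xi = params.minimum_position(s)
            slope = (free_energy(params, s, xi + h) - free_energy(params, s, xi - h)) / (2 * h)
            assert abs(slope) < 1e-6

    def test_full_cycle_drops_by_atp_free_energy(self, params):
        assert params.cycle_equilibrium_log() == pytest.approx(params.dg_atp, abs=1e-12)
        assert params.detachment_drop > 0


class TestTransitionRates:
    def test_detailed_balance_at_random_strains(self, params, rng):
        """kf/kr = exp(dG/kBT) to 1e-9 relative everywhere, including capped regions."""
        xs = rng.uniform(-18.0, 18.0, 50)
        for tr in params.transitions:
            if not tr.reversible:
                continue
            kf, kr = pair_rates(params, tr, xs)
            dg = np.asarray(free_energy(params, tr.frm, xs)) - np.asarray(
                free_energy(params, tr.to, xs)
            )
            assert np.all(kf > 0) and np.all(kr > 0)
            assert np.allclose(np.log(kf / kr), dg, rtol=0, atol=1e-9)

    def test_forward_equals_reverse_where_free_energies_cross(self, params):
        # AMD_L -> AMD_H: locate the strain where total free energies are equal
        from scipy.optimize import brentq

        g = lambda x: free_energy(params, StateId.AMD_L, x) - free_energy(
            params, StateId.AMD_H, x
        )
        x_eq = brentq(g, -10, 10)
        kf = transition_rate(params, StateId.AMD_L, StateId.AMD_H, x_eq)
        kr = transition_rate(params, StateId.AMD_H, StateId.AMD_L, x_eq)
        assert kf == pytest.approx(kr, rel=1e-9)

    def test_zero_strain_constants_match_config(self, params):
        # attachment at its optimum reproduces the configured rate constant
        tr, _ = find_transition(params, StateId.MDP, StateId.AMDP_PP)
        assert transition_rate(params, StateId.MDP, StateId.AMDP_PP, params.x1) == (
            pytest.approx(tr.k0)
        )
        # hydrolysis is strain-independent
        tr_h, _ = find_transition(params, StateId.MT, StateId.MDP)
        assert transition_rate(params, StateId.MT, StateId.MDP, 3.7) == pytest.approx(
            tr_h.k0
        )

    def test_rates_capped_jointly(self, params):
        # deep in the capped region the larger of the pair sits at the cap
        # and the ratio still satisfies detailed balance
        tr, _ = find_transition(params, StateId.AMD_L, StateId.AMD_H)
        kf, kr = pair_rates(params, tr, np.array([-18.0]))
        assert max(kf[0], kr[0]) <= params.rate_cap * (1 + 1e-12)
        assert kf[0] == pytest.approx(params.rate_cap)

    def test_unknown_transition_rejected(self, params):
        with pytest.raises(KeyError):
            transition_rate(params, StateId.MT, StateId.AM, 0.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.floats(-25.0, 25.0),
        st.floats(0.5, 6.0),
        st.floats(1.0, 10.0),
    )
    def test_detailed_balance_survives_parameter_variation(self, x, ks, kbt):
        """The rate construction keeps kf/kr = exp(dG/kBT) for arbitrary
        stiffness, temperature and strain, cap included."""
        p = ModelParameters(ks=ks, kbt=kbt)
        for tr in p.transitions:
            if not tr.reversible:
                continue
            kf, kr = pair_rates(p, tr, np.array([x]))
            dg = float(
                np.asarray(free_energy(p, tr.frm, x)) - np.asarray(free_energy(p, tr.to, x))
            )
            assert np.log(kf[0] / kr[0]) == pytest.approx(dg, abs=1e-9)
            assert max(kf[0], kr[0]) <= p.rate_cap * (1 + 1e-12)

    def test_irreversible_reverse_rate_is_zero(self, params):
        tr, _ = find_transition(params, StateId.AM, StateId.MT)
        _, kr = pair_rates(params, tr, np.array([0.0]))
        assert kr[0] == 0.0
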