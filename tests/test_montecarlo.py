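"""Gillespie engine, quasi-static mechanics and trace bookkeeping."""

import numpy as np
import pytest
from scipy import optimize, stats

from xbridge import (
    Ensemble,
    ModelParameters,
    MotorHead,
    SimulationConfig,
    StateId,
    Transition,
    rebalance_filament,
    run_simulation,
)
from xbridge.core import CYCLE_ORDER, STATE_INDEX
from xbridge.montecarlo import _Engine, propensity_table


# ----------------------------------------------------------------------
# quasi-static force balance
# ----------------------------------------------------------------------
class TestRebalance:
    def test_single_head_zero_load_moves_by_its_strain(self, params):
        # one rigor head pre-strained by 3 nm: the filament slides 3 nm and
        # the residual force vanishes
        head = MotorHead(id=0, offset_nm=3.0, state=StateId.AM, bound_site=3.0)
        ens = Ensemble(params=params, heads=[head])
        z = rebalance_filament(ens)
        assert z == pytest.approx(3.0)

    def test_two_equal_springs_average_their_strains(self, params):
        heads = [
            MotorHead(id=0, offset_nm=2.0, state=StateId.AM, bound_site=2.0),
            MotorHead(id=1, offset_nm=6.0, state=StateId.AM, bound_site=6.0),
        ]
        ens = Ensemble(params=params, heads=heads)
        assert rebalance_filament(ens) == pytest.approx(4.0)

    def test_no_attached_heads_leaves_position(self, params):
        ens = Ensemble(
            params=params,
            heads=[MotorHead(id=0, offset_nm=0.0, state=StateId.MDP)],
            filament_position=5.0,
        )
        assert rebalance_filament(ens) == 5.0

    def test_nonlinear_balance_matches_bisection_oracle(self, params, rng):
        p = params.copy_with(elasticity="nonlinear")
        anchors = rng.uniform(-5, 10, 10)
        pool = [StateId.AMD_L, StateId.AMD_H, StateId.AM]
        states = [pool[i] for i in rng.integers(0, 3, 10)]
        heads = [
            MotorHead(id=i, offset_nm=0.0, state=s, bound_site=float(c))
            for i, (s, c) in enumerate(zip(states, anchors))
        ]
        ens = Ensemble(params=p, heads=heads, external_load=12.0)
        z = rebalance_filament(ens, external_load=12.0)

        def residual(zz):
            tot = 0.0
            for h in heads:
                s = (h.bound_site - zz) - p.minimum_position(h.state)
                k = p.ks if s >= 0 else p.ks_compliant
                tot += k * s
            return tot - 12.0

        z_ref = optimize.bisect(residual, -100, 100, xtol=1e-9)
        assert z == pytest.approx(z_ref, abs=1e-6)
        assert abs(residual(z)) < 1e-6


# ----------------------------------------------------------------------
# propensities
# ----------------------------------------------------------------------
class TestPropensities:
    def test_engine_matches_reference_enumeration(self, params):
        """Vectorized propensity rows equal the head-by-head enumeration."""
        offsets = np.array([-9.0, -2.0, 4.5, 5.5, 12.0])
        states = [StateId.MT, StateId.MDP, StateId.AMD_L, StateId.AMDP_PP, StateId.AM]
        anchors = [None, None, 4.5, 5.5, 12.0]
        cfg = SimulationConfig(
            mode="isometric",
            n_heads=5,
            duration=1.0,
            seed=0,
            offsets=offsets,
            initial_states=np.array([STATE_INDEX[s] for s in states]),
            initial_anchors=np.array([np.nan if a is None else a for a in anchors]),
        )
        eng = _Engine(params, cfg)
        heads = [
            MotorHead(id=i, offset_nm=float(o), state=s, bound_site=a)
            for i, (o, s, a) in enumerate(zip(offsets, states, anchors))
        ]
        ens = Ensemble(params=params, heads=heads)
        table = propensity_table(ens)
        for row in table.itertuples():
            e_idx = next(
                i
                for i, e in enumerate(eng.edges)
                if CYCLE_ORDER[e.frm].value == row[2]
                and CYCLE_ORDER[e.to].value == row[3]
                and (e.site_delta is None or e.site_delta == row.site_delta)
            )
            assert eng.R[row.head, e_idx] == pytest.approx(row.rate, rel=1e-12)
        assert eng.R.sum() == pytest.approx(table["rate"].sum(), rel=1e-12)

    def test_waiting_times_are_exponential(self):
        """A frozen two-state flicker yields iid exponential waits (KS test)."""
        k = 123.0
        p = ModelParameters(
            transitions=[
                Transition(StateId.MT, StateId.MDP, k0=k, reversible=False),
                Transition(StateId.MDP, StateId.MT, k0=k, reversible=False),
            ]
        )
        cfg = SimulationConfig(
            mode="isometric",
            n_heads=1,
            duration=1e9,
            seed=99,
            offsets=np.array([0.0]),
            initial_states=np.array([STATE_INDEX[StateId.MT]]),
            initial_anchors=np.array([np.nan]),
        )
        eng = _Engine(p, cfg)
        waits = np.array([eng.step() for _ in range(20_000)])
        assert waits.mean() == pytest.approx(1.0 / k, rel=0.02)
        _, pval = stats.kstest(waits, "expon", args=(0, 1.0 / k))
        assert pval > 0.01

    def test_head_selection_is_uniform_over_identical_heads(self):
        """Five identical flicker heads fire equally often (chi-square)."""
        k = 50.0
        p = ModelParameters(
            transitions=[
                Transition(StateId.MT, StateId.MDP, k0=k, reversible=False),
                Transition(StateId.MDP, StateId.MT, k0=k, reversible=False),
            ]
        )
        cfg = SimulationConfig(
            mode="isometric",
            n_heads=5,
            duration=1e9,
            seed=7,
            offsets=np.zeros(5),
            initial_states=np.full(5, STATE_INDEX[StateId.MT]),
            initial_anchors=np.full(5, np.nan),
        )
        eng = _Engine(p, cfg)
        first_state = eng.state.copy()
        counts = np.zeros(5)
        for _ in range(10_000):
            before = eng.state.copy()
            eng.step()
            counts[np.nonzero(eng.state != before)[0][0]] += 1
        assert first_state is not None
        _, pval = stats.chisquare(counts)
        assert pval > 0.01

    def test_absorbing_configuration_ends_cleanly(self):
        p = ModelParameters(
            transitions=[Transition(StateId.MT, StateId.MDP, k0=10.0, reversible=False)]
        )
        cfg = SimulationConfig(mode="isometric", n_heads=3, duration=10.0, seed=1)
        # all heads start in MDP, which has no outgoing transition here
        trace = run_simulation(cfg, p)
        assert trace.times.size == 1  # initial record only


# ----------------------------------------------------------------------
# full simulations
# ----------------------------------------------------------------------
class TestRunSimulation:
    def test_deterministic_for_fixed_seed(self, params):
        cfg = SimulationConfig(mode="zero_load", n_heads=12, duration=0.02, seed=42)
        a = run_simulation(cfg, params)
        b = run_simulation(cfg, params)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.counts, b.counts)

    def test_occupancy_conservation_and_monotone_time(self, params):
        cfg = SimulationConfig(mode="zero_load", n_heads=18, duration=0.05, seed=3)
        tr = run_simulation(cfg, params)
        assert np.all(tr.counts.sum(axis=1) == 18)
        assert np.all(np.diff(tr.times) > 0)

    def test_zero_duration_records_initial_state_only(self, params):
        cfg = SimulationConfig(mode="zero_load", n_heads=5, duration=0.0, seed=0)
        tr = run_simulation(cfg, params)
        assert tr.times.size == 1
        assert tr.counts[0, STATE_INDEX[StateId.MDP]] == 5

    def test_unloaded_ensemble_shortens(self, params):
        """Net sliding is in the shortening direction, below solver Vmax."""
        from xbridge import fv_curve

        vmax = fv_curve(params).vmax
        vels = []
        for seed in range(6):
            cfg = SimulationConfig(mode="zero_load", n_heads=18, duration=0.1, seed=seed)
            tr = run_simulation(cfg, params)
            vels.append(tr.velocity())
        assert np.mean(vels) > 0
        assert np.mean(vels) < vmax

    def test_isometric_force_rises_to_positive_plateau(self, params):
        cfg = SimulationConfig(
            mode="isometric", n_heads=300, duration=0.15, seed=5, initial_state="MDP"
        )
        tr = run_simulation(cfg, params)
        assert tr.forces[0] == 0.0
        late = tr.forces[tr.times > 0.1]
        assert late.mean() > 0.5 * 300 * 1.0  # plateau of order 1 pN/head
        assert np.all(tr.positions == 0.0)

    def test_all_attached_start_counts(self, params):
        cfg = SimulationConfig(
            mode="isometric", n_heads=10, duration=0.0, seed=0, initial_state="AMDP_PP"
        )
        tr = run_simulation(cfg, params)
        assert tr.counts[0, STATE_INDEX[StateId.AMDP_PP]] == 10

    def test_trace_round_trips_through_disk(self, params, tmp_path):
        cfg = SimulationConfig(mode="zero_load", n_heads=8, duration=0.01, seed=9)
        tr = run_simulation(cfg, params)
        tr.save(tmp_path / "run")
        import json

        import pandas as pd

        df = pd.read_csv(tmp_path / "run.tsv", sep="\t")
        assert np.allclose(df["time_s"], tr.times)
        assert np.allclose(df["position_nm"], tr.positions)
        meta = json.loads((tmp_path / "run.meta.json").read_text())
        assert meta["seed"] == 9
        assert meta["config"]["mode"] == "zero_load"

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(mode="pushmepullyou")
        with pytest.raises(ValueError):
            SimulationConfig(mode="zero_load", load=5.0)
        with pytest.raises(ValueError):
            SimulationConfig(duration=-1.0)
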