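"""Rate law, thermodynamic weighting, ODE right-hand side, steady states."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nitronet.chem import Environment, R_KJ, Reaction, Species, ThermoTable
from nitronet.dynamics import (
    CompiledSystem,
    equilibrium_state,
    major_species,
    rate_constant,
    reaction_rate,
    solve_steady_state,
)
from nitronet.enumeration import ReactionSet, enumerate_all
from nitronet.synthetic import SyntheticSpec, generate_system


class TestRateConstant:
    def test_continuous_at_zero_driving_force(self):
        for p in (0.0, 0.3, 1.0):
            assert rate_constant(0.0, p, 2.5, 288.15) == pytest.approx(2.5)
            assert rate_constant(-1e-12, p, 2.5, 288.15) == pytest.approx(2.5)

    def test_endergonic_limit_at_full_weighting(self):
        # at p = 1 every endergonic reaction keeps the reference constant
        assert rate_constant(250.0, 1.0, 1.0, 288.15) == pytest.approx(1.0)

    def test_exergonic_limit_at_zero_weighting(self):
        assert rate_constant(-250.0, 0.0, 1.0, 288.15) == pytest.approx(1.0)

    @given(
        dg=st.floats(min_value=-400.0, max_value=-0.01),
        p=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_forward_reverse_ratio_is_equilibrium_constant(self, dg, p):
        rt = R_KJ * 288.15
        k_f = rate_constant(dg, p, 1.0, 288.15)
        k_r = rate_constant(-dg, p, 1.0, 288.15)
        assert math.log(k_f / k_r) == pytest.approx(-dg / rt, rel=1e-9)

    def test_cap_applies_in_log_space(self):
        k = rate_constant(-1e5, 1.0, 1.0, 288.15, cap_log=300.0)
        assert k == pytest.approx(math.exp(300.0))


class TestReactionRate:
    def test_nitrate_reduction_is_second_order_in_nitrate(self, table):
        rxn = Reaction("r2", {"NO3-": -2, "NO2-": 2, "O2": 1})
        env = Environment(o2=1e-5, ph=8.0)
        conc = {sid: 0.0 for sid in table.state_ids}
        conc["NO3-"] = 2e-4
        assert reaction_rate(rxn, 3.0, conc, env, table) == pytest.approx(
            3.0 * (2e-4) ** 2
        )

    def test_nitrite_oxidation_includes_fixed_oxygen(self, table):
        rxn = Reaction("r1", {"NO2-": -2, "O2": -1, "NO3-": 2})
        env = Environment(o2=1e-5, ph=8.0)
        conc = {sid: 0.0 for sid in table.state_ids}
        conc["NO2-"] = 1e-4
        assert reaction_rate(rxn, 2.0, conc, env, table) == pytest.approx(
            2.0 * (1e-4) ** 2 * 1e-5
        )

    def test_depleted_reactant_kills_rate(self, table):
        rxn = Reaction("r", {"NH4+": -1, "NO2-": -1, "N2": 1, "H2O": 2})
        conc = {sid: 1e-5 for sid in table.state_ids}
        conc["NH4+"] = 0.0
        assert reaction_rate(rxn, 1.0, conc, Environment(o2=1e-5, ph=8.0),
                             table) == 0.0


class TestRhs:
    def test_empty_state_sees_only_ammonia_influx(self, table, reaction_set):
        env = Environment(o2=1e-5, ph=8.0, influx=1e-5)
        sys_ = CompiledSystem(reaction_set, table, env)
        deriv = sys_.rhs(0.0, np.zeros(11))
        expected = np.zeros(11)
        expected[table.state_index["NH3"]] = 1e-5
        np.testing.assert_allclose(deriv, expected)

    def test_without_reactions_steady_state_is_influx_over_efflux(self, table):
        env = Environment(o2=1e-5, ph=8.0, influx=1e-5, efflux=1e-3)
        ss = solve_steady_state(ReactionSet(), env, table)
        assert ss.converged
        expected = np.zeros(11)
        expected[table.state_index["NH3"]] = env.influx / env.efflux
        np.testing.assert_allclose(ss.conc, expected, rtol=1e-6, atol=1e-12)

    def test_nitrogen_balance_identity_at_random_states(self, table, reaction_set,
                                                        n_atoms):
        """a . dM/dt = I - D (a . M): the reaction term always cancels.

        Checked at mild weighting so the gross rates stay within floating
        point range of the net (the identity is exact algebraically, but
        at strong weighting opposing 1e40-scale fluxes drown the 1e-8
        net in rounding)."""
        env = Environment(o2=1e-5, ph=8.0, influx=1e-5, efflux=1e-3, p=0.005)
        sys_ = CompiledSystem(reaction_set, table, env)
        rng = np.random.default_rng(1)
        for _ in range(5):
            conc = 10 ** rng.uniform(-9, -5, size=11)
            lhs = float(n_atoms @ sys_.rhs(0.0, conc))
            rhs_ = env.influx - env.efflux * float(n_atoms @ conc)
            assert lhs == pytest.approx(rhs_, rel=1e-6, abs=1e-18)

    def test_jacobian_matches_finite_differences(self, table, reaction_set):
        env = Environment(o2=1e-5, ph=8.0, p=0.0)
        sys_ = CompiledSystem(reaction_set, table, env)
        conc = np.full(11, 1e-5)
        J = sys_.jac(0.0, conc)
        scale = float(np.abs(sys_.rhs(0.0, conc)).max())
        for j in range(11):
            dx = np.zeros(11)
            dx[j] = 1e-7 * conc[j]
            fd = (sys_.rhs(0.0, conc + dx) - sys_.rhs(0.0, conc - dx)) / (2 * dx[j])
            np.testing.assert_allclose(
                J[:, j], fd, rtol=1e-5, atol=1e-7 * scale / conc[j]
            )


def _isomer_pair(dg: float):
    """A⇌B with same composition and charge, dG0(A->B) = dg."""
    species = [
        Species("A", "isomer A", {"Q": 1}, 0, 0.0, "nitrogen_species"),
        Species("B", "isomer B", {"Q": 1}, 0, dg, "nitrogen_species"),
        Species("Hp", "proton", {"H": 1}, 1, 0.0, "proton"),
        Species("Wat", "water", {"H": 2, "O": 1}, 0, 0.0, "water"),
        Species("El", "electron", {}, -1, 0.0, "electron"),
    ]
    table = ThermoTable(species)
    rs = ReactionSet(
        [Reaction("ab", {"A": -1, "B": 1}), Reaction("ba", {"A": 1, "B": -1})]
    )
    return table, rs


class TestSteadyStates:
    def test_single_reversible_pair_reaches_closed_form_equilibrium(self):
        dg = -7.0
        table, rs = _isomer_pair(dg)
        env = Environment(o2=1.0, ph=7.0, influx=0.0, efflux=0.0,
                          initial_conc=1e-5, p=0.5)
        ss = solve_steady_state(rs, env, table)
        assert ss.converged
        keq = math.exp(-dg / env.rt)
        a, b = ss.conc_map()["A"], ss.conc_map()["B"]
        assert b / a == pytest.approx(keq, rel=1e-6)
        assert a + b == pytest.approx(2e-5, rel=1e-9)  # closed: mass kept

    def test_equilibrium_is_independent_of_weighting(self):
        table, rs = _isomer_pair(-7.0)
        conc = {}
        for p in (0.0, 1.0):
            env = Environment(o2=1.0, ph=7.0, influx=0.0, efflux=0.0, p=p)
            conc[p] = solve_steady_state(rs, env, table).conc
        np.testing.assert_allclose(conc[0.0], conc[1.0], rtol=1e-6)

    def test_open_system_total_nitrogen_is_influx_over_efflux(
        self, worked_example_ss, worked_example_env, n_atoms
    ):
        total = float(n_atoms @ worked_example_ss.conc)
        target = worked_example_env.influx / worked_example_env.efflux
        assert total == pytest.approx(target, rel=1e-6)

    def test_power_definition_holds_per_reaction(self, worked_example_ss):
        np.testing.assert_allclose(
            worked_example_ss.P,
            -worked_example_ss.dG * worked_example_ss.r,
            rtol=1e-12,
        )

    def test_continuation_agrees_with_integration_at_mild_weighting(
        self, table, reaction_set
    ):
        env = Environment(o2=1e-5, ph=8.0, p=0.01)
        by_int = solve_steady_state(reaction_set, env, table, method="integrate")
        by_ptc = solve_steady_state(reaction_set, env, table, method="ptc")
        assert by_int.converged and by_ptc.converged
        np.testing.assert_allclose(by_ptc.conc, by_int.conc, rtol=1e-5)

    def test_unweighted_mode_uses_reference_constant_everywhere(
        self, table, reaction_set
    ):
        env = Environment(o2=1e-5, ph=8.0, k_def=2.0, bep_weighted=False)
        sys_ = CompiledSystem(reaction_set, table, env)
        np.testing.assert_allclose(sys_.k, 2.0)

    def test_concentrations_remain_nonnegative(self, worked_example_ss):
        assert (worked_example_ss.conc >= 0).all()

    def test_synthetic_open_system_conserves_core_element_throughput(self):
        tbl, halves = generate_system(SyntheticSpec(style="ladder", seed=5))
        rs = enumerate_all(halves, electron_id="El")
        env = Environment(o2=1.0, ph=7.0, influx=1e-5, efflux=1e-3, p=0.5)
        ss = solve_steady_state(rs, env, tbl)
        assert ss.converged
        q = np.array([tbl[s].count("Q") for s in tbl.state_ids], float)
        assert float(q @ ss.conc) == pytest.approx(env.influx / env.efflux, rel=1e-6)


class TestEquilibriumOracle:
    def test_projection_reproduces_pair_closed_form(self):
        dg = -5.0
        table, rs = _isomer_pair(dg)
        env = Environment(o2=1.0, ph=7.0, influx=0.0, efflux=0.0, p=0.5)
        sys_ = CompiledSystem(rs, table, env)
        ref = np.array([1e-5, 1e-5])
        eq = equilibrium_state(sys_, ref)
        keq = math.exp(-dg / env.rt)
        assert eq[1] / eq[0] == pytest.approx(keq, rel=1e-10)
        assert eq.sum() == pytest.approx(2e-5, rel=1e-10)

    def test_projection_preserves_elemental_totals(self):
        tbl, halves = generate_system(SyntheticSpec(style="ladder", seed=2))
        rs = enumerate_all(halves, electron_id="El")
        env = Environment(o2=1.0, ph=7.0, influx=0.0, efflux=0.0, p=0.5)
        sys_ = CompiledSystem(rs, tbl, env)
        ref = np.full(len(tbl.state_ids), 1e-5)
        eq = equilibrium_state(sys_, ref)
        q = np.array([tbl[s].count("Q") for s in tbl.state_ids], float)
        assert float(q @ eq) == pytest.approx(float(q @ ref), rel=1e-10)
        np.testing.assert_allclose(sys_.delta_r_G(eq), 0.0, atol=1e-8)


class TestMajorSpecies:
    def _fake_ss(self, conc, table):
        from nitronet.dynamics import SteadyState

        n = len(conc)
        return SteadyState(
            conc=np.asarray(conc, float), env=Environment(o2=1e-5, ph=8.0),
            state_ids=tuple(table.state_ids[:n]), reaction_ids=[],
            dG0=np.array([]), dG=np.array([]), r=np.array([]), P=np.array([]),
            capped=np.array([], dtype=bool), converged=True, residual=0.0,
            t_end=1.0,
        )

    def test_single_dominant_species(self, table):
        conc = [0.0] * 11
        conc[4] = 1e-3
        assert major_species(self._fake_ss(conc, table)) == {"N2"}

    def test_uniform_split_keeps_all_eleven(self, table):
        ss = self._fake_ss([1e-5] * 11, table)
        assert len(major_species(ss)) == 11

    def test_threshold_is_a_share_of_total(self, table):
        conc = [1e-3] + [5e-6] * 10  # each minor is 0.49% of the total
        assert major_species(self._fake_ss(conc, table)) == {"NO3-"}

    def test_dinitrogen_is_major_at_moderate_weighting(self, worked_example_ss):
        assert "N2" in major_species(worked_example_ss)
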