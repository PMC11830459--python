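"""Species/reaction data model, balance checking and Gibbs arithmetic."""

import io
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nitronet.chem import (
    ChemError,
    Environment,
    HalfReaction,
    R_KJ,
    Reaction,
    balance_couple,
    canonicalize,
    check_balance,
    delta_r_G,
    delta_r_G0,
    equation_string,
    load_half_reactions_csv,
    load_species_csv,
    nitrogen_extra_reactions,
    nitrogen_half_reactions,
    nitrogen_thermo_table,
    o2_mg_per_l_to_molar,
    parse_stoich_field,
    reverse,
)

NITRATE_HALF = {"NO3-": -1, "H+": -2, "e-": -2, "NO2-": 1, "H2O": 1}


class TestBalance:
    def test_nitrate_reduction_couple_is_balanced(self, table):
        half = HalfReaction("eq1", NITRATE_HALF, n_e=2)
        assert check_balance(half, table) == []

    def test_missing_water_breaks_oxygen_and_charge(self, table):
        rxn = Reaction("broken", {"NO3-": -1, "NO2-": 1})
        violations = check_balance(rxn, table)
        assert any("O" in v for v in violations)

    def test_empty_stoichiometry_is_vacuously_balanced(self, table):
        assert check_balance(Reaction("null", {}), table) == []

    def test_unknown_species_raises_with_id(self, table):
        with pytest.raises(ChemError, match="XYZ"):
            check_balance(Reaction("bad", {"XYZ": -1, "NO2-": 1}), table)

    def test_every_curated_half_reaction_is_balanced(self, table):
        for half in nitrogen_half_reactions(table):
            assert check_balance(half, table) == []

    def test_every_curated_extra_is_balanced(self, table):
        extras = nitrogen_extra_reactions(table)
        assert len(extras) == 6  # three acid-base equilibria, both directions
        for rxn in extras:
            assert check_balance(rxn, table) == []

    def test_every_enumerated_reaction_is_balanced(self, table, reaction_set):
        for rxn in reaction_set:
            assert check_balance(rxn, table) == []


class TestCanonicalize:
    def test_divides_by_gcd(self):
        rxn = Reaction("r", {"NO3-": -4, "NO2-": 4, "O2": 2})
        canon = canonicalize(rxn)
        assert canon.stoich == {"NO3-": Fraction(-2), "NO2-": Fraction(2),
                                "O2": Fraction(1)}

    def test_clears_fractional_coefficients(self):
        rxn = Reaction("r", {"NO3-": Fraction(-1, 2), "NO2-": Fraction(1, 2),
                             "O2": Fraction(1, 4)})
        canon = canonicalize(rxn)
        assert all(c.denominator == 1 for c in canon.stoich.values())
        assert canon.stoich["O2"] == 1

    def test_idempotent(self, reaction_set):
        for rxn in reaction_set.reactions[::97]:
            once = canonicalize(rxn)
            assert canonicalize(once).stoich == once.stoich

    def test_forward_and_reverse_stay_distinct(self):
        fwd = Reaction("f", {"NO3-": -2, "NO2-": 2, "O2": 1})
        assert canonicalize(fwd)._key() != canonicalize(reverse(fwd))._key()


class TestGibbs:
    def test_zero_net_stoichiometry_gives_zero(self, table):
        assert delta_r_G0(Reaction("null", {}), table) == 0.0

    def test_reversal_antisymmetry(self, table, reaction_set):
        for rxn in reaction_set.reactions[::211]:
            assert delta_r_G0(reverse(rxn), table) == pytest.approx(
                -delta_r_G0(rxn, table)
            )

    def test_ammonia_protonation_matches_hand_sum(self, table):
        # dGf(NH4+) - dGf(NH3) - dGf(H+) = -79.31 - (-26.50) - 0
        rxn = Reaction("prot", {"NH3": -1, "H+": -1, "NH4+": 1})
        assert delta_r_G0(rxn, table) == pytest.approx(-52.81, abs=1e-9)

    def test_hess_additivity(self, table):
        r1 = Reaction("r1", {"NH3": -1, "H+": -1, "NH4+": 1})
        r2 = Reaction("r2", {"NO3-": -2, "NO2-": 2, "O2": 1})
        summed = Reaction(
            "sum",
            {
                sid: Fraction(r1.stoich.get(sid, 0)) + Fraction(r2.stoich.get(sid, 0))
                for sid in set(r1.stoich) | set(r2.stoich)
            },
        )
        assert delta_r_G0(summed, table) == pytest.approx(
            delta_r_G0(r1, table) + delta_r_G0(r2, table)
        )

    def test_unit_activities_reduce_to_standard_value(self, table):
        rxn = Reaction("r", {"NO3-": -2, "NO2-": 2, "O2": 1})
        env = Environment(o2=1.0, ph=0.0, temperature=298.15)
        conc = {sid: 1.0 for sid in table.state_ids}
        assert delta_r_G(rxn, conc, env, table) == pytest.approx(
            delta_r_G0(rxn, table)
        )

    def test_zero_at_constructed_equilibrium(self, table):
        """At concentrations satisfying K_eq = exp(-dG0/RT), dG vanishes."""
        rxn = Reaction("prot", {"NH3": -1, "H+": -1, "NH4+": 1})
        env = Environment(o2=1e-5, ph=7.0, temperature=288.15)
        dg0 = delta_r_G0(rxn, table)
        keq = math.exp(-dg0 / env.rt)
        nh3 = 1e-6
        conc = {sid: 1.0 for sid in table.state_ids}
        conc["NH3"] = nh3
        conc["NH4+"] = keq * nh3 * env.h_conc
        assert delta_r_G(rxn, conc, env, table) == pytest.approx(0.0, abs=1e-9)

    def test_quotient_invariant_when_molecularity_balances(self, table):
        rxn = Reaction("iso", {"NH3": -1, "H+": -1, "NH4+": 1})
        # 1 solute each side once H+ is fixed: doubling NH3 and NH4+
        # together leaves Q unchanged
        env = Environment(o2=1e-5, ph=7.0)
        base = {sid: 1e-6 for sid in table.state_ids}
        doubled = {sid: 2e-6 for sid in table.state_ids}
        assert delta_r_G(rxn, base, env, table) == pytest.approx(
            delta_r_G(rxn, doubled, env, table)
        )

    def test_in_situ_antisymmetry_for_random_concentrations(self, table, reaction_set):
        rng = np.random.default_rng(0)
        env = Environment(o2=1e-5, ph=8.0)
        for rxn in reaction_set.reactions[::301]:
            conc = {sid: float(10 ** rng.uniform(-9, -3)) for sid in table.state_ids}
            fwd = delta_r_G(rxn, conc, env, table)
            rev = delta_r_G(reverse(rxn), conc, env, table)
            assert fwd + rev == pytest.approx(0.0, abs=1e-9)

    def test_negative_concentration_rejected(self, table):
        rxn = Reaction("r", {"NO3-": -2, "NO2-": 2, "O2": 1})
        conc = {sid: 1e-6 for sid in table.state_ids}
        conc["NO3-"] = -1e-9
        with pytest.raises(ChemError):
            delta_r_G(rxn, conc, Environment(o2=1e-5, ph=8.0), table)


class TestCouples:
    def test_nitrate_nitrite_couple_reproduces_textbook_form(self, table):
        half = balance_couple("NO3-", "NO2-", table)
        assert dict(half.stoich) == NITRATE_HALF
        assert half.n_e == 2

    def test_non_reduction_pair_rejected(self, table):
        with pytest.raises(ChemError, match="not a reduction"):
            balance_couple("NO2-", "NO3-", table)  # wrong orientation


class TestEnvironment:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"o2": 0.0, "ph": 7.0},
            {"o2": 1e-5, "ph": 7.0, "p": 1.5},
            {"o2": 1e-5, "ph": 7.0, "p": -0.1},
            {"o2": 1e-5, "ph": 7.0, "efflux": -1e-3},
            {"o2": 1e-5, "ph": 7.0, "temperature": 0.0},
        ],
    )
    def test_invalid_environments_rejected(self, kwargs):
        with pytest.raises(ChemError):
            Environment(**kwargs)

    def test_ph_fixes_proton_concentration(self):
        assert Environment(o2=1e-5, ph=8.0).h_conc == pytest.approx(1e-8)


class TestParsers:
    def test_stoich_field_roundtrip(self):
        stoich = parse_stoich_field("NO3-:-1;NO2-:1;O2:1/2")
        assert stoich == {"NO3-": Fraction(-1), "NO2-": Fraction(1),
                          "O2": Fraction(1, 2)}

    @pytest.mark.parametrize(
        "text,match",
        [
            ("NO3-:x", "bad coefficient"),
            ("NO3-", "expected"),
            ("NO3-:1;NO3-:2", "duplicate"),
            (":1", "empty species"),
        ],
    )
    def test_malformed_stoich_reports_position(self, text, match):
        with pytest.raises(ChemError, match=match):
            parse_stoich_field(text, where="test")

    def test_half_reaction_loader_reports_line_numbers(self, table):
        csv = "id,n_e,stoich\nh1,2,NO3-:-1;H+:-2;e-:-2;NO2-:1;H2O:1\nh2,9,NO3-:-1\n"
        with pytest.raises(ChemError, match="line 3"):
            load_half_reactions_csv(io.StringIO(csv), table)

    def test_species_loader_rejects_missing_columns(self):
        with pytest.raises(ChemError, match="missing columns"):
            load_species_csv(io.StringIO("id,name\nx,y\n"))


class TestNitrogenTable:
    def test_eleven_nitrogen_species_in_fixed_order(self, table):
        assert len(table.state_ids) == 11
        assert table.state_ids[0] == "NO3-"
        assert table.state_ids[-1] == "NH3"

    def test_proton_and_electron_energies_are_zero(self, table):
        assert table["H+"].delta_f_G0 == 0.0
        assert table["e-"].delta_f_G0 == 0.0

    def test_curated_couples_count(self, table):
        halves = nitrogen_half_reactions(table)
        assert len(halves) == 38  # 37 nitrogen couples + the O2/H2O couple

    def test_ammonium_pka_implied_by_table(self, table):
        """The shipped formation energies must reproduce pKa(NH4+) = 9.25."""
        dg = table["NH3"].delta_f_G0 - table["NH4+"].delta_f_G0
        pka = dg / (R_KJ * 298.15 * math.log(10))
        assert pka == pytest.approx(9.25, abs=0.05)


def test_o2_saturation_ceiling_conversion():
    assert o2_mg_per_l_to_molar(10.0) == pytest.approx(3.1e-4, rel=0.02)


@given(
    coeffs=st.dictionaries(
        st.sampled_from(["NO3-", "NO2-", "NO", "N2O", "N2", "O2", "H+", "H2O"]),
        st.integers(min_value=-6, max_value=6).filter(lambda v: v != 0),
        min_size=1,
        max_size=5,
    )
)
def test_canonicalize_idempotent_on_arbitrary_stoichiometries(coeffs):
    rxn = Reaction("r", coeffs)
    once = canonicalize(rxn)
    assert canonicalize(once).stoich == once.stoich
    g = math.gcd(*(int(c) for c in once.stoich.values()))
    assert g == 1
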