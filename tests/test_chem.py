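"""Reaction network contents, balance rules and rate-constant transforms."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackchem import chem


# Compilation rate constants of the azide / hydrogen scheme (M^-1 s^-1).
PRINTED_CONSTANTS = [
    ("R1", {"e_aq-", "H"}, 2.5e10),
    ("R2", {"e_aq-"}, 6.2e9),
    ("R3", {"H"}, 4.6e9),
    ("R4", {"N3-", "H"}, 3.15e9),
    ("R5", {"N3-", "e_aq-"}, 1.5e6),
    ("R6", {"N3-", "H3O+"}, 1.0e10),
    ("R7", {"HN3", "e_aq-"}, 1.2e10),
    ("R8", {"HN3", "H"}, 6.3e7),
    ("R9", {"N3-", "OH"}, 1.2e10),
    ("R10", {"HN3", "OH"}, 1.0e7),
    ("R11", {"N3", "e_aq-"}, 2.4e10),
    ("R12", {"N3", "H"}, 1.0e10),
    ("R13", {"N3", "H2O2"}, 5.0e6),
    ("R14", {"N3"}, 3.9e9),
    ("R15", {"N3", "N3-"}, 2.4e5),
    ("R16", {"N3", "O2-"}, 1.2e10),
    ("R17", {"e_aq-"}, 19.0),
]


class TestDefaultNetwork:
    @pytest.mark.parametrize("rid,reactants,k", PRINTED_CONSTANTS)
    def test_azide_scheme_constants(self, network, rid, reactants, k):
        rxn = network.reaction(rid)
        assert set(rxn.reactants) == reactants
        assert rxn.rate_constant == k

    def test_hydrogen_forming_channels(self, network):
        assert network.reaction("R1").products == ("H2", "OH-")
        assert set(network.reaction("R2").products) == {"H2", "OH-"}
        assert network.reaction("R3").products == ("H2",)

    def test_sink_channels_flagged(self, network):
        for rid in ("R5", "R8", "R13"):
            assert network.reaction(rid).sink

    def test_protonation_channel_off_by_default(self, network):
        # speciation is handled as a static acid-base partition instead
        assert not network.reaction("R6").enabled

    def test_every_specified_reaction_balances(self, network):
        """Charge exact, N exact, H/O balanced up to implicit waters, for
        every non-sink reaction (validated on construction; recheck here)."""
        for rxn in network.reactions:
            if not rxn.sink:
                network._check_balance(rxn)

    def test_unbalanced_reaction_rejected(self, network):
        bad = chem.Reaction("X1", ("H", "H"), ("H2", "H2"), 1.0e9)
        with pytest.raises(ValueError, match="imbalance"):
            chem.ReactionNetwork(dict(network.species),
                                 network.reactions + [bad])

    def test_duplicate_ids_rejected(self, network):
        dup = chem.Reaction("R1", ("H", "H"), ("H2",), 1e9)
        with pytest.raises(ValueError, match="duplicate"):
            chem.ReactionNetwork(dict(network.species),
                                 network.reactions + [dup])

    def test_azide_diffusion_coefficients(self, network):
        assert network.species["N3-"].diffusion_coefficient == pytest.approx(
            1.84e-5, rel=1e-12)
        assert network.species["N3"].diffusion_coefficient == pytest.approx(
            1.84e-5, rel=1e-12)

    def test_yaml_round_trip(self, network):
        again = chem.ReactionNetwork.from_yaml(network.to_yaml())
        assert again.to_dict() == network.to_dict()


class TestEncounterRadius:
    def test_inverse_of_definition(self):
        # choose k = 4 pi N_A D R0 for R0 = 0.5 nm, recover R0
        d = 1.0e-5
        k = chem.smoluchowski_rate(0.5, d)
        assert chem.encounter_radius(k, d).radius_nm == pytest.approx(0.5)

    def test_linearity_in_rate(self):
        d = 2.0e-5
        r1 = chem.encounter_radius(1e9, d).radius_nm
        r2 = chem.encounter_radius(2e9, d).radius_nm
        assert r2 == pytest.approx(2 * r1)

    def test_hand_converted_value(self):
        """k1 = 2.5e10 M^-1 s^-1 with D(e_aq-)+D(H) = 1.19e-4 cm^2/s.
        Hand conversion: 2.5e10 / 6.02214076e23 L/s = 4.1513e-14 L/s
        = 4.1513e-2 nm^3/ps; D = 1.19e-2 nm^2/ps;
        R = 4.1513e-2 / (4 pi 1.19e-2) = 0.27761 nm."""
        r = chem.encounter_radius(2.5e10, 1.19e-4).radius_nm
        assert r == pytest.approx(0.27761, abs=1e-4)

    @given(k=st.floats(1e5, 1e11), d=st.floats(1e-6, 2e-4))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, k, d):
        r = chem.encounter_radius(k, d).radius_nm
        assert chem.smoluchowski_rate(r, d) == pytest.approx(k, rel=1e-10)

    def test_partial_control_collins_kimball(self):
        p = chem.encounter_radius(1e9, 1e-4, model="partially-controlled",
                                  k_act=4e9)
        # long-time rate: 1/k = 1/k_diff + 1/k_act
        k_diff = chem.smoluchowski_rate(p.radius_nm, 1e-4)
        assert 1 / k_diff + 1 / 4e9 == pytest.approx(1 / 1e9, rel=1e-9)
        assert p.v_nm_ps > 0

    def test_partial_control_unphysical(self):
        with pytest.raises(ValueError, match="unphysical"):
            chem.encounter_radius(1e9, 1e-4, model="partially-controlled",
                                  k_act=5e8)


class TestIonicStrength:
    def test_neutral_partner(self):
        assert chem.ionic_strength_factor(0, -1, 1.0) == 1.0

    def test_zero_ionic_strength(self):
        assert chem.ionic_strength_factor(-1, -1, 0.0) == 1.0

    def test_closed_form_value(self):
        # log10 f = 1.02 * 1 * sqrt(0.1)/(1 + sqrt(0.1)) = 0.2450584
        assert chem.ionic_strength_factor(-1, -1, 0.1) == pytest.approx(
            1.75816, abs=2e-4)

    def test_like_unlike_direction(self):
        assert chem.ionic_strength_factor(-1, -1, 0.5) > 1.0
        assert chem.ionic_strength_factor(+1, -1, 0.5) < 1.0

    @given(za=st.integers(-2, 2), zb=st.integers(-2, 2),
           i=st.floats(0.0, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_under_exchange(self, za, zb, i):
        assert chem.ionic_strength_factor(za, zb, i) == pytest.approx(
            chem.ionic_strength_factor(zb, za, i))

    @given(i=st.floats(1e-6, 5.0), j=st.floats(1e-6, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_ionic_strength(self, i, j):
        lo, hi = sorted((i, j))
        assert (chem.ionic_strength_factor(-1, -1, lo)
                <= chem.ionic_strength_factor(-1, -1, hi))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chem.ionic_strength_factor(-1, -1, -0.1)


class TestSpeciation:
    def test_half_at_pka(self):
        assert chem.hn3_fraction(4.7) == pytest.approx(0.5)

    def test_fully_deprotonated_limit(self):
        assert chem.hn3_fraction(14.0) < 1e-9

    def test_neutral_ph_value(self):
        # 1/(1 + 10^2.3) = 4.99e-3: azide is almost entirely anionic
        assert chem.hn3_fraction(7.0) == pytest.approx(4.988e-3, rel=1e-3)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            chem.hn3_fraction(-1.0)


class TestScavengingCapacity:
    def test_zero_concentration(self):
        assert chem.scavenging_capacity(1.5e6, 0.0) == 0.0

    def test_unit_concentration(self):
        assert chem.scavenging_capacity(3.15e9, 1.0) == 3.15e9

    def test_scavenging_time_spur_lifetime_order(self):
        """e_aq- in 5 M azide: scavenging time 1/(k5 c) = 1.33e-7 s, the
        same order as the ~0.2 us spur lifetime."""
        cap = chem.scavenging_capacity(1.5e6, 5.0)
        assert cap == pytest.approx(7.5e6)
        assert 1.0 / cap == pytest.approx(1.333e-7, rel=1e-3)

    def test_water_reaction_as_first_order(self):
        # e_aq- + H2O at 19 M^-1 s^-1 folds to ~1.05e3 s^-1
        assert chem.intrinsic_first_order_rate(19.0) == pytest.approx(
            1051.46, rel=1e-4)
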