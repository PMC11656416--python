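"""Speciation oracle and Davies activity helper."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nmrpka as n
from nmrpka.errors import ConvergenceError, DomainError


def closed_form_monoprotic_ph(pKa: float, C: float) -> float:
    """Independent oracle: exact [H+] of a monoprotic acid including water.

    Positive root of h^3 + Ka*h^2 - (Ka*C + Kw)*h - Ka*Kw = 0.
    """
    Ka = 10.0**-pKa
    roots = np.roots([1.0, Ka, -(Ka * C + n.KW), -Ka * n.KW])
    h = max(r.real for r in roots if abs(r.imag) < 1e-30 and r.real > 0)
    return -math.log10(h)


class TestDavies:
    def test_zero_ionic_strength(self):
        assert n.davies_log_gamma(1, 0.0) == 0.0

    def test_printed_value_at_10mM(self):
        # sqrt(0.01)/(1.1) - 0.003 = 0.0879091; x 0.509 = 0.0447457
        assert n.davies_log_gamma(1, 0.01) == pytest.approx(-0.0447457, abs=1e-6)
        assert n.davies_log_gamma(-1, 0.01) == pytest.approx(-0.0447457, abs=1e-6)

    def test_charge_squared_scaling(self):
        assert n.davies_log_gamma(2, 0.01) == pytest.approx(
            4 * n.davies_log_gamma(1, 0.01)
        )

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(DomainError):
            n.davies_log_gamma(1, -0.001)


class TestSpeciation:
    def test_pure_water(self):
        state = n.solve_speciation(use_activity=False)
        assert state.pH == pytest.approx(7.0, abs=1e-9)

    def test_strong_acid_alone(self):
        state = n.solve_speciation(strong_anions=0.010, use_activity=False)
        assert state.pH == pytest.approx(2.0, abs=1e-6)

    def test_spec_example_monoprotic(self):
        acid = n.AcidSpecies("acetic", (4.76,), 0.010, 0)
        state = n.solve_speciation([acid], use_activity=False)
        assert state.pH == pytest.approx(3.389, abs=2e-3)

    @pytest.mark.parametrize("pKa", [2.0, 4.0, 6.0, 8.0, 10.0])
    @pytest.mark.parametrize("C", [0.001, 0.010, 0.100])
    def test_matches_closed_form_monoprotic(self, pKa, C):
        acid = n.AcidSpecies("HA", (pKa,), C, 0)
        state = n.solve_speciation([acid], use_activity=False)
        assert state.pH == pytest.approx(closed_form_monoprotic_ph(pKa, C), abs=1e-8)

    @pytest.mark.parametrize("pKa,C", [(2.0, 0.010), (2.0, 0.100), (3.0, 0.100)])
    def test_matches_quadratic_where_water_negligible(self, pKa, C):
        # the water-free quadratic is only valid well below neutrality
        Ka = 10.0**-pKa
        h = (-Ka + math.sqrt(Ka * Ka + 4 * Ka * C)) / 2
        acid = n.AcidSpecies("HA", (pKa,), C, 0)
        state = n.solve_speciation([acid], use_activity=False)
        assert state.pH == pytest.approx(-math.log10(h), abs=1e-8)

    def test_charge_residual_tiny(self):
        acid = n.AcidSpecies("phosphoric", (2.16, 7.21, 12.32), 0.060, 0)
        ind = n.INDICATORS["1,2,4-triazole"]
        state = n.solve_speciation(
            [acid], base=ind, base_conc=0.050, strong_anions=0.002, use_activity=True
        )
        assert abs(state.charge_residual) < 1e-12

    def test_more_base_never_lowers_ph(self):
        acid = n.AcidSpecies("HA", (4.76,), 0.010, 0)
        ind = n.INDICATORS["2-methylimidazole"]  # neutral free base
        phs = [
            n.solve_speciation([acid], base=ind, base_conc=b).pH
            for b in np.linspace(0.0, 0.040, 9)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(phs, phs[1:]))

    def test_more_base_never_lowers_ph_sodium_salt(self):
        # an anionic base arrives as its sodium salt: counter-ion included
        acid = n.AcidSpecies("HA", (4.76,), 0.010, 0)
        ind = n.INDICATORS["acetate"]
        phs = [
            n.solve_speciation([acid], base=ind, base_conc=b, strong_cations=b).pH
            for b in np.linspace(0.0, 0.040, 9)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(phs, phs[1:]))

    def test_more_acid_never_raises_ph(self):
        ind = n.INDICATORS["2-methylimidazole"]
        phs = [
            n.solve_speciation(
                [n.AcidSpecies("HA", (9.19,), c, 0)], base=ind, base_conc=0.010
            ).pH
            for c in np.linspace(0.0, 0.040, 9)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(phs, phs[1:]))

    def test_activity_reduces_to_ideal_at_infinite_dilution(self):
        # water's own ions floor the ionic strength near 1e-7 M, so the two
        # conventions can only agree to the Davies term at that I (~2e-4)
        acid = n.AcidSpecies("HA", (5.0,), 1e-7, 0)
        on = n.solve_speciation([acid], use_activity=True)
        off = n.solve_speciation([acid], use_activity=False)
        assert on.pH == pytest.approx(off.pH, abs=1e-3)

    def test_activity_on_shifts_indicator_equilibrium_by_davies_term(self):
        # a charged conjugate pair in salt: mixed pKa moves by dz2*A*f(I)
        ind = n.INDICATORS["2-methylimidazole"]
        salt = 0.05
        state = n.solve_speciation(
            base=ind, base_conc=0.010, strong_cations=salt,
            strong_anions=salt + 0.005, use_activity=True,
        )
        bh, b = state.species[ind.name]
        pKa_mixed_obs = state.pH + math.log10(bh / b)
        expected = ind.pKa0 + ind.dz2 * 0.509 * (
            math.sqrt(state.ionic_strength) / (1 + math.sqrt(state.ionic_strength))
            - 0.3 * state.ionic_strength
        )
        assert pKa_mixed_obs == pytest.approx(expected, abs=1e-9)

    def test_multiprotic_fractions_sum_to_total(self):
        acid = n.AcidSpecies("citric-like", (3.1, 4.8, 6.4), 0.010, 0)
        state = n.solve_speciation([acid], use_activity=True)
        assert state.species["citric-like"].sum() == pytest.approx(0.010, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            n.solve_speciation(strong_anions=-0.01)

    @given(
        pKa=st.floats(2.0, 10.0),
        C=st.floats(0.001, 0.100),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_closed_form_agreement_property(self, pKa, C):
        acid = n.AcidSpecies("HA", (pKa,), C, 0)
        state = n.solve_speciation([acid], use_activity=False)
        assert abs(state.pH - closed_form_monoprotic_ph(pKa, C)) < 1e-8


class TestDomainTypes:
    def test_acid_requires_increasing_pka(self):
        with pytest.raises(DomainError):
            n.AcidSpecies("bad", (7.0, 4.0), 0.010, 0)

    def test_site_dz2(self):
        assert n.AcidSpecies("HA", (4.0,), 0.01, 0).site_dz2(0) == -1
        assert n.AcidSpecies("BH", (9.0,), 0.01, +1).site_dz2(0) == +1
        assert n.AcidSpecies("H2PO4-", (7.21,), 0.01, -1).site_dz2(0) == -3

    def test_packaged_indicators(self):
        assert len(n.INDICATORS) == 5
        for ind in n.INDICATORS.values():
            assert ind.dz2 in (-1, +1)
            lo, hi = ind.pH_window
            assert lo >= ind.pKa0 - 1.5 and hi <= ind.pKa0 + 1.5
            assert lo <= ind.pKa0 <= hi

    def test_formate_has_inverted_limits(self):
        f = n.INDICATORS["formate"]
        assert f.delta_H < f.delta_L

    def test_load_indicator_by_name_and_dict(self):
        assert n.load_indicator("acetate").pKa0 == 4.76
        custom = n.load_indicator(
            {
                "name": "x",
                "pKa0": 5.0,
                "delta_H": 2.0,
                "delta_L": 1.0,
                "dz2": -1,
                "n_protons": 1,
                "pH_window": [4.0, 6.0],
            }
        )
        assert custom.delta_H == 2.0
        with pytest.raises(DomainError):
            n.load_indicator("no-such-indicator")
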