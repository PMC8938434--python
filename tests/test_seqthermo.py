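"""Sequence arithmetic and Stokes-law hydrodynamics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from fgphase import seqthermo as st


class TestRepeatSequence:
    def test_full_repeat_construction(self, unit):
        seq = st.build_repeat_sequence(unit, 52)
        assert len(seq) == 624
        assert seq.full_sequence == unit * 52
        assert st.count_motifs(seq.full_sequence, "FG") == 52

    def test_single_residue(self):
        seq = st.build_repeat_sequence("G", 1)
        assert seq.full_sequence == "G"
        assert st.count_motifs(seq.full_sequence) == 0

    def test_seven_repeat_fragment(self, unit):
        seq = st.build_repeat_sequence(unit, 7)
        assert len(seq) == 84
        assert st.count_motifs(seq.full_sequence) == 7

    def test_invalid_character_named_in_error(self):
        with pytest.raises(ValueError, match="'B'"):
            st.build_repeat_sequence("GGB", 2)

    def test_zero_repeats_rejected(self):
        with pytest.raises(ValueError):
            st.build_repeat_sequence("GG", 0)


class TestMolecularWeight:
    def test_unit_mass(self, unit):
        # Independent summation over the average residue-mass table + one water:
        # 4G + L + F + N + 2T + Q + P + A + 18.02 = 1119.20 Da.
        assert st.molecular_weight(unit) == pytest.approx(1119.20, abs=0.05)

    def test_free_glycine(self):
        assert st.molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_full_length_matches_stock_calibration(self, full_spec):
        # The 52-repeat comes to ~57.3 kDa, within 5% of the 60 ug/ul per 1 mM
        # stock calibration.
        assert full_spec.mw == pytest.approx(57.3e3, rel=0.01)
        assert full_spec.mw == pytest.approx(60e3, rel=0.05)

    def test_peptide_bond_additivity(self, unit):
        a, b = unit[:5], unit[5:]
        assert st.molecular_weight(a) + st.molecular_weight(b) - st.WATER_MASS == \
            pytest.approx(st.molecular_weight(unit), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.molecular_weight("")


class TestConcentrations:
    def test_condensed_phase_mass_concentration(self, full_spec):
        # 4.5 mM of the 52-repeat protein is ~258 mg/ml (reported ~260 mg/ml).
        assert st.molar_to_mass_conc(4.5e-3, full_spec.mw) == pytest.approx(258, abs=2)

    def test_zero_and_unit_cases(self):
        assert st.molar_to_mass_conc(0.0, 1e5) == 0.0
        assert st.molar_to_mass_conc(1e-3, 60e3) == pytest.approx(60.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            st.molar_to_mass_conc(-1.0, 100.0)

    @given(st_h.floats(1e-9, 1.0), st_h.floats(1e2, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_molar_mass_round_trip(self, c, mw):
        assert st.mass_to_molar_conc(st.molar_to_mass_conc(c, mw), mw) == \
            pytest.approx(c, rel=1e-12)

    def test_motif_molarity(self):
        assert st.motif_molarity(4.5e-3, 52) == pytest.approx(234e-3)
        assert st.motif_molarity(123.0, 0) == 0.0
        assert st.motif_molarity(1e-6, 52) == pytest.approx(52e-6)

    def test_sphere_local_concentration(self):
        # 52 FG motifs within the chain's ~5 nm hydrodynamic sphere: ~165 mM
        # (~170 mM reported).
        assert st.sphere_local_concentration(52, 5.0) == pytest.approx(0.165, abs=0.002)
        # r^-3 scaling
        assert st.sphere_local_concentration(52, 10.0) == \
            pytest.approx(st.sphere_local_concentration(52, 5.0) / 8.0, rel=1e-12)
        assert st.sphere_local_concentration(1, 1.0) == pytest.approx(0.3965, abs=0.002)

    def test_linearity_in_count(self):
        base = st.sphere_local_concentration(1, 5.0)
        assert st.sphere_local_concentration(13, 5.0) == pytest.approx(13 * base, rel=1e-12)
        assert st.motif_molarity(2e-3, 26) == pytest.approx(26 * st.motif_molarity(2e-3, 1))


class TestViscosityAndStokes:
    def test_handbook_values(self):
        assert st.water_viscosity(293.15) == pytest.approx(1.002e-3, rel=0.005)
        assert st.water_viscosity(297.15) == pytest.approx(0.911e-3, rel=0.005)

    def test_monotone_decreasing(self):
        assert st.water_viscosity(297.0) < st.water_viscosity(293.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.water_viscosity(250.0)

    def test_hydrated_radius(self, full_spec, fragment_spec):
        assert st.hydrated_radius(full_spec) == pytest.approx(28.7, abs=0.1)
        assert st.hydrated_radius(fragment_spec) == pytest.approx(16.3, abs=0.1)

    def test_hydration_shell_is_additive(self, full_spec):
        bare = st.bare_radius(full_spec.mw, full_spec.partial_specific_volume)
        assert st.hydrated_radius(full_spec) == pytest.approx(bare + 3.2, abs=1e-12)

    def test_tau_c_cubic_scaling(self):
        cond = st.SolutionConditions.water(24.0)
        assert st.sed_tau_c(20.0, cond) == pytest.approx(8 * st.sed_tau_c(10.0, cond))

    def test_diffusion_examples(self):
        cond = st.SolutionConditions(294.0, st.water_viscosity(294.0))
        assert st.stokes_einstein_D(5.0, cond) == pytest.approx(44.0, rel=0.02)
        assert st.stokes_einstein_D(10.0, cond) == \
            pytest.approx(st.stokes_einstein_D(5.0, cond) / 2.0)
        cond20 = st.SolutionConditions(293.15, st.water_viscosity(293.15))
        assert st.stokes_einstein_D(1.0, cond20) == pytest.approx(214.0, rel=0.01)

    def test_stokes_einstein_debye_identity(self):
        # D * tau_c = 2 r^2 / 9 exactly, for the same r, T, eta.
        cond = st.SolutionConditions.water(24.0)
        r_nm = 3.1
        d = st.stokes_einstein_D(r_nm, cond) * 1e-12          # m^2/s
        tau = st.sed_tau_c(r_nm * 10.0, cond) * 1e-9          # s
        assert d * tau == pytest.approx(2.0 * (r_nm * 1e-9) ** 2 / 9.0, rel=1e-12)
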