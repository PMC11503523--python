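"""Forward models: Nernst law, Beer-Lambert superposition, fast exchange."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metallospec import (
    PotentiometricCalibration,
    TitrationDesign,
    UsageError,
    fixture_shift_table,
    fixture_spectral_profile,
    nernst_slope,
    simulate_potentiometric,
    simulate_shifts,
    simulate_spectra,
)
from metallospec.titration import ligand_mole_fractions


def make_design(acid, ligand_conc, titrant_conc, v_max, n, T=298.15):
    comp = {"H": acid}
    if ligand_conc is not None:
        comp["GMT"] = ligand_conc
    return TitrationDesign(
        initial_volume=0.025,
        initial_composition=comp,
        titrant="NaOH",
        titrant_concentration=titrant_conc,
        additions=list(np.linspace(0.0, v_max, n)),
        temperature=T,
    )


class TestPotentiometric:
    def test_nernst_arithmetic_strong_acid(self, strong_acid_model):
        """E = 400 + 59.16*log10(1e-3) = 222.52 mV before any base."""
        design = TitrationDesign(
            initial_volume=0.025,
            initial_composition={"H": 1e-3},
            titrant="NaOH",
            titrant_concentration=0.1,
            additions=[0.0],
            temperature=298.15,
        )
        calib = PotentiometricCalibration(E0=400.0, nernst=59.16)
        _, emf = simulate_potentiometric(design, strong_acid_model, calib)
        assert emf[0] == pytest.approx(222.52, abs=0.01)

    def test_equivalence_at_steepest_step(self, strong_acid_model):
        """Steepest emf step sits at v_eq = C_a V0 / C_b."""
        design = make_design(1e-2, None, 0.1, 3.0e-3, 301)
        v, emf = simulate_potentiometric(
            design, strong_acid_model, PotentiometricCalibration(E0=400.0)
        )
        slope = np.diff(emf) / np.diff(v)
        v_mid = 0.5 * (v[1:] + v[:-1])
        v_eq_expected = 1e-2 * 0.025 / 0.1
        assert v_mid[np.argmin(slope)] == pytest.approx(v_eq_expected, abs=2e-5)

    def test_single_jump_with_amine_in_proton_total(self, gmt_model_25):
        """The amine (pK 3.60) titrates jointly with the mineral acid.

        One equivalence jump at the total-proton equivalence; the second
        finite difference of emf vs volume changes sign exactly once.
        """
        design = make_design(1e-2, 5e-4, 0.1, 2.85e-3, 150)
        v, emf = simulate_potentiometric(
            design, gmt_model_25, PotentiometricCalibration(E0=400.0)
        )
        d2 = np.diff(emf, 2)
        s = np.sign(d2)
        s = s[s != 0]
        assert int(np.sum(s[1:] != s[:-1])) == 1
        slope = np.diff(emf) / np.diff(v)
        v_mid = 0.5 * (v[1:] + v[:-1])
        # all 10 mM of analytical protons (incl. those parked on the amine)
        assert v_mid[np.argmin(slope)] == pytest.approx(2.5e-3, abs=2e-5)

    def test_junction_terms_enter_linearly(self, strong_acid_model):
        design = make_design(1e-2, None, 0.1, 1e-3, 5)
        base = PotentiometricCalibration(E0=400.0)
        jcal = PotentiometricCalibration(E0=400.0, junction_acid=10.0)
        _, e0 = simulate_potentiometric(design, strong_acid_model, base)
        _, e1 = simulate_potentiometric(design, strong_acid_model, jcal)
        # delta = j_a * [H+]; [H+] ~ diluted 1e-2
        h = 1e-2 * 0.025 / 0.025
        assert e1[0] - e0[0] == pytest.approx(10.0 * h, rel=1e-3)

    def test_dilution_conserves_moles(self, gmt_model_25):
        design = make_design(1e-2, 5e-4, 0.1, 2.5e-3, 20)
        for v in design.additions:
            totals = design.totals_at(v)
            moles_l = totals["GMT"] * (design.initial_volume + v)
            assert moles_l == pytest.approx(5e-4 * 0.025, rel=1e-12)
            moles_h = totals["H"] * (design.initial_volume + v)
            expected = 1e-2 * 0.025 - 0.1 * v
            assert moles_h == pytest.approx(expected, rel=1e-12, abs=1e-18)

    def test_temperature_mismatch_rejected(self, gmt_model_25):
        design = make_design(1e-2, 5e-4, 0.1, 1e-3, 5, T=310.15)
        with pytest.raises(UsageError):
            simulate_potentiometric(
                design, gmt_model_25, PotentiometricCalibration(E0=400.0)
            )


class TestSpectra:
    def test_beer_lambert_from_printed_epsilon_maximum(self, gmt_model_37):
        """0.06 mmol/L fully protonated at eps(280 nm) = 14000 gives Abs 0.840."""
        profile = fixture_spectral_profile()
        i280 = int(np.argmin(np.abs(profile.wavelengths - 280.0)))
        A = simulate_spectra([0.5], gmt_model_37, {"GMT": 6e-5}, profile)
        frac = 1.0 / (1.0 + 10.0 ** (0.5 - 3.51))
        assert A[0, i280] == pytest.approx(0.840, abs=2e-3)
        assert A[0, i280] == pytest.approx(0.840 * frac + 6e-5 * (1 - frac) *
                                           profile.epsilon["GMT"][i280], rel=1e-6)

    def test_zero_total_concentration_gives_zero_matrix(self, gmt_model_37):
        profile = fixture_spectral_profile()
        A = simulate_spectra([2.0, 6.0], gmt_model_37, {"GMT": 0.0}, profile)
        assert np.all(A == 0.0)

    def test_isosbestic_point_is_pH_independent(self, gmt_model_37):
        """The fixture bands cross at 260 nm, so Abs(260) is constant in pH."""
        profile = fixture_spectral_profile()
        i260 = int(np.argmin(np.abs(profile.wavelengths - 260.0)))
        assert profile.epsilon["(GMT)H"][i260] == pytest.approx(
            profile.epsilon["GMT"][i260], rel=1e-12
        )
        A = simulate_spectra(np.linspace(2.0, 8.0, 13), gmt_model_37,
                             {"GMT": 6e-5}, profile)
        assert np.ptp(A[:, i260]) <= 1e-12

    def test_linear_in_total_at_pinned_pH(self, gmt_model_37):
        profile = fixture_spectral_profile()
        A1 = simulate_spectra([3.0], gmt_model_37, {"GMT": 5e-5}, profile)
        A2 = simulate_spectra([3.0], gmt_model_37, {"GMT": 1e-4}, profile)
        assert np.allclose(A2, 2.0 * A1, rtol=1e-10)

    def test_missing_epsilon_rejected(self, zn_model_45):
        profile = fixture_spectral_profile()  # lacks the Zn complex bands
        with pytest.raises(UsageError, match="missing molar absorptivities"):
            simulate_spectra([3.0], zn_model_45, {"Zn": 4e-5, "GMT": 4e-5}, profile)


class TestShifts:
    def test_midpoint_shift_at_pH_equals_pK(self, gmt_model_25):
        """At pH = pK the CH-6' signal averages (7.9 + 7.7)/2 = 7.80 ppm."""
        table = fixture_shift_table()
        i = table.nuclei.index("CH-6p")
        d = simulate_shifts([3.60], gmt_model_25, {"GMT": 5e-3}, table)
        assert d[0, i] == pytest.approx(7.80, abs=1e-6)

    def test_high_pH_limit_is_free_ligand_shift(self, gmt_model_25):
        table = fixture_shift_table()
        i = table.nuclei.index("CH-6p")
        d = simulate_shifts([10.0], gmt_model_25, {"GMT": 5e-3}, table)
        assert d[0, i] == pytest.approx(7.70, abs=1e-4)

    def test_mole_fractions_sum_to_one(self, zn_model_45):
        _, X = ligand_mole_fractions(
            np.arange(2.0, 10.1, 0.5), zn_model_45, {"Zn": 6e-3, "GMT": 5e-3}, "GMT"
        )
        assert np.abs(X.sum(axis=1) - 1.0).max() <= 1e-10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(ph=st.floats(min_value=1.5, max_value=11.0))
def test_observed_shift_is_convex_combination(ph):
    """Fast-exchange average always lies within the species-shift envelope."""
    from metallospec import fixture_model

    model = fixture_model("gmt_acid_base_25C")
    table = fixture_shift_table()
    d = simulate_shifts([ph], model, {"GMT": 5e-3}, table)
    for j, nuc in enumerate(table.nuclei):
        lo = min(table.delta["(GMT)H"][nuc], table.delta["GMT"][nuc])
        hi = max(table.delta["(GMT)H"][nuc], table.delta["GMT"][nuc])
        assert lo - 1e-12 <= d[0, j] <= hi + 1e-12
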